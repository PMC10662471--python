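"""SESC identification from static postures and center of pressure.

Only the horizontal CoM projection (the force-plate CoP) is observable
in practice.  This script identifies the subject-specific vector V from
2D CoP readings over diverse static postures, then predicts the full 3D
CoM of held-out postures — including the never-observed vertical
coordinate — and scores it against the generator's ground truth.
"""

import warnings

import numpy as np

from sescom import estimate_com, identify_partial, min_postures
from sescom.synthetic import NoiseSpec, generate_observations, sample_postures, sample_subject

subject = sample_subject(7)
model = subject.model("d")
print(f"minimum postures for 2D identification: {min_postures(model)} (= ceil(3n/2), n=9)")

train = sample_postures(model, 40, 11)
noise = NoiseSpec(cop_noise_sd_mm=3.0, angle_noise_sd_deg=0.75)
obs = generate_observations(subject, model, train, noise, 13)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)  # hinge-child y-columns
    result = identify_partial(obs, model)
print(f"identified from k={result.k_postures} postures; "
      f"rank {result.rank}/{result.n_params}, residual RMS "
      f"{1000 * result.residual_rms:.2f} mm")

holdout = generate_observations(
    subject, model, sample_postures(model, 25, 17), noise, 19
)
err = np.array([
    estimate_com(model, result.vector, o.posture) - o.true_com for o in holdout
]) * 1000.0
rms = np.sqrt((err**2).mean(axis=0))
print(f"held-out 3D CoM RMS error (AP, ML, vertical): "
      f"{rms[0]:.2f}, {rms[1]:.2f}, {rms[2]:.2f} mm")
print("-> a few mm per axis, on the order of the 3 mm CoP sensor noise;")
print("   the vertical coordinate is recovered although it was never measured.")
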