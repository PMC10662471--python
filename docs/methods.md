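# Methods

## Model and coordinate conventions

The body is a rooted tree of joints; the segment attached distal to joint j
is rigid, with mass mⱼ and a constant CoM offset cⱼ in joint j's frame. The
global frame is X anteroposterior (anterior positive), Y mediolateral,
Z vertical up, so flexion/extension is rotation about Y and a hinge-only body
moves purely in the sagittal (X–Z) plane. Multi-DoF joints compose as
R = R_y(α)·R_x(β)·R_z(γ), the ZXY-"fixed" order used by IMU motion-capture
exports; 2-DoF joints keep the leading R_y R_x pair. Angles are radians and
lengths meters inside the library; every file and CLI boundary uses degrees
and millimeters. The same sign conventions are applied to both body sides;
side-specific mirroring conventions exist in some mocap stacks, but the
identification is invariant to any fixed, consistent choice.

The simplest preset (a) deserves a note: a 7-segment, 7-joint body whose
named joints are trunk root, shoulders and ankles would have only 5 joints;
the unique 7-joint tree consistent with two three-deep branches (and with the
knee-for-ankle swap that defines preset c) also includes the hips, and that
is the topology shipped. The head is lumped with the trunk and each arm is a
single segment — elbows and wrists never enter any preset.

## The SESC reparameterization

CoM = d₁ + B·V with B = [R₁ … Rₙ] the global joint rotations of the posture
and V constant per subject×model. The closed form used for ground truth is

    vⱼ = ( mⱼ cⱼ + Σ_{children q of j} M_subtree(q) · offset_q ) / M,

which satisfies d₁ + B V = weighted-segment CoM identically; the test suite
asserts this to 1e-10 m over random subjects and postures for all presets,
and it is the oracle for everything downstream.

## Identification

Full-3D identification stacks the 3-row B blocks of k postures; practical
(partial) identification drops the vertical row, stacks the AP/ML rows against
CoP − d₁, and needs k ≥ ⌈3n/2⌉ postures (enforced as an error, overridable).
d₁ is taken per posture from the posture's root position (floating base); the
synthetic generator uses d₁ = 0 by default, and frame unification places the
recorded session in the same body-rooted frame.

The least-squares solution is computed by SVD with a relative singular-value
cutoff of 1e-10 rather than via the normal equations (B†=(BᵀB)⁻¹Bᵀ squares
the condition number); both agree on well-conditioned systems.

### Structural rank deficiency

Whenever a child joint is a hinge about Y, its global rotation satisfies
R_child·e_y = R_parent·e_y, so its y-column of B duplicates its parent's at
*every* posture. All four presets therefore yield rank-deficient design
matrices — e.g. the richest body has rank 23 of 27 (knees and ankles copy
their parents' y-columns), and the hinge-only body additionally has one
shared ML column across all joints. Because the null space is
posture-independent, the minimum-norm solution predicts CoM exactly; the
identification result reports rank, condition number and the deficient
columns, full-3D identification raises an explicit error when rank < 3n, and
CoP identification warns and returns the minimum-norm vector. Individual
components of V tied to a duplicated column are not separately meaningful —
only their sums are — which is why recovery is asserted in prediction space
(held-out CoM), not parameter space, and why estimator unbiasedness is also
tested on predictions.

A corollary used by the evaluation layer: the hinge-only body's ML estimate
is the constant d₁_y + Σⱼ vⱼ_y, so its difference-vs-mean (Bland–Altman)
regression per subject has slope exactly −2 (d = 2c − 2m).

## Preprocessing

CoP at 1000 Hz is filtered with a 4th-order Butterworth low-pass at 10 Hz,
applied forward–backward. Zero-phase filtering is a deliberate choice (a
causal pass would phase-shift CoP relative to the angle channels; only the
magnitude response matters for static analysis) — the effective magnitude
response is the squared 4th-order response. Resampling to 60 Hz is polyphase
with line padding. Static detection slides a 1 s window with stride one
sample; a window passes when every angle channel's SD is below 1.5° and each
CoP axis SD is below 6 mm (the displacement criterion is read per axis, the
stricter of the two readings, configurable); overlapping passing windows are
merged and runs shorter than 5 s discarded; the emitted posture is the
channel mean over the run's central 1 s. The 75/25 identification/test split
is a seeded random partition with train size round(0.75·k) (a chronological
split is available by flag); a typical session of 98 postures splits
74/24.

## Synthetic data

The generator emulates an identification study: subjects drawn around a
neutral adult template (total mass U(55, 95) kg, stature scale U(0.9, 1.1),
±10% relative jitter on segment mass fractions, renormalized; mass fractions
and segment CoM offsets follow standard anthropometric proportions with the
trunk+head at 0.578 of body mass), ~98 static postures per subject sampled
uniformly within conservative healthy ranges of motion per joint, CoP equal
to the true horizontal CoM plus Gaussian noise, and measured angles with
Gaussian noise. Noise defaults are half the static criteria (3 mm, 0.75°) so
scheduled holds pass detection with margin. The truth body is the richest
preset (d) by default, so simpler fitted models incur systematic error purely
from their missing DoFs — the model-complexity effect. Raw sessions are
holds joined by smooth cosine ramps, angles at 60 Hz and CoP at 1000 Hz, with
an optional constant plate-to-body offset to exercise frame unification.

What the generator does **not** emulate: physiological sway dynamics,
soft-tissue artifact, IMU bias/drift, subject-specific posture repertoires,
or anthropometric covariance structure. Passing tests therefore demonstrate
correctness of the estimation machinery and the qualitative
complexity-vs-accuracy ordering, not the millimeter-level error magnitudes of
any real cohort, whose values depend on the actual recordings.

## Evaluation

Per axis: RMS error, Pearson/Spearman correlations, and Bland–Altman bias
with 95% limits of agreement (bias ± 1.96·SD of differences). Proportional
bias is a pooled OLS regression of difference on pairwise mean plus
per-subject slopes summarized by their mean and between-subject SD — a
two-stage, random-intercept-style summary; a full likelihood-based
mixed-effects model is deliberately out of scope and every report carries a
note saying so. The cross-model table reports per-subject RMS mean ± SD and
quartiles with subject pairing preserved in pairwise differences; the
normality-gated hypothesis-test battery (Shapiro–Wilk, RM-ANOVA/paired-t,
Friedman/Wilcoxon) is standard off-the-shelf statistics and is left to
external tools, for which the table exposes the paired per-subject values.

A known edge: when an estimator is constant per subject but subjects differ,
the pooled difference-on-mean regression consists of parallel lines with
slope −2 and distinct intercepts; the per-subject slope of −2 is the robust,
asserted quantity, while the pooled R² depends on intercept dispersion and is
not asserted.

## Problem sizes and determinism

Default study conditions are 18 subjects × 98 postures, truth body (d),
3 mm / 0.75° noise, 75/25 split; the complexity-ordering experiment uses 20
cohort replicates of that size, and smaller sizes appear in unit tests as
stated in each test. All sampling flows through `numpy.random.Generator`
seeded explicitly; identical seeds give byte-identical datasets, reports and
manifests.

## Limitations

Static postures only (no dynamic or Kalman identification); no symmetry
reductions or node-based SESC variants; no vendor file formats or hardware
interfacing; LoA are reported without repeated-measures corrections or
confidence intervals.
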