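# Methods

This note documents the models, parameters and design choices behind
`covisa`, in the order the online pipeline runs them.

## Scan protocol and cue schedule

`ScanProtocol` defaults describe a single 995-volume EPI run: TR = 1.62 s,
270 localizer + 725 control volumes, 96×96 matrix × 35 slices at
1.848 × 1.848 × 2 mm. The localizer tiles into 54 five-volume trials
(8.1 s each). Trials alternate center/directional starting with a center
trial; the 27 directional slots are a seeded balanced permutation of
9 right / 9 left / 9 up. The paper-facing constraint is only that
directional trials are always separated by a center trial; the exact
start, counts and balance are this package's choices (balance keeps the
GLM design well-conditioned and the classifier classes even).

Tests and the acceptance script run the same timing on a 24×24×12 grid
("desk scale"); the full-size grid uses identical code paths and is
exercised only where geometry matters (voxel-volume arithmetic).

## Synthetic sessions

Each voxel's signal is

    y_v(t) = b_v · (1 + a_v · (s_d * h)(t)) + drift_v(t) + ε_v(t)

where `b_v` is the baseline (≈1000 arbitrary scanner units, with a smooth
deterministic "tissue texture" of ±15–25% inside an ellipsoidal brain
mask), `a_v` the voxel's fractional response amplitude (default 0.03 in
its direction's ROI, 0 elsewhere), `s_d` the indicator of attention state
`d`, and `h` the hemodynamic impulse response. Four disjoint 48-voxel
cuboid ROIs mirror the contralateral organization of attention-driven
visual cortex at toy scale (left-attention ROI in the right hemisphere and
vice versa, up inferior, center medial). The texture exists for two
reasons: real grey/white matter has intensity structure, and a uniform
ellipsoid would leave rigid registration with an unidentifiable rotation.

**HRF.** The response kernel is a canonical double-gamma (peak ≈ 5 s,
undershoot ≈ 16 s at 1/6 amplitude) sampled at TR and normalized to unit
peak; a pure-delay kernel is available as a degenerate alternative for
sensitivity checks. The underlying experiment reports only that the BOLD
response is slow; the functional form is our choice, and the GLM can also
be run on raw boxcars (`convolve_regressors=False`).

**Noise.** Default session noise is white Gaussian noise with sd 8 (≈0.8%
of baseline), a per-voxel random walk with step sd 0.8, and a per-voxel
linear trend with endpoint sd 15 — drift comparable to or larger than the
task effect over the run, so the drift regressor and the detrending stage
do real work, while single-trial effects remain decodable, as they must be
for a feasible BCI. All noise is driven by one seeded generator;
regeneration is bit-identical. What the generator does **not** emulate:
physiological (cardiac/respiratory) noise, spatial noise correlations,
scanner spikes and slow gain drift of non-polynomial shape, or retinotopic
realism of the ROI layout. Passing tests therefore demonstrate the
correctness and closed-loop viability of the analysis chain, not its
performance on human 7T data.

**Closed-loop synthesis.** Because the subject's attention depends on the
robot's pose, control-phase volumes cannot be precomputed. The
`OnlineSynthesizer` produces one volume per call from the evolving state
history (causal HRF convolution), with noise processes continuous across
the localizer/control boundary.

## Motion correction

Each volume is rigidly registered to the first localizer volume: 6
parameters (Euler angles about the volume center + translation, world
coordinates = index × voxel size). The metric is the mean squared
difference between the two images after Gaussian smoothing (σ = 1 voxel,
applied for metric evaluation only). The optimizer is a stochastic
gradient descent with exactly 50 iterations: each iteration draws 2048
random grid voxels, evaluates the analytic metric gradient there (chain
rule through the linearly interpolated smoothed moving image, zero-filled
out of field), and takes a step along the normalized, lever-arm
preconditioned gradient with decaying length a/(A+k)^α (defaults a = 3 mm,
A = 10, α = 0.602). The step is additionally damped by the gradient norm
relative to its running peak, which suppresses the stochastic jitter floor
once inside the convergence basin. The cited optimization scheme specifies
no gains or sample counts; all are exposed in `RegistrationConfig`, and
the defaults were calibrated on the noiseless desk-scale phantom to
recover injected translations of up to 2 voxels within 0.2 voxel.
Samples are drawn from the full grid, not only brain voxels — restricting
to template-body voxels leaves moving-image structure over background
unpenalized and measurably biases the optimum.

The corrected image is produced from the *unsmoothed* moving image by
interpolating cubic B-spline resampling (prefiltered, so grid points are
reproduced exactly under the identity transform); out-of-field voxels are 0.

## Incremental GLM and t-maps

Per-voxel regression state is the accumulator triple (XᵀX, Xᵀy, yᵀy),
updated rank-1 with each volume — O(voxels) per update, no image history
— and algebraically identical to a batch least-squares fit at any point.
We chose the accumulator formulation over recursive inverse updates for
numerical simplicity; the system is solved (once, when maps are requested)
by dense inversion with a pseudo-inverse fallback for rank-deficient
designs. The design is five columns: the four HRF-convolved attention
boxcars and a linear ramp; there is no separate intercept (the four
condition columns jointly absorb the constant). Contrast t values use
t = wᵀβ̂ / √((RSS/ν)·wᵀ(XᵀX)⁻¹w) with ν = N − 5; residual sums of squares
within 1e−12 of yᵀy are clamped to zero (exact fits) and map to a
sign-matched infinite sentinel. No prewhitening, spatial smoothing or
multiple-testing correction is applied — selection is rank-based.

## Feature selection

From each of the four t-maps the 500 highest-t voxels are taken (ties at
the boundary broken toward the lower linear index, so selection is
deterministic; values, not magnitudes, are ranked). The four sets are
merged by union (≤2000 voxels) and connected components smaller than 5
voxels are removed under face-adjacent 6-connectivity — the most
conservative standard neighborhood; 18/26 are selectable. The filter is
idempotent. Voxels whose detrended localizer series has (numerically)
zero variance are excluded afterwards, since they cannot be z-scored.

## Detrending and normalization

The low-frequency trend of a length-T series is the solution of the
second-difference-regularized least squares problem, trend =
(I + λ²D₂ᵀD₂)⁻¹ y with λ = 200; the system is pentadiagonal and solved
via banded Cholesky (factor cached per (T, λ)). An exactly linear series
detrends to zero; λ = 0 removes everything; λ → ∞ removes only the best
straight line. At the end of the localizer the full series of every
selected voxel is detrended in batch and its mean/SD are frozen as the
normalizer. During control, each new volume's raw values are appended to
the kept raw history and the trailing `control_window` (default 100
volumes) is re-detrended; the newest detrended sample is z-scored with the
frozen statistics. Whether the original online system used a growing
history or a window is unknowable from its description; the trailing
window is causal, has bounded cost, and equals full-history batch
detrending whenever the window covers the history. Endpoint bias of the
smoothness prior at the newest sample is accepted as-is.

## Classifier

Six binary soft-margin linear SVMs (C = 1), one per unordered class pair,
trained on the detrended, normalized localizer feature vectors. Training
labels are the cue active `label_lag_volumes` earlier (default 2 volumes ≈
3.24 s) to compensate hemodynamic delay; the first `lag` volumes are
dropped. Lag 0 and late-trial-only labeling are available for comparison;
the original labeling window is not documented. Classification evaluates
all six pairwise votes; the strict-majority class wins and *any* tie for
first place — including ties involving center — resolves to center, so
the robot never acts on an ambiguous volume. The per-pair fits delegate to
a standard SVM solver; the voting rule is implemented here because the
usual one-vs-one tie-breaks differ.

## Control loop

State machine: a decoded right/left/up volume emits its command
(turn ∓30°, forward 50 cm) and opens a 5-volume refractory window — one
volume carrying the movement, then four washout volumes (6.48 s) with the
video feed off. Classification continues during refractory but is logged
and suppressed rather than skipped, preserving auditability. A forward
move that would cross a wall reverts to the pre-command pose (the
experimenters moved the physical robot back by hand). Optional Gaussian
movement jitter (σ ≈ 2 cm / 2°) mimics the toy robot's imprecision;
default off.

The arena is a 4 × 5 m room with four 25 × 50 cm floor targets laid out
as an inner loop; the original room's dimensions are unpublished, so the
layout is qualitative and fully configurable. The robot starts at target
four and targets must be entered (closed rectangles, robot center point)
in the sequence 1→2→3→4→1→…

The scripted planner subject attends UP when a forward step strictly
reduces distance to the next target's center, otherwise turns toward it;
during refractory it rests at center. A decodable non-center label
additionally requires 5 volumes of sustained attention (the BOLD rise),
and the subject rests for an initial washout at control start (the last
localizer trial's response is still decaying). Together these reproduce
the canonical timing arithmetic: minimum inter-command interval
10 TR = 16.2 s and at most ⌊725/10⌋ = 72 commands per session. The rise
and initial rest are properties of the simulated subject/hemodynamics;
the state machine itself enforces only the 5-volume refractory.

With the perfect-decoder bypass (`decoder="truth"`) the planner reaches
all four targets well within the control phase on the default arena; with
the trained SVM decoder the default synthetic session behaves nearly
identically — the toy phantom's SNR makes decoding easy, which is the
point: failures then indicate pipeline defects, not noise.

## Problem sizes and numerical notes

Tests and the acceptance script use the 24×24×12 grid with the full
270/725-volume timing; a complete closed-loop SVM session runs in a few
seconds at ≈5 ms/volume, comfortably inside the 1.62 s TR (the soft
real-time property is logged, not asserted). Determinism: every stochastic
component (schedule, noise, registration sampling, movement jitter) is
driven by an explicit seed; identical seeds give byte-identical session
logs. Degenerate inputs are rejected loudly: constant registration
templates, non-finite GLM inputs or transforms, zero-variance voxels,
mismatched volume counts or grids.

## Known limitations

- The simulator's noise model is far simpler than 7T EPI reality (see
  above); decoding accuracies here say nothing quantitative about humans.
- Euler-angle registration is fine for small head motion but is not a
  general-purpose registrar (no multi-resolution pyramid, no masks).
- The one-sample-per-TR HRF discretization ignores slice timing.
- The planner subject is deliberately simple (greedy, one-step lookahead);
  it can stall in contrived arenas with concave obstacles, which the
  default room does not have.
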