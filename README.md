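# covisa — a closed-loop fMRI brain–computer interface on covert visuospatial attention

`covisa` simulates and decodes a real-time fMRI experiment in which a subject
steers a telepresence robot purely by shifting covert visuospatial attention
— to the **right**, **left**, **up**, or back to the **center** — while
keeping the eyes fixated. Attending a peripheral location modulates
retinotopic visual cortex contralaterally; those BOLD modulations are
decodable from single volumes at high field, fast enough to close the loop
within one repetition time.

The package is aimed at researchers prototyping real-time fMRI / BCI
analysis pipelines who need a fully synthetic, deterministic stand-in for
the scanner and the subject: every stage of the online analysis is
implemented and testable end to end without any acquisition hardware.

## The pipeline

A session is a single 995-volume run (TR = 1.62 s): a **localizer phase**
(270 volumes) of cued 5-volume attention trials — right/left/up trials
randomized and always separated by a center trial — followed by a
**control phase** (725 volumes) in which each decoded volume may issue a
robot command (UP → 50 cm forward, RIGHT/LEFT → 30° turn).

Per volume, the online analysis is:

1. **Motion correction** (`covisa.motion`) — rigid registration to the
   first localizer volume: sum-of-squared-differences metric on images
   smoothed with a Gaussian of σ = 1 voxel, 50 iterations of stochastic
   gradient descent, cubic-B-spline resampling.
2. **Incremental GLM** (`covisa.glm`) — per-voxel sufficient statistics
   (XᵀX, Xᵀy, yᵀy) updated with every localizer image for a design of five
   regressors (right, left, up, center attention + linear drift). Four
   one-vs-rest contrast t-maps (e.g. right − ⅓[left + up + center]) are
   identical to a batch fit:
   t = wᵀβ̂ / √( (RSS/ν) · wᵀ(XᵀX)⁻¹w ), ν = N − 5.
3. **Feature selection** (`covisa.features`) — union of the 500
   highest-t voxels from each of the four maps, then removal of connected
   components smaller than 5 voxels (6-connectivity); the surviving voxels
   (always < 2000) are the classifier's feature space.
4. **Detrending + normalization** (`covisa.detrend`) — smoothness-priors
   detrending, trend = (I + λ²D₂ᵀD₂)⁻¹y with λ = 200 (D₂ the
   second-difference operator), then per-voxel z-scoring with baseline and
   scale frozen at the end of the localizer; control volumes are detrended
   causally over a trailing window of the kept raw history.
5. **Classification** (`covisa.classifier`) — six pairwise linear C-SVMs
   (C = 1, one-against-one) over {right, left, up, center}; majority vote,
   any tie for first place → center (no action).
6. **Control loop** (`covisa.control`) — a decoded direction issues its
   command, then a 5-volume refractory window (1 movement volume + 4
   washout volumes with the video feed off, 6.48 s) suppresses further
   commands while the hemodynamic response subsides. With the ~5-TR BOLD
   rise this caps the command rate at one per 10 TRs (16.2 s), at most 72
   commands in the 1174.5 s control phase.

The **simulator** (`covisa.simulate`) replaces scanner and subject: a
textured ellipsoidal phantom with four attention-responsive voxel clusters,
double-gamma hemodynamics, random-walk + linear drift, white noise and
optional rigid head motion — all seeded and bit-reproducible. A scripted
planner "subject" attends toward whichever command brings the robot closer
to the next of four floor targets, which must be visited in sequence.

## Worked example

```bash
covisa run --seed 1 --out out/
```

runs a complete closed-loop session on the desk-scale 24×24×12 grid and
prints:

```
[run] mask=1624 voxels, training_accuracy=1.00, commands=71, targets_reached=8 (4.6s, 0.005s/volume vs TR 1.62s)
[run] target  cumulative_seconds  cumulative_movements
[run] 1       85.9                6
[run] 2       233.3               15
[run] 3       388.8               24
[run] 4       502.2               31
...
```

Reading: feature selection kept 1624 voxels (< 2000); the SVM reproduced
every lagged localizer label; during control the decoder issued 71 commands
(≤ 72, the refractory-rule maximum) and the robot reached the first four
targets after 86 s, 233 s, 389 s and 502 s of control time using 6, 15, 24
and 31 movements — the same cumulative-time (movement-count) format used
for human sessions. Per-volume processing at 5 ms is far inside the 1.62 s
TR budget. `covisa simulate` writes a session to 4-D NIfTI with events and
ground-truth sidecars; `covisa evaluate --log out/session_log.tsv --plot
path.png` summarizes a log and draws the robot's floor path.

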