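# Methods

## Problem and data model

Unilateral facial paralysis (FP) weakens the voluntary facial muscles on
one side, producing resting (static) asymmetry and a reduced range of
motion (dynamic asymmetry). The package assesses FP from *facial
animation units* (FAUs): 17 dimensionless scalar activations per video
frame, as produced by the Kinect v2 SDK's face tracker, each
approximating a FACS action-unit intensity. A recording protocol
consists of a rest session plus five voluntary movements — smiling, eye
closure, raising eyebrows, blowing cheeks, whistling — each captured as
an ordered frame sequence.

Units are identified by descriptor name (`lip_corner_puller_left`, …),
never by numeric code: published numberings of this unit set are
internally inconsistent, while names are unambiguous. Twelve units form
six left/right mirror pairs. Activation ranges: the ten paired units
other than the eyebrow lowerers live in [0, 1]; the eyebrow lowerers and
the five unpaired units live in [−1, 1], because raising the eyebrows
legitimately drives the lowerer units below zero. The tracker does not
publish activation ranges; these are the tightest ranges consistent with
the symmetry index construction below.

The rest baseline is the per-unit **median** over the rest session's
frames (restricted to frames whose tracking flag is not bad). A median
rather than a single "resting frame" is robust to transient tracker
glitches and reduces to the frame itself for single-frame sessions.

## Symmetry analysis

For one mirror pair, the animation symmetry index is

    ASI = (1 − |L − R|) × 100 %,

clamped to [0, 100]. The clamp matters only for the eyebrow pair, whose
units can take opposite signs so |L − R| may exceed 1; clamping keeps
the index interpretable as percent symmetry. Three areas are scored —
eyes, eyebrows, and mouth — where the mouth index is the exact
arithmetic mean of four component pairs (lip corner puller, lip
stretcher, lip corner depressor, cheek puff) and each movement's total
is the exact mean of the three areas. A full evaluation yields 18 area
values (3 areas × 6 movements, rest included).

Static symmetry uses the rest baseline frame. Dynamic symmetry is
evaluated at the **peak frame** of each movement — the frame maximising
the mean direction-folded movement-minus-rest delta over the movement's
engaged units, ties broken to the earliest frame. Evaluating at the peak
rather than averaging over the session makes the index reflect maximal
effort, mirrors how clinicians rate "at maximal movement", and makes the
static/dynamic split crisp; it is a design choice, since averaging over
frames would also be defensible. Display rounding is to whole percent;
JSON output keeps full precision.

## Movement grading

Each voluntary movement engages one unit per facial side (plus, for
whistling, the shared lip pucker), with a known direction of motion:
puller, eye-closed, and cheek-puff units increase; the eyebrow lowerers
decrease during a brow raise; the cheek-puff units decrease during
whistling. The *effective delta* of a unit is
`direction × (peak value − rest value)`, so expected motion is always
positive. The per-side grade is

    grade = min(10, floor((max(Δ, 0) + 1e−9) × 10)),

i.e. one point per completed 0.1 of effective delta, 10/10 at a
full-range change of 1.0. The 1e−9 epsilon guards binary-float artifacts
(0.3 × 10 = 2.999…); negative deltas (paradoxical or synkinetic motion)
clamp to grade 0 rather than raising, because such motion is expected in
FP and must not crash a report. Whistling's per-side delta is the
unweighted mean of the shared pucker delta and that side's cheek
decrease — the source procedure defines the three deltas but not their
combination, and the unweighted mean is the least-informative choice
that still produces a per-side grade; it is exposed through the same
per-side/shared mechanism as every other movement, so users can supply
a different movement specification.

## Feature ranking (ReliefF)

To identify the units engaged by each movement, binary ReliefF is run on
the 17-dimensional movement-minus-rest difference vectors of one
movement versus rest: for every instance, the k = 10 nearest hits and
misses are found by Manhattan distance on range-normalised features, and

    W[f] = Σᵢ [ Σ_miss diff(f) − Σ_hit diff(f) ] / (m·k),

with diff the range-normalised absolute difference and m the number of
instances (all instances are used — no subsampling — removing the only
randomness source of classic ReliefF). A zero-range (constant) feature
is defined to have diff 0, hence weight 0. Weights lie in [−1, 1].

The consensus "most important" list aggregates per-movement results by
**mean weight** across the five movements, not mean rank: uninformative
features have near-zero weight in every movement, but their *ranks*
among one another are an arbitrary noise permutation, so mean rank can
promote a never-engaged unit above a unit that is decisive for one
movement. Mean weight keeps every engaged unit on top. The resulting
top-9 — the six mouth/eye/brow pair units of the four per-side movements
plus lip pucker and the cheek pair — is frozen as the default classifier
feature set and can be overridden.

## Movement classification and the ability decision

The six-class movement recogniser is a standardise-then-RBF-SVM pipeline
(C = 10, gamma = 'scale') with sigmoid (Platt) probability calibration on
five unshuffled stratified folds, fitted on the selected
difference-vector features. For a fixed training set the fit is fully
deterministic; the seed tags the artifact and drives training-data
generation. Models serialise with joblib, embedding a schema version and
the feature list, and reload to bit-identical confidence vectors.

The ability decision maps a six-class confidence vector and the intended
movement to yes / no / maybe: if the top two confidences differ by
strictly less than the margin (default 0.07, i.e. 7 percentage points —
absolute, not relative) *and* the intended movement is one of the two,
the evidence is ambiguous → "maybe"; otherwise "yes" iff the intended
movement is the top class. Equal probabilities tie-break in canonical
label order, which makes the rule total; a gap of exactly the margin is
definite ("just less than" is strict), with a 1e−12 guard so that e.g.
0.47 − 0.40 compares as exactly 0.07. An intended movement outside the
top two is "no" even when the top two are close — ambiguity between two
other movements says nothing about the intended one.

## Synthetic session generator

The generator stands in for depth-camera acquisition; the clinical
dataset it emulates (13 patients, 375 records) is not public. Each
session is

    value(t) = rest + offset + profile × rise(t) × attenuation + noise,

clamped to legal ranges, where

* **rest** — symmetric resting activations: 0 everywhere except a 0.2
  cheek-puff tone, which is needed so whistling's cheek *decrease* is
  representable without clamping;
* **profile** — per-movement peak deltas of the engaged units: |Δ| = 0.8
  in the movement's direction, except whistling's cheek decrease, capped
  at −0.2 by the resting tone (a larger programmed decrease would clamp
  at zero and destroy the linearity of severity attenuation);
* **rise(t)** — a smoothstep ramp from 0 to 1 reaching the peak at
  two-thirds of the session and holding it, so the last third of the
  frames sit at maximal effort (n_frames = 30 ≈ 1 s of tracking);
* **attenuation** — `1 − severity` on the affected side's units
  (severity ∈ [0, 1]; 0 = healthy, 1 = complete palsy). Side-less units
  (whistling's lip pucker) are *not* attenuated by default, so the
  healthy side's grades are exactly invariant to severity; the
  `attenuate_shared` flag enables the clinically realistic alternative
  in which puckering — a bilateral act — degrades too, at the cost of
  that invariance. The `mirrored_blow` flag (default off) models the
  observation that some patients can puff the affected cheek but not the
  healthy one, by attenuating the healthy side for blowing-cheeks only;
* **offset** — a fixed per-patient static asymmetry on the affected
  side's paired units, drawn once per patient from
  N(0, (rest_asymmetry_scale × severity)²) with scale default 0.05;
  because it is constant within a patient it cancels out of all
  movement-minus-rest deltas and shows up only in the symmetry indices,
  which is exactly how static asymmetry behaves;
* **noise** — i.i.d. Gaussian per frame and unit, sd default 0.01,
  modelling tracker jitter.

All randomness derives from the config seed via per-patient and
per-session streams (stable CRC hashing of the patient id), so any
subset of sessions is reproducible independently of generation order.
"Noise-free" in tests means both `noise_sd = 0` and
`rest_asymmetry_scale = 0`.

The defaults are modeling choices, not measurements: real FAU noise
spectra, resting asymmetry magnitudes, and per-patient variation in peak
excursion are unknown, and the generator produces no synkinesis, no
fatigue across repetitions, no tracking dropouts, and identical peak
excursions for all subjects. Passing tests therefore demonstrate the
correctness and monotonicity of the *assessment pipeline* under
controlled conditions, not clinical validity on real recordings.

## Problem sizes

The test suite and examples use deliberately small simulations: ReliefF
recovery runs at 200 subjects per class (400-instance binary problems),
classifier training at 60 per class (360 vectors, six classes) with
held-out evaluation at 20–30 per class, and severity sweeps over 11
noise-free points. These sizes are far past the concentration thresholds
the generator's noise level implies, so larger runs change nothing but
runtime.

## Known limitations

* The grading and symmetry stages evaluate a single peak frame; brief
  tracking glitches at the peak propagate into the report (the rest
  baseline, by contrast, is median-protected).
* The classifier is trained on simulated healthy subjects; it is a
  functional stand-in demonstrating the pipeline, not a clinically
  trained model, and its near-perfect hold-out accuracy reflects the
  generator's separability rather than real-world performance.
* The whistling delta combination and the peak-frame rule are documented
  design choices that cannot be verified against the undeposited
  clinical recordings.
* Severity acts as a single multiplicative attenuation; real palsy
  patterns differ per muscle group and include synkinesis, which is out
  of scope.
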