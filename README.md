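# fpassess

Quantitative assessment of unilateral facial paralysis (FP) from facial
animation units (FAUs) — the 17 per-frame scalar activations produced by
the Kinect v2 SDK's face tracker, each approximating a FACS action-unit
intensity. The package is aimed at rehabilitation-informatics
researchers and engineers building objective FP grading tools: it turns
a patient's recording protocol (a rest session plus five voluntary
movements — smiling, eye closure, raising eyebrows, blowing cheeks,
whistling) into a structured assessment report, and ships a synthetic
session generator so the whole pipeline runs without camera hardware.

Three assessment stages:

1. **Symmetry analysis.** For each mirrored unit pair,
   `ASI = (1 − |L − R|) × 100 %`, clamped to [0, 100]. Three facial
   areas are scored — eyes, eyebrows, mouth (the mouth index averages
   four component pairs) — statically at rest and dynamically at each
   movement's peak frame: 18 indices plus per-movement totals.
2. **Ability of movement.** A six-class probabilistic movement
   classifier (RBF-SVM with calibrated probabilities over
   movement-minus-rest difference features) plus a three-valued
   decision: *yes* if the intended movement is clearly the top class,
   *maybe* if the top two confidences are within 7 percentage points
   and the intended movement is one of them, *no* otherwise.
3. **Per-side grading.** For each movement, the direction-folded
   movement-minus-rest delta Δ of the engaged unit on each side maps to
   an integer grade: one point per completed 0.1, so
   `grade = min(10, floor(10·Δ))`, with 10/10 at a full-range change
   of 1.0 and 0 for absent or paradoxical motion — ten grades per
   patient (5 movements × 2 sides).

See `docs/methods.md` for the full model description, parameter
defaults, and design rationale.

## Worked example

```python
from fpassess import (
    GeneratorConfig, generate_patient, generate_training_dataset,
    train_movement_classifier, assess_patient, render_report,
)

model = train_movement_classifier(generate_training_dataset(40, seed=5), seed=5)
config = GeneratorConfig(seed=6, severity=0.5, affected_side="left")
report = assess_patient(generate_patient(config, "demo_patient"), model=model)
print(render_report(report, "text"))
```

prints

```
FP assessment report — patient demo_patient

Animation symmetry indices (percent)
movement            eyes  brows  mouth  total
rest                 100    100     99    100
smiling               99    100     89     96
eye_closure           59    100     99     86
raising_eyebrows      98     60     99     86
blowing_cheeks       100     98     90     96
whistling             99    100     97     99

Ability of performing the facial movements
smiling              yes   (classified as smiling)
eye_closure          yes   (classified as eye_closure)
raising_eyebrows     yes   (classified as raising_eyebrows)
blowing_cheeks       yes   (classified as blowing_cheeks)
whistling            yes   (classified as whistling)

Facial function grades (0-10, left / right)
smiling              4 / 8
eye_closure          4 / 8
raising_eyebrows     4 / 8
blowing_cheeks       4 / 8
whistling            4 / 4
```

The simulated patient has left-sided palsy at severity 0.5: the area
each movement engages loses symmetry (eyes drop to 59 % during eye
closure because the left eye closes only half as far), the affected
left side grades 4 where the healthy right side grades 8
(0.8 × (1 − 0.5) = 0.4 → 4 points), and every movement is still
*recognised* — ability answers whether the movement happened at all,
not how well it was performed. More narrative walkthroughs, one per
capability, live in `examples/`.

## Command line

```bash
fpassess simulate --patients 3 --severity 0.5 --seed 7 --out sessions.csv
fpassess train --n-per-class 60 --seed 7 --out model.joblib
fpassess assess --data sessions.csv --model model.joblib --format text
fpassess rank-features --n-per-class 100 --seed 7   # ReliefF TSV per movement
```

Exit codes: 0 success, 2 validation/schema error, 3 missing input.

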