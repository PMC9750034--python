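"""End-to-end assessment: classifier training, ability decisions, full report.

Trains the six-class movement classifier on simulated healthy subjects,
then assesses a moderately affected palsy patient. The printed report
contains 18 symmetry indices, 5 ability decisions (yes / no / maybe via
the 7-percentage-point confidence margin), and 10 per-side grades.
"""

from fpassess import (
    GeneratorConfig,
    assess_patient,
    generate_patient,
    generate_training_dataset,
    render_report,
    train_movement_classifier,
)

model = train_movement_classifier(generate_training_dataset(40, seed=5), seed=5)

config = GeneratorConfig(seed=6, severity=0.5, affected_side="left")
sessions = generate_patient(config, "demo_patient")
report = assess_patient(sessions, model=model)

print(render_report(report, "text"))
print("counts:", report.counts())
print("an ability of 'maybe' would mean the top two class confidences were")
print("within 7 percentage points with the intended movement among them.")
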