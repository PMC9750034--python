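"""Grade the five voluntary movements per facial side on the 0-10 scale.

A grade awards one point per completed 0.1 of movement-minus-rest
change of the engaged unit (direction-folded so "more movement" is
always positive), capped at 10. The affected side of a palsy patient
scores lower than the healthy side.
"""

from fpassess import GeneratorConfig, generate_patient, grade_report

config = GeneratorConfig(seed=3, severity=0.4, affected_side="left", noise_sd=0.0,
                         rest_asymmetry_scale=0.0)
report = grade_report(generate_patient(config, "demo"))

print(f"{'movement':<18}{'left':>5}{'right':>6}   deltas (L, R)")
for movement, g in report.movements.items():
    print(
        f"{movement:<18}{g.left_grade:>5}{g.right_grade:>6}   "
        f"({g.left_delta:+.3f}, {g.right_delta:+.3f})"
    )
print()
print("healthy-side grades reflect the full 0.8 peak excursion (grade 8);")
print("the affected left side reaches 0.8 x (1 - 0.4) = 0.48 -> grade 4.")
print("whistling averages the shared lip-pucker delta with each side's cheek decrease.")
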