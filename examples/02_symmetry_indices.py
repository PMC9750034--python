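"""Compute animation symmetry indices (ASIs) for one patient.

Each index is (1 - |left - right|) x 100 percent for a mirrored unit
pair, evaluated at rest (static symmetry) and at each movement's peak
frame (dynamic symmetry). The mouth index averages four component
pairs; each movement's total averages the three facial areas.
"""

from fpassess import GeneratorConfig, asi_report, generate_patient

config = GeneratorConfig(seed=2, severity=0.5, affected_side="right", noise_sd=0.0,
                         rest_asymmetry_scale=0.0)
report = asi_report(generate_patient(config, "demo"))

print(f"{'movement':<18}{'eyes':>7}{'brows':>7}{'mouth':>7}{'total':>7}")
for movement in report.movements:
    print(
        f"{movement:<18}"
        f"{report.per_area[(movement, 'eyes')]:>7.1f}"
        f"{report.per_area[(movement, 'eyebrows')]:>7.1f}"
        f"{report.per_area[(movement, 'mouth')]:>7.1f}"
        f"{report.per_movement_total[movement]:>7.1f}"
    )
print()
print("100 = perfect left/right symmetry; the area engaged by each movement")
print("drops by severity x peak excursion (here 0.5 x 0.8 = 40 points on the pair).")
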