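"""Generate synthetic FAU sessions for a unilateral-palsy patient.

Builds a left-sided palsy subject at severity 0.6, writes the sessions
to CSV, and prints the peak activation of the smiling units on each
side: the affected (left) side reaches only (1 - severity) of the
healthy side's excursion.
"""

from fpassess import GeneratorConfig, generate_patient, write_sessions

config = GeneratorConfig(seed=1, severity=0.6, affected_side="left", noise_sd=0.0,
                         rest_asymmetry_scale=0.0)
sessions = generate_patient(config, "demo_patient")
write_sessions(sessions, "demo_sessions.csv")

smiling = next(s for s in sessions if s.movement == "smiling")
peak = smiling.frames[-1]
print(f"sessions generated: {len(sessions)} (rest + 5 movements)")
print(f"peak lip corner puller  left: {peak.values['lip_corner_puller_left']:.3f}")
print(f"peak lip corner puller right: {peak.values['lip_corner_puller_right']:.3f}")
print("left/right = 1 - severity: the palsy attenuates the affected side only")
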