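"""Per-side movement grading: score rule, peak selection, deltas."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fpassess as fp
from fpassess import MOVEMENT_SPECS
from fpassess.errors import MissingInputError, ValidationError

from conftest import make_frame, make_session


class TestScoreFromDelta:
    @pytest.mark.parametrize(
        "delta,grade",
        [
            (1.0, 10),
            (0.34, 3),
            (-0.2, 0),
            (0.0, 0),
            (0.3, 3),     # 0.3 * 10 = 2.999... must still score 3
            (0.0999999, 0),
            (0.1, 1),
            (2.5, 10),    # capped
        ],
    )
    def test_one_point_per_completed_tenth(self, delta, grade):
        assert fp.score_from_delta(delta) == grade

    def test_non_decreasing_with_full_range(self):
        deltas = np.linspace(-0.5, 1.5, 401)
        grades = [fp.score_from_delta(d) for d in deltas]
        assert grades == sorted(grades)
        assert set(grades) == set(range(11))


class TestEffectiveDelta:
    def test_positive_direction(self):
        rest = make_frame(lip_corner_puller_left=0.1)
        peak = make_frame(lip_corner_puller_left=0.7)
        assert fp.effective_delta(peak, rest, "lip_corner_puller_left", +1) == (
            pytest.approx(0.6)
        )

    def test_negative_direction_folds_sign(self):
        # brow raise decreases the lowerer unit; fold makes it positive
        rest = make_frame(left_eyebrow_lowerer=0.0)
        peak = make_frame(left_eyebrow_lowerer=-0.5)
        assert fp.effective_delta(peak, rest, "left_eyebrow_lowerer", -1) == (
            pytest.approx(0.5)
        )

    def test_unknown_descriptor(self):
        f = make_frame()
        with pytest.raises(ValidationError, match="descriptor"):
            fp.effective_delta(f, f, "nose_wrinkle", +1)


class TestPeakSelection:
    def test_monotone_ramp_selects_last(self):
        rest = make_frame()
        fs = [make_frame(lip_corner_puller_left=v) for v in (0.0, 0.3, 0.6)]
        s = make_session("smiling", fs)
        assert fp.select_peak_frame(s, rest) == 2

    def test_single_frame(self):
        s = make_session("smiling", [make_frame()])
        assert fp.select_peak_frame(s, make_frame()) == 0

    def test_plateau_ties_to_first(self):
        fs = [make_frame(lip_corner_puller_left=v) for v in (0.0, 0.8, 0.8, 0.8)]
        s = make_session("smiling", fs)
        assert fp.select_peak_frame(s, make_frame()) == 1


class TestGradeMovement:
    def test_smiling_per_side(self):
        rest = make_frame(lip_corner_puller_left=0.1, lip_corner_puller_right=0.1)
        peak = make_frame(lip_corner_puller_left=0.7, lip_corner_puller_right=0.9)
        g = fp.grade_movement(make_session("smiling", [peak]), rest)
        assert (g.left_delta, g.right_delta) == (pytest.approx(0.6), pytest.approx(0.8))
        assert (g.left_grade, g.right_grade) == (6, 8)

    def test_whistling_combines_pucker_and_cheek_decrease(self):
        rest = make_frame(lip_pucker=0.0, left_cheek_puff=0.3, right_cheek_puff=0.3)
        peak = make_frame(lip_pucker=0.6, left_cheek_puff=0.1, right_cheek_puff=0.3)
        g = fp.grade_movement(make_session("whistling", [peak]), rest)
        assert g.left_delta == pytest.approx(0.4)   # mean(0.6, +0.2)
        assert g.right_delta == pytest.approx(0.3)  # mean(0.6, 0.0)
        assert (g.left_grade, g.right_grade) == (4, 3)

    def test_no_movement_grades_zero(self):
        rest = make_frame(left_cheek_puff=0.2, right_cheek_puff=0.2)
        g = fp.grade_movement(make_session("blowing_cheeks", [rest]), rest)
        assert (g.left_grade, g.right_grade) == (0, 0)

    def test_rest_session_not_gradable(self):
        with pytest.raises(ValidationError):
            fp.grade_movement(make_session("rest", [make_frame()]), make_frame())

    def test_mirror_equivariance(self):
        """Swapping all left/right units swaps the per-side grades."""
        rest = make_frame()
        peak = make_frame(left_eye_closed=0.45, right_eye_closed=0.9)
        mirrored = make_frame(left_eye_closed=0.9, right_eye_closed=0.45)
        g = fp.grade_movement(make_session("eye_closure", [peak]), rest)
        gm = fp.grade_movement(make_session("eye_closure", [mirrored]), rest)
        assert (g.left_grade, g.right_grade) == (gm.right_grade, gm.left_grade)
        assert g.left_delta == pytest.approx(gm.right_delta)


class TestGradeReport:
    def test_full_patient_yields_ten_grades(self, healthy_patient):
        report = fp.grade_report(healthy_patient)
        assert len(report.movements) == 5
        grades = [
            g for m in report.movements.values() for g in (m.left_grade, m.right_grade)
        ]
        assert len(grades) == 10
        assert all(0 <= g <= 10 for g in grades)

    def test_missing_rest_session_rejected(self, healthy_patient):
        voluntary = [s for s in healthy_patient if s.movement != "rest"]
        with pytest.raises(MissingInputError, match="rest"):
            fp.grade_report(voluntary)

    def test_healthy_sides_equal(self, healthy_patient):
        report = fp.grade_report(healthy_patient)
        for g in report.movements.values():
            assert g.left_grade == g.right_grade

    def test_complete_palsy_zeroes_affected_per_side_movements(self):
        cfg = fp.GeneratorConfig(
            seed=3, noise_sd=0.0, severity=1.0, affected_side="left",
            rest_asymmetry_scale=0.0,
        )
        report = fp.grade_report(fp.generate_patient(cfg, "p"))
        # the four strictly per-side movements lose the affected side entirely
        for movement in ("smiling", "eye_closure", "raising_eyebrows", "blowing_cheeks"):
            g = report.movements[movement]
            assert g.left_grade == 0
            assert g.right_grade == 8  # healthy side keeps the 0.8 peak delta

    def test_mirrored_blow_flips_blowing_cheeks(self):
        cfg = fp.GeneratorConfig(
            seed=3, noise_sd=0.0, severity=1.0, affected_side="left",
            rest_asymmetry_scale=0.0, mirrored_blow=True,
        )
        report = fp.grade_report(fp.generate_patient(cfg, "p"))
        g = report.movements["blowing_cheeks"]
        assert g.left_grade == 8 and g.right_grade == 0

    def test_matches_brute_force_scan_from_csv(self, tmp_path, palsy_patient):
        """Independent oracle: re-derive every grade by scanning the raw CSV."""
        path = str(tmp_path / "sessions.csv")
        fp.write_sessions(palsy_patient, path)
        report = fp.grade_report(fp.read_sessions(path))

        df = pd.read_csv(path)
        rest_rows = df[df["movement"] == "rest"]
        rest = rest_rows[list(fp.DESCRIPTORS)].median()
        for movement, spec in MOVEMENT_SPECS.items():
            rows = df[df["movement"] == movement]
            best_score, best = -np.inf, None
            for _, row in rows.sort_values("frame_index").iterrows():
                units = spec.per_side["left"] + spec.per_side["right"] + spec.shared
                score = np.mean([sgn * (row[d] - rest[d]) for d, sgn in units])
                if score > best_score:
                    best_score, best = score, row
            expected = {}
            for side in ("left", "right"):
                units = spec.per_side[side] + spec.shared
                delta = np.mean([sgn * (best[d] - rest[d]) for d, sgn in units])
                expected[side] = min(10, int(np.floor((max(delta, 0) + 1e-9) * 10)))
            g = report.movements[movement]
            assert (g.left_grade, g.right_grade) == (
                expected["left"],
                expected["right"],
            )
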