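"""Movement classifier, confidence vectors, and the ability decision."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import fpassess as fp
from fpassess import MOVEMENTS, VOLUNTARY_MOVEMENTS
from fpassess.classify import ConfidenceVector
from fpassess.errors import MissingInputError, ValidationError

from conftest import make_frame, make_session


def confidence(**probs) -> ConfidenceVector:
    """Confidence vector with the residual mass spread over absent labels."""
    rest = [m for m in MOVEMENTS if m not in probs]
    residual = 1.0 - sum(probs.values())
    full = dict(probs)
    for m in rest:
        full[m] = residual / len(rest)
    return ConfidenceVector(probs=full)


class TestConfidenceVector:
    def test_must_sum_to_one(self):
        probs = {m: 0.2 for m in MOVEMENTS}
        with pytest.raises(ValidationError, match="sum"):
            ConfidenceVector(probs=probs)

    def test_top_two_tie_break_canonical(self):
        cv = confidence(smiling=0.3, whistling=0.3, rest=0.3)
        (m1, _), (m2, _) = cv.top_two()
        assert (m1, m2) == ("rest", "smiling")  # canonical label order


class TestAbilityDecision:
    def test_worked_example_forty_vs_fortysix(self):
        """40% smiling vs 46% eye closure: 'maybe' for both, 'no' elsewhere."""
        cv = confidence(smiling=0.40, eye_closure=0.46)
        assert fp.ability_decision(cv, "smiling") == "maybe"
        assert fp.ability_decision(cv, "eye_closure") == "maybe"
        for other in ("raising_eyebrows", "blowing_cheeks", "whistling"):
            assert fp.ability_decision(cv, other) == "no"

    def test_residual_split_does_not_matter(self):
        for split in ([0.14, 0, 0, 0], [0.05, 0.05, 0.02, 0.02]):
            probs = {
                "smiling": 0.40,
                "eye_closure": 0.46,
                "raising_eyebrows": split[0],
                "blowing_cheeks": split[1],
                "whistling": split[2],
                "rest": split[3],
            }
            cv = ConfidenceVector(probs=probs)
            assert fp.ability_decision(cv, "smiling") == "maybe"

    def test_certain_intended_is_yes(self):
        cv = confidence(smiling=1.0)
        assert fp.ability_decision(cv, "smiling") == "yes"

    def test_gap_exactly_at_margin_is_definite(self):
        # "just less than 7%": a 7-point gap is no longer ambiguous
        cv = confidence(smiling=0.47, eye_closure=0.40)
        assert fp.ability_decision(cv, "smiling") == "yes"
        assert fp.ability_decision(cv, "eye_closure") == "no"

    def test_uniform_confidence_is_maybe_for_top_two(self):
        cv = ConfidenceVector(probs={m: 1 / 6 for m in MOVEMENTS})
        (m1, _), (m2, _) = cv.top_two()
        assert fp.ability_decision(cv, m1) == "maybe"
        assert fp.ability_decision(cv, m2) == "maybe"

    def test_invalid_intended_rejected(self):
        with pytest.raises(ValidationError, match="intended"):
            fp.ability_decision(confidence(smiling=1.0), "shrug")

    def test_margin_one_everything_in_top_two_is_maybe(self):
        cv = confidence(smiling=0.6, whistling=0.3)
        assert fp.ability_decision(cv, "smiling", margin=1.0) == "maybe"
        assert fp.ability_decision(cv, "whistling", margin=1.0) == "maybe"
        assert fp.ability_decision(cv, "rest", margin=1.0) == "no"

    def test_margin_zero_eliminates_maybe_except_exact_ties(self):
        cv = confidence(smiling=0.5, whistling=0.45)
        assert fp.ability_decision(cv, "smiling", margin=0.0) == "yes"
        assert fp.ability_decision(cv, "whistling", margin=0.0) == "no"

    def test_partition_total_and_disjoint_on_probability_grid(self):
        """Every simplex point maps to exactly one of yes/no/maybe."""
        grid = [g / 10 for g in range(11)]
        labels = ("smiling", "eye_closure", "whistling")
        for p in itertools.product(grid, repeat=2):
            if sum(p) > 1:
                continue
            probs = {
                "smiling": p[0],
                "eye_closure": p[1],
                "whistling": round(1 - sum(p), 10),
            }
            cv = confidence(**{k: v for k, v in probs.items()})
            for intended in labels:
                assert fp.ability_decision(cv, intended) in ("yes", "no", "maybe")


class TestFeatureVector:
    def test_rest_session_vs_own_baseline_is_zero(self):
        frame = make_frame(left_cheek_puff=0.2, right_cheek_puff=0.2)
        session = make_session("rest", [frame, frame])
        rest = fp.rest_baseline(session)
        vec = fp.build_feature_vector(session, rest)
        assert vec == pytest.approx(np.zeros(9))

    def test_difference_lands_in_named_slot(self):
        rest = make_frame(lip_corner_puller_left=0.1)
        peak = make_frame(lip_corner_puller_left=0.7)
        session = make_session("smiling", [peak])
        vec = fp.build_feature_vector(session, rest)
        slot = fp.DEFAULT_SELECTED_FEATURES.index("lip_corner_puller_left")
        assert vec[slot] == pytest.approx(0.6)
        assert np.count_nonzero(vec) == 1

    def test_invariant_to_frame_permutation_with_clear_peak(self):
        rest = make_frame()
        fs = [make_frame(left_eye_closed=v) for v in (0.0, 0.4, 0.9)]
        v1 = fp.build_feature_vector(make_session("eye_closure", fs), rest)
        v2 = fp.build_feature_vector(make_session("eye_closure", fs[::-1]), rest)
        assert v1 == pytest.approx(v2)


class TestTraining:
    @pytest.fixture(scope="class")
    @staticmethod
    def model():
        data = fp.generate_training_dataset(60, seed=42)
        return fp.train_movement_classifier(data, seed=42)

    def test_holdout_accuracy(self, model):
        test = fp.generate_training_dataset(20, seed=1042)
        idx = [fp.DESCRIPTORS.index(d) for d in model.selected]
        X = np.stack([s.as_array()[idx] for s in test])
        y = np.array([s.label for s in test])
        acc = np.mean(model.pipeline.predict(X) == y)
        assert acc >= 0.90

    def test_training_deterministic(self, model):
        data = fp.generate_training_dataset(60, seed=42)
        again = fp.train_movement_classifier(data, seed=42)
        probe = fp.generate_training_dataset(5, seed=9)
        for s in probe:
            idx = [fp.DESCRIPTORS.index(d) for d in model.selected]
            x = s.as_array()[idx]
            assert model.predict_confidence(x).probs == pytest.approx(
                again.predict_confidence(x).probs, abs=0
            )

    def test_model_round_trip(self, model, tmp_path):
        path = str(tmp_path / "model.joblib")
        model.save(path)
        loaded = fp.MovementClassifier.load(path)
        assert loaded.selected == model.selected
        probe = fp.generate_training_dataset(3, seed=8)
        idx = [fp.DESCRIPTORS.index(d) for d in model.selected]
        for s in probe:
            x = s.as_array()[idx]
            assert loaded.predict_confidence(x).probs == model.predict_confidence(x).probs

    def test_missing_class_rejected(self):
        data = [
            s for s in fp.generate_training_dataset(10, seed=2)
            if s.label != "whistling"
        ]
        with pytest.raises(ValidationError, match="whistling"):
            fp.train_movement_classifier(data, seed=2)

    def test_healthy_patient_all_yes(self, model):
        cfg = fp.GeneratorConfig(seed=77, noise_sd=0.0, severity=0.0)
        sessions = fp.generate_patient(cfg, "p")
        rest = fp.rest_baseline([s for s in sessions if s.movement == "rest"][0])
        voluntary = [s for s in sessions if s.movement != "rest"]
        results = fp.ability_report(voluntary, model, rest)
        assert len(results) == 5
        assert all(r.decision == "yes" for r in results.values())
        for m in VOLUNTARY_MOVEMENTS:
            assert results[m].predicted == m

    def test_ability_report_requires_model(self, healthy_patient):
        rest = fp.rest_baseline(
            [s for s in healthy_patient if s.movement == "rest"][0]
        )
        with pytest.raises(MissingInputError, match="model|classifier"):
            fp.ability_report(healthy_patient, None, rest)
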