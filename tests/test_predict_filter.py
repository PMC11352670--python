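"""Predictor backends and the safety/consensus/energy filter cascade."""

import pandas as pd
import pytest

from pepscreen import (
    ConsensusPolicy,
    CompositionHeuristicPredictor,
    PoseEnergy,
    SafetyVerdict,
    SeededRandomPredictor,
    TableBackedPredictor,
    Thresholds,
    apply_safety_filters,
    consensus_bioactivity,
    filter_poses_by_energy,
    predict_bioactivity,
    score_threshold_gate,
)
from pepscreen.datasets import reported_poses
from pepscreen.errors import InputError, PredictionError
from pepscreen.predictors import BIOACTIVITY_CLASSES


def passing_verdict(seq, **overrides):
    base = dict(
        sequence=seq,
        toxic=False,
        bitterness_score=100.0,
        plasma_half_life_s=1000.0,
        intestinal_half_life_s=5.0,
    )
    base.update(overrides)
    return SafetyVerdict(**base)


class TestPredictors:
    def test_table_backed_returns_exact_table_calls(self):
        rows = []
        for seq, pos in [("AAAAA", "ACP"), ("CCCCC", "AMP"), ("DDDDD", None)]:
            for cls in BIOACTIVITY_CLASSES:
                rows.append(
                    {"sequence": seq, "class": cls,
                     "score": float(cls == pos), "call": int(cls == pos)}
                )
        predictor = TableBackedPredictor(pd.DataFrame(rows))
        preds = predict_bioactivity(["AAAAA", "CCCCC", "DDDDD"], predictor)
        assert preds[0].positive_classes == ("ACP",)
        assert preds[1].positive_classes == ("AMP",)
        assert preds[2].positive_classes == ()

    def test_table_backed_strict_raises_on_missing_key(self):
        predictor = TableBackedPredictor(
            pd.DataFrame(
                [{"sequence": "AAAAA", "class": "ACP", "score": 1.0, "call": 1}]
            )
        )
        with pytest.raises(PredictionError, match="no table entry"):
            predictor.predict(["GGGGG"])

    def test_table_backed_default_negative_mode(self):
        predictor = TableBackedPredictor(
            pd.DataFrame(
                [{"sequence": "AAAAA", "class": "ACP", "score": 1.0, "call": 1}]
            ),
            strict=False,
        )
        (pred,) = predictor.predict(["GGGGG"])
        assert pred.positive_classes == ()

    def test_seeded_random_is_deterministic_and_order_free(self):
        a = SeededRandomPredictor(42).predict(["AAAAA", "CCCCC"])
        b = SeededRandomPredictor(42).predict(["CCCCC", "AAAAA"])
        assert a[0].scores == b[1].scores
        assert SeededRandomPredictor(43).predict(["AAAAA"])[0].scores != a[0].scores

    def test_seeded_random_calls_consistent_with_scores(self):
        predictor = SeededRandomPredictor(7, positive_rate=0.3)
        for pred in predictor.predict([f"PEP{i}AAAA" for i in range(50)]):
            for cls in BIOACTIVITY_CLASSES:
                assert pred.calls[cls] == (pred.scores[cls] >= 0.7)

    def test_heuristic_supports_multilabel(self):
        # cationic + hydrophobic: positive for both ACP and AMP
        (pred,) = CompositionHeuristicPredictor().predict(["KKKKKLLLLL"])
        assert "ACP" in pred.positive_classes and "AMP" in pred.positive_classes

    def test_totality_enforced(self):
        class Lossy:
            name = "lossy"
            version = "0"

            def predict(self, peptides):
                return []

        with pytest.raises(PredictionError, match="returned 0 predictions"):
            predict_bioactivity(["AAAAA"], Lossy())


class TestSafetyCascade:
    def test_bitterness_boundary(self):
        verdicts = {
            "A" * 5: passing_verdict("A" * 5, bitterness_score=333.0),
            "C" * 5: passing_verdict("C" * 5, bitterness_score=334.0),
        }
        kept, audit = apply_safety_filters(list(verdicts), verdicts)
        assert kept == ["A" * 5]  # 333 retained, strictly above excluded
        assert audit[1].failed_at == "bitterness"

    def test_plasma_boundary_inclusive(self):
        verdicts = {
            "A" * 5: passing_verdict("A" * 5, plasma_half_life_s=800.0),
            "C" * 5: passing_verdict("C" * 5, plasma_half_life_s=799.99),
        }
        kept, audit = apply_safety_filters(list(verdicts), verdicts)
        assert kept == ["A" * 5]
        assert audit[1].failed_at == "plasma"

    def test_intestinal_boundary_strict(self):
        verdicts = {
            "A" * 5: passing_verdict("A" * 5, intestinal_half_life_s=1.5),
            "C" * 5: passing_verdict("C" * 5, intestinal_half_life_s=1.0),
        }
        kept, audit = apply_safety_filters(list(verdicts), verdicts)
        assert kept == ["A" * 5]  # exactly 1.0 s is not "greater than 1.0 s"
        assert audit[1].failed_at == "intestinal"

    def test_toxicity_is_first_gate_in_audit(self):
        v = passing_verdict("AAAAA", toxic=True, bitterness_score=999.0)
        kept, audit = apply_safety_filters(["AAAAA"], {"AAAAA": v})
        assert kept == []
        assert audit[0].failed_at == "toxicity"

    def test_all_passing_is_identity_and_idempotent(self):
        peptides = ["AAAAA", "CCCCC", "GGGGG"]
        verdicts = {p: passing_verdict(p) for p in peptides}
        kept, audit = apply_safety_filters(peptides, verdicts)
        assert kept == peptides
        assert all(a.retained and a.failed_at is None for a in audit)
        again, _ = apply_safety_filters(kept, verdicts)
        assert again == kept

    def test_survivors_are_subset(self):
        peptides = ["AAAAA", "CCCCC"]
        verdicts = {
            "AAAAA": passing_verdict("AAAAA"),
            "CCCCC": passing_verdict("CCCCC", toxic=True),
        }
        kept, _ = apply_safety_filters(peptides, verdicts)
        assert set(kept) <= set(peptides)

    def test_missing_verdict_rejected(self):
        with pytest.raises(InputError, match="no safety verdict"):
            apply_safety_filters(["AAAAA"], {})

    def test_negative_half_life_rejected(self):
        with pytest.raises(InputError):
            passing_verdict("AAAAA", plasma_half_life_s=-1.0)


class TestConsensus:
    policy = ConsensusPolicy("ACP", ("ACPred", "MLACP2", "ACPPfel"))

    def test_all_positive_rule(self):
        calls = {"ACPred": True, "MLACP2": True, "ACPPfel": True}
        assert consensus_bioactivity("AAAAA", calls, self.policy)

    def test_two_of_three_fails_all_positive(self):
        calls = {"ACPred": True, "MLACP2": True, "ACPPfel": False}
        assert not consensus_bioactivity("AAAAA", calls, self.policy)

    def test_m_of_n_generalization(self):
        policy = ConsensusPolicy("ACP", ("ACPred", "MLACP2", "ACPPfel"), m=2)
        calls = {"ACPred": True, "MLACP2": True, "ACPPfel": False}
        assert consensus_bioactivity("AAAAA", calls, policy)

    def test_unknown_and_missing_platforms_rejected(self):
        with pytest.raises(InputError, match="unknown platforms"):
            consensus_bioactivity("AAAAA", {"Other": True}, self.policy)
        with pytest.raises(InputError, match="missing platform"):
            consensus_bioactivity("AAAAA", {"ACPred": True}, self.policy)

    def test_invalid_policy(self):
        with pytest.raises(InputError):
            ConsensusPolicy("ACP", ())
        with pytest.raises(InputError):
            ConsensusPolicy("ACP", ("a", "b"), m=3)


class TestScoreGate:
    def test_strictly_greater(self):
        assert score_threshold_gate({"ADP": 301.0}, "ADP", 300.0)
        assert not score_threshold_gate({"AHP": 1.0}, "AHP", 1.0)

    def test_greater_or_equal_configuration(self):
        assert score_threshold_gate({"AHP": 1.0}, "AHP", 1.0, "greater-or-equal")

    def test_less_direction(self):
        assert score_threshold_gate({"ACP": 0.2}, "ACP", 0.5, "less")

    def test_missing_score_and_bad_direction(self):
        with pytest.raises(InputError):
            score_threshold_gate({}, "ACP", 0.5)
        with pytest.raises(InputError):
            score_threshold_gate({"ACP": 1.0}, "ACP", 0.5, "sideways")


class TestPoseEnergy:
    def test_boundary_inclusive_at_cutoff(self):
        poses = [
            PoseEnergy("AAAAA", "T", 1, -30.0),
            PoseEnergy("CCCCC", "T", 1, -29.9),
        ]
        kept = filter_poses_by_energy(poses)
        assert [p.sequence for p in kept] == ["AAAAA"]

    def test_sorted_ascending_with_stable_ties(self):
        poses = [
            PoseEnergy("B" * 5, "T", 2, -31.0),
            PoseEnergy("A" * 5, "T", 1, -45.0),
            PoseEnergy("B" * 5, "T", 1, -31.0),
        ]
        kept = filter_poses_by_energy(poses)
        assert [p.energy_mean for p in kept] == sorted(p.energy_mean for p in kept)
        assert [(p.sequence, p.pose) for p in kept] == [
            ("AAAAA", 1), ("BBBBB", 1), ("BBBBB", 2)
        ]

    def test_all_outputs_at_or_below_cutoff(self):
        kept = filter_poses_by_energy(reported_poses(), -35.0)
        assert kept and all(p.energy_mean <= -35.0 for p in kept)

    def test_published_boundary_row_survives(self):
        kept = filter_poses_by_energy(reported_poses())
        by_seq = {p.sequence for p in kept}
        assert "EMIWDLLVS" in by_seq  # mean -30.7 sits inside the cutoff

    def test_negative_sd_rejected(self):
        with pytest.raises(InputError):
            PoseEnergy("AAAAA", "T", 1, -40.0, energy_sd=-1.0)
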