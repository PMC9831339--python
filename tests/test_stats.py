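import numpy as np
import pandas as pd
import pytest

import beadtask as bt
from beadtask._utils import inv_logit
from beadtask.cohort import AgentSpec, simulate_participant
from beadtask.data import ParticipantData
from beadtask.stats import (
    behavioral_summary,
    cliffs_delta,
    evidence_asymmetry_slope,
    final_estimate_difference,
    partial_spearman,
    prior_dependent_slope,
    ranksum_test,
    response_variance,
    signrank_test,
    spearman,
)

from conftest import make_participant


class TestFinalEstimateDifference:
    def test_ideal_observer_all_zero(self, ideal_participant):
        pairs, mean = final_estimate_difference(ideal_participant)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(pairs["difference"], 0.0, atol=1e-12)

    def test_neglecter_positive_differences(self, neglect_participant):
        pairs, mean = final_estimate_difference(neglect_participant)
        assert mean > 0
        nz = pairs["abs_asymmetry"] > 0
        assert (pairs.loc[nz, "difference"] > 0).all()

    def test_wrong_choice_pairs_dropped(self, neglect_participant):
        data = neglect_participant
        full_pairs, _ = final_estimate_difference(data)
        flags = data.choice_correct.copy()
        flags[:10] = False
        data2 = ParticipantData(
            data.participant_id, data.beads, data.ratios, data.estimates, flags,
            majority_color=data.majority_color, pair_id=data.pair_id,
            evidence_asymmetry=data.evidence_asymmetry, is_repeated=data.is_repeated,
        )
        reduced_pairs, _ = final_estimate_difference(data2)
        assert len(reduced_pairs) < len(full_pairs)


class TestEvidenceAsymmetrySlope:
    def test_ideal_zero_slope(self, ideal_participant):
        pairs, _ = final_estimate_difference(ideal_participant)
        assert evidence_asymmetry_slope(pairs) == pytest.approx(0.0, abs=1e-12)

    def test_neglecter_positive_slope(self, neglect_participant):
        pairs, _ = final_estimate_difference(neglect_participant)
        assert evidence_asymmetry_slope(pairs) > 0

    def test_translation_invariance(self, neglect_participant):
        pairs, _ = final_estimate_difference(neglect_participant)
        shifted = pairs.copy()
        shifted["difference"] += 0.17
        assert evidence_asymmetry_slope(shifted) == pytest.approx(evidence_asymmetry_slope(pairs), abs=1e-10)

    def test_insufficient_points_missing(self):
        assert np.isnan(evidence_asymmetry_slope(pd.DataFrame(columns=["abs_asymmetry", "difference"])))


class TestPriorDependentSlope:
    def test_ideal_zero(self, ideal_participant):
        assert prior_dependent_slope(ideal_participant) == pytest.approx(0.0, abs=1e-9)

    def test_underweighting_negative(self, neglect_participant):
        assert prior_dependent_slope(neglect_participant) < 0

    def test_overweighting_positive(self, design):
        over = make_participant(design, "weighted_bayes", bt.WeightedBayesParams(1.15, 0.8))
        assert prior_dependent_slope(over) > 0

    def test_by_condition_signs(self, neglect_participant):
        per = prior_dependent_slope(neglect_participant, by_condition=True)
        assert set(per) <= {"51:49", "60:40", "90:10"}
        assert all(v < 0 for v in per.values() if np.isfinite(v))


class TestResponseVariance:
    def _fragment_data(self, logits_by_trial):
        """Three trials with identical displayed beads whose estimates differ
        by a fixed offset per trial, so every fragment variance is the
        variance of the offsets."""
        n = len(logits_by_trial)
        beads = np.tile([1, 1, 0, 1, 1, 1, 1, 0], (n, 1))
        est = np.array([[0.5] + list(inv_logit(np.full(8, l))) for l in logits_by_trial])
        return ParticipantData(
            0, beads, np.array(["60:40"] * n, dtype=object), est, np.ones(n, dtype=bool),
            majority_color=np.array(["blue"] * n, dtype=object),
        )

    def test_hand_computed_variance(self):
        data = self._fragment_data([0.4, 0.5, 0.6])
        assert response_variance(data) == pytest.approx(0.01, abs=1e-12)

    def test_deterministic_agent_zero(self, neglect_participant):
        assert response_variance(neglect_participant) == 0.0

    def test_min_instances_enforced(self):
        data = self._fragment_data([0.4, 0.6])
        assert np.isnan(response_variance(data))

    def test_color_relabeling_invariance(self, design, neglect_params):
        agent = AgentSpec("weighted_bayes", neglect_params, 0.5, 0.0)
        frame = simulate_participant(design, agent, np.random.default_rng(8))
        base = response_variance(ParticipantData.from_frame(frame))
        flipped = frame.copy()
        flipped["majority_color"] = flipped["majority_color"].map({"blue": "green", "green": "blue"})
        assert response_variance(ParticipantData.from_frame(flipped)) == pytest.approx(base, abs=1e-12)


class TestBehavioralSummary:
    def test_all_measures_finite_for_noisy_agent(self, design, neglect_params):
        noisy = make_participant(design, "weighted_bayes", neglect_params, late_noise_sd=0.4, seed=3)
        summary = behavioral_summary(noisy)
        assert set(summary) == {
            "mean_final_estimate_difference",
            "evidence_asymmetry_slope",
            "prior_dependent_slope",
            "response_variance",
        }
        assert all(np.isfinite(v) for v in summary.values())


class TestNonparametrics:
    def test_cliffs_delta_extremes(self):
        assert cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0
        x = np.arange(50)
        assert cliffs_delta(x, np.random.default_rng(0).permutation(x)) == 0.0

    def test_signrank_and_ranksum_detect_shifts(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1.0, 80)
        _, p_sign = signrank_test(x, 0.0)
        assert p_sign < 0.01
        _, p_rank = ranksum_test(x, rng.normal(0.0, 1.0, 80))
        assert p_rank < 0.05
        _, p_null = signrank_test(np.zeros(10), 0.0)
        assert p_null == 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            signrank_test([])
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    def test_partial_spearman_with_independent_covariate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        Z = rng.normal(size=(500, 2))
        rho_raw, _ = spearman(x, y)
        rho_part, _ = partial_spearman(x, y, Z)
        assert rho_part == pytest.approx(rho_raw, abs=0.05)

    def test_partial_spearman_removes_common_cause(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=600)
        x = z + 0.5 * rng.normal(size=600)
        y = z + 0.5 * rng.normal(size=600)
        rho_raw, _ = spearman(x, y)
        rho_part, p = partial_spearman(x, y, z)
        assert rho_raw > 0.5
        assert abs(rho_part) < 0.2
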