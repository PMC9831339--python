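import numpy as np
import pytest

import beadtask as bt
from beadtask.cohort import (
    AgentSpec,
    CohortSpec,
    _copula_scores,
    _sample_agents,
    choice_score,
    expected_payout,
    generate_cohort,
    simulate_participant,
)
from beadtask.data import ParticipantData
from beadtask.stats import cliffs_delta, response_variance, spearman


class TestSimulateParticipant:
    def test_ideal_matches_closed_form(self, design):
        frame = simulate_participant(
            design, AgentSpec("ideal", bt.WeightedBayesParams.ideal(), 0.0, 0.0), np.random.default_rng(0)
        )
        ideal = bt.WeightedBayesParams.ideal()
        for _, row in frame.iterrows():
            seq = design.trials[int(row["trial_index"])]
            expected = bt.simulate_trajectory(seq, ideal).estimates
            got = [row[f"estimate_{d}"] for d in range(9)]
            assert np.allclose(got, expected)

    def test_determinism_under_seed(self, design, neglect_params):
        agent = AgentSpec("weighted_bayes", neglect_params, 0.4, 0.015)
        a = simulate_participant(design, agent, np.random.default_rng(5))
        b = simulate_participant(design, agent, np.random.default_rng(5))
        assert a.equals(b)

    def test_neglecter_shows_positive_pair_differences(self, design, neglect_params):
        from beadtask.stats import final_estimate_difference

        frame = simulate_participant(
            design, AgentSpec("weighted_bayes", neglect_params, 0.0, 0.0), np.random.default_rng(0)
        )
        pairs, mean = final_estimate_difference(ParticipantData.from_frame(frame))
        assert mean > 0
        assert (pairs.loc[pairs["abs_asymmetry"] > 0, "difference"] > 0).all()

    def test_late_noise_increases_response_variance(self, design, neglect_params):
        out = {}
        for sd in (0.2, 0.6):
            vals = []
            for rep in range(6):
                agent = AgentSpec("weighted_bayes", neglect_params, sd, 0.0)
                frame = simulate_participant(design, agent, np.random.default_rng(100 + rep))
                vals.append(response_variance(ParticipantData.from_frame(frame)))
            out[sd] = np.mean(vals)
        assert out[0.6] > out[0.2] > 0

    def test_response_variance_tracks_late_noise_variance(self, design, neglect_params):
        """Fragment-matched response variance is proportional to the late
        noise variance (the attenuation factor ~0.83 reflects the median
        over small-sample fragment variances)."""
        sd = 0.5
        vals = []
        for rep in range(12):
            agent = AgentSpec("weighted_bayes", neglect_params, sd, 0.0)
            frame = simulate_participant(design, agent, np.random.default_rng(rep))
            vals.append(response_variance(ParticipantData.from_frame(frame)))
        ratio = np.mean(vals) / sd**2
        assert 0.6 < ratio < 1.05

    def test_invalid_agent_rejected(self):
        with pytest.raises(ValueError):
            AgentSpec("telepathy", None)
        with pytest.raises(ValueError):
            AgentSpec("ideal", bt.WeightedBayesParams.ideal(), late_noise_sd=-0.1)


class TestGenerateCohort:
    def test_shapes_and_determinism(self):
        spec = CohortSpec(n_participants=5, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert len(a.participants) == 5
        assert len(a.trials) == 5 * 55
        assert a.trials.equals(b.trials) and a.participants.equals(b.participants)

    def test_copula_hits_target_spearman(self):
        rng = np.random.default_rng(3)
        anchor = rng.normal(size=500)
        from scipy import stats as sps

        vals = _copula_scores(rng, anchor, -0.25, lambda q: sps.expon.ppf(q, scale=55.0))
        rho, _ = spearman(anchor, vals)
        assert rho == pytest.approx(-0.25, abs=0.08)
        vals0 = _copula_scores(rng, anchor, 0.0, lambda q: sps.expon.ppf(q, scale=55.0))
        rho0, _ = spearman(anchor, vals0)
        assert abs(rho0) < 0.1

    def test_cohort_pdi_correlates_with_omega1(self):
        cohort = generate_cohort(CohortSpec(n_participants=150, seed=4, pdi_spearman=-0.4))
        rho, _ = spearman(cohort.participants["omega1"], cohort.participants["pdi"])
        assert rho < -0.15

    def test_two_group_spec_recovers_cliffs_delta(self):
        agents, truth = _sample_agents(
            CohortSpec(
                n_participants=400,
                groups={"n_low": 200, "n_high": 200, "omega1_shift": 0.044},
            ),
            np.random.default_rng(0),
        )
        omega1 = np.array([t["omega1"] for t in truth])
        delta = cliffs_delta(omega1[200:], omega1[:200])  # low vs high group
        assert delta == pytest.approx(0.30, abs=0.12)

    def test_group_sizes_validated(self):
        with pytest.raises(ValueError):
            CohortSpec(n_participants=10, groups={"n_low": 3, "n_high": 3})

    def test_noisy_cohort_carries_mapped_weights(self):
        cohort = generate_cohort(CohortSpec(n_participants=4, agent_type="noisy_sampling", seed=1, late_noise_sd=0.0))
        p = cohort.participants
        assert {"sigma2_prior", "omega1"} <= set(p.columns)
        assert (p["omega1"] < 1).all() and (p["omega1"] > 0).all()


class TestBinarizedScore:
    def test_perfect_estimate_never_loses(self):
        rng = np.random.default_rng(0)
        assert all(bt.binarized_score(0.7, 0.7, rng) == 0.0 for _ in range(1000))

    def test_loss_frequency_matches_squared_error(self):
        rng = np.random.default_rng(1)
        e = 0.3
        losses = sum(bt.binarized_score(0.9, 0.9 - e, rng) < 0 for _ in range(100_000))
        assert losses / 100_000 == pytest.approx(e**2, rel=0.05)

    def test_expected_payout_maximized_at_objective(self):
        objective = 0.73
        grid = np.linspace(0, 1, 101)
        payoffs = [expected_payout(g, objective) for g in grid]
        assert grid[int(np.argmax(payoffs))] == pytest.approx(objective, abs=0.005)
        assert max(payoffs) == 0.0

    def test_choice_score(self):
        assert choice_score(True) == 0.0 and choice_score(False) == -5.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            bt.binarized_score(1.2, 0.5, np.random.default_rng(0))
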