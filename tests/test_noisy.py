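import numpy as np
import pytest

import beadtask as bt
from beadtask.cohort import AgentSpec, simulate_participant
from beadtask.data import CohortDataset, ParticipantData
from beadtask.design import RATIO_LABELS
from beadtask.noisy import (
    DEFAULT_W2,
    NoisySamplingModel,
    logistic_gaussian_integral,
    weight_decomposition,
)


class TestWeightDecomposition:
    def test_noiseless_is_ideal(self):
        wd = weight_decomposition(0.0, 0.2)
        assert (wd.gamma, wd.Sigma2, wd.rho, wd.weight, wd.eps_var) == (1.0, 0.0, 1.0, 1.0, 0.0)
        wd0 = weight_decomposition(0.0, 0.0)
        assert wd0.weight == 1.0 and wd0.eps_var == 0.0

    def test_worked_example(self):
        wd = weight_decomposition(0.2, 0.2)
        assert wd.gamma == pytest.approx(0.5)
        assert wd.Sigma2 == pytest.approx(0.1)
        assert wd.rho == pytest.approx(1.0304, abs=1e-4)
        assert wd.weight == pytest.approx(0.4853, abs=1e-4)
        assert wd.eps_var == pytest.approx(0.0471, abs=1e-4)

    def test_monotonicity_in_noise(self):
        sig = np.linspace(0.01, 2.0, 30)
        w = [weight_decomposition(s, 0.4).weight for s in sig]
        assert all(a > b for a, b in zip(w, w[1:]))
        assert weight_decomposition(1e6, 0.4).weight < 1e-5
        # transmitted response noise grows with representation noise while
        # the prior is still partially trusted (sigma2 well below omega2);
        # near sigma2 ~ omega2 the optimal discounting gamma -> 0 takes over
        # and shrinks it again
        sig_low = np.linspace(0.01, 0.3, 15)
        e = [weight_decomposition(s, 0.4).eps_var for s in sig_low]
        assert all(a < b for a, b in zip(e, e[1:]))

    def test_invariant_ranges(self):
        for s2 in (0.0, 0.1, 1.0, 5.0):
            for w2 in (0.0, 0.2, 1.4):
                wd = weight_decomposition(s2, w2)
                assert 0 <= wd.gamma <= 1
                assert wd.Sigma2 <= min(w2, s2) + 1e-12
                assert wd.rho >= 1
                assert 0 <= wd.weight <= 1

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            weight_decomposition(-0.1, 0.2)

    @pytest.mark.parametrize("rho_form", ["linear", "sqrt"])
    def test_rho_approximates_logistic_gaussian_integral(self, rho_form):
        """Both correction forms track logit E[logistic(z)] over the
        relevant variance range; the integral is the independent oracle."""
        for m in (0.3, 1.0, 2.0):
            for s2, w2 in ((0.1, 0.2), (0.2, 0.2), (0.5, 0.6)):
                wd = weight_decomposition(s2, w2, rho_form=rho_form)
                exact = logistic_gaussian_integral(wd.gamma * m, wd.Sigma2)
                approx_logit = wd.gamma * m / wd.rho
                exact_logit = np.log(exact / (1 - exact))
                assert approx_logit == pytest.approx(exact_logit, rel=0.07)


class TestNoisyPosterior:
    def test_zero_noise_reduces_to_ideal(self):
        p = bt.NoisySamplingParams(0.0, {l: 0.0 for l in RATIO_LABELS})
        mean, sampled = bt.noisy_posterior(0.3, +1, "60:40", p, np.random.default_rng(0))
        ideal = bt.update_belief(0.3, +1, "60:40", bt.WeightedBayesParams.ideal())
        assert mean == sampled == pytest.approx(ideal, abs=1e-15)

    def test_mean_is_weighted_bayes_update_bit_identical(self):
        p = bt.NoisySamplingParams(0.15, {"51:49": 0.05, "60:40": 0.2, "90:10": 0.7})
        wb = p.to_weighted_bayes()
        for prior in (-2.0, 0.0, 1.3):
            for bead in (+1, -1):
                mean, _ = bt.noisy_posterior(prior, bead, "90:10", p, np.random.default_rng(0))
                assert mean == bt.update_belief(prior, bead, "90:10", wb)

    def test_sampled_variance_matches_eps_var(self):
        p = bt.NoisySamplingParams(0.3, {"51:49": 0.1, "60:40": 0.25, "90:10": 0.6})
        rng = np.random.default_rng(11)
        draws = np.array([bt.noisy_posterior(0.5, +1, "60:40", p, rng)[1] for _ in range(100_000)])
        assert np.var(draws) == pytest.approx(p.eps_var("60:40"), rel=0.02)


class TestNoisySamplingFit:
    def test_ideal_participant_recovers_zero_noise(self, ideal_participant):
        fit = NoisySamplingModel(ideal_participant).fit(n_restarts=6, rng=0)
        assert fit.params.sigma2_prior == pytest.approx(0.0, abs=1e-3)
        assert fit.rmse < 1e-3

    def test_mean_prediction_equivalence(self, neglect_participant):
        """The objective at theta equals the weighted-Bayes RMSE at the
        mapped weights (the structural reduction used throughout)."""
        from beadtask.data import predict_weighted_bayes

        model = NoisySamplingModel(neglect_participant)
        theta = np.array([0.2, 0.1, 0.2, 0.6])
        mapped = model._params(theta).to_weighted_bayes()
        pred = predict_weighted_bayes(model.data, mapped.omega1, mapped.omega2)
        manual = float(np.sqrt(np.mean((pred - model.data.reported) ** 2)))
        assert model.rmse(theta) == manual

    def test_grid_search_selects_lowest_group_bic(self, design, neglect_params):
        frames = []
        for pid in range(2):
            agent = AgentSpec("weighted_bayes", neglect_params, 0.1, 0.0)
            frames.append(simulate_participant(design, agent, np.random.default_rng(pid), pid))
        import pandas as pd

        cohort = CohortDataset(
            pd.concat(frames, ignore_index=True),
            pd.DataFrame({"participant_id": [0, 1]}),
        )
        fits, w2, table = bt.fit_noisy_sampling(cohort, w2_grid=[0.2, 0.6], n_restarts=3, rng=0)
        assert len(table) == 16  # 2^4 grid points
        best_row = table.loc[table["group_bic"].idxmin()]
        assert w2 == {k.replace("w2_", ""): best_row[k] for k in table.columns if k.startswith("w2_")}
        assert set(fits) == {0, 1}

    def test_degenerate_grid_selects_single_point(self, ideal_participant):
        import pandas as pd

        # single-point grid: the fixed study values are selected trivially
        frame_cohort = CohortDataset(
            _as_frame(ideal_participant), pd.DataFrame({"participant_id": [0]})
        )
        fits, w2, table = bt.fit_noisy_sampling(frame_cohort, w2_grid=None, n_restarts=2, rng=0)
        assert len(table) == 1
        assert w2 == DEFAULT_W2

    def test_empty_dataset_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            bt.fit_noisy_sampling(CohortDataset(pd.DataFrame(), pd.DataFrame({"participant_id": []})))


def _as_frame(pdata: ParticipantData):
    import pandas as pd

    rows = []
    for i in range(pdata.n_trials):
        row = {"participant_id": 0, "trial_index": i, "ratio": pdata.ratios[i], "correct": bool(pdata.choice_correct[i])}
        for d in range(8):
            row[f"bead_{d + 1}"] = pdata.beads[i, d]
        for d in range(9):
            row[f"estimate_{d}"] = pdata.estimates[i, d]
        rows.append(row)
    return pd.DataFrame(rows)
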