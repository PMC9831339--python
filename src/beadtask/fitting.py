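"""Per-participant model fitting, BIC, and the study's exclusion screens.

Models are fitted to each participant's post-draw probability estimates by
minimizing the root-mean-squared error (RMSE) between model-predicted and
reported probabilities, with the participant's own pre-draw estimate
defining each trial's starting prior and trials with an incorrect final
choice excluded. Fits are restarted from random starting points within the
parameter bounds and the lowest-RMSE restart is kept.

Model comparison uses BIC = n * ln(sum(error^2)/n) + l * ln(n), where n is
the number of fitted estimates and l the number of free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .data import CohortDataset, ParticipantData, predict_heuristic, predict_weighted_bayes
from .models import DEFAULT_VARIANTS, HeuristicParams, ModelVariant, WeightedBayesParams

#: Squared-error floor (per estimate) keeping BIC finite on perfect fits.
SSE_FLOOR_PER_N = 1e-12


def bic(sum_sq_error: float, n: int, l: int) -> float:
    """Schwarz criterion on the RMSE scale: n*ln(SSE/n) + l*ln(n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    sse = max(float(sum_sq_error), SSE_FLOOR_PER_N * n)
    return float(n * np.log(sse / n) + l * np.log(n))


@dataclass
class FitResult:
    """Best fit of one model variant to one participant."""

    participant_id: object
    variant: ModelVariant
    theta: np.ndarray
    rmse: float
    n: int
    n_restarts: int
    converged: bool

    @property
    def n_params(self) -> int:
        return self.variant.n_params

    @property
    def sum_sq_error(self) -> float:
        return self.rmse**2 * self.n

    @property
    def bic(self) -> float:
        return bic(self.sum_sq_error, self.n, self.n_params)

    @property
    def params(self):
        if self.variant.heuristic:
            return HeuristicParams(float(self.theta[0]))
        return self.variant.unpack(self.theta)

    def param_dict(self) -> dict:
        if self.variant.heuristic:
            return {"c": float(self.theta[0])}
        p = self.variant.unpack(self.theta)
        return {"omega1": p.omega1, **{f"omega2_{l}": v for l, v in p.omega2.items()}}

    def summary(self) -> str:
        lines = [
            f"Weighted-Bayes fit: participant {self.participant_id}, variant {self.variant.name}",
            f"  n estimates: {self.n}   free parameters: {self.n_params}",
            f"  RMSE: {self.rmse:.5f}   BIC: {self.bic:.2f}   restarts: {self.n_restarts}",
        ]
        for k, v in self.param_dict().items():
            lines.append(f"  {k:>14s} = {v:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "variant": self.variant.name,
            "rmse": self.rmse,
            "n": self.n,
            "l": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            **self.param_dict(),
        }


class WeightedBayesModel:
    """One participant's estimate data under one model variant.

    Parameters
    ----------
    data : ParticipantData
        Trial data; trials with an incorrect final choice are dropped.
    variant : ModelVariant
        Tied/free structure of the weights (or a heuristic rule).
    """

    def __init__(self, data: ParticipantData, variant: ModelVariant):
        self.data = data.retained()
        self.variant = variant

    def predict(self, theta) -> np.ndarray:
        """Model-predicted post-draw probabilities, shape (n_trials, 8)."""
        if self.variant.heuristic:
            return predict_heuristic(self.data, self.variant.heuristic, float(np.atleast_1d(theta)[0]))
        p = self.variant.unpack(theta)
        return predict_weighted_bayes(self.data, p.omega1, p.omega2)

    def rmse(self, theta) -> float:
        return float(np.sqrt(np.mean((self.predict(theta) - self.data.reported) ** 2)))

    def fit(self, n_restarts: int = 100, bounds=(0.0, 20.0), rng=None) -> FitResult:
        """Multi-restart bounded minimization of the RMSE.

        Restarts draw starting points uniformly within the bounds; the
        lowest-RMSE restart wins, ties broken by the lexicographically
        smallest parameter vector.
        """
        if self.data.n_trials == 0:
            raise ValueError("no retained trials to fit")
        rng = np.random.default_rng(rng)
        n = self.data.n_trials * 8
        k = self.variant.n_params
        if k == 0:
            r = self.rmse(np.empty(0))
            return FitResult(self.data.participant_id, self.variant, np.empty(0), r, n, 0, True)
        if self.variant.heuristic:
            lo, hi = 0.5 + 1e-6, 1 - 1e-6
        else:
            lo, hi = bounds
        best_theta, best_rmse, ok = None, np.inf, False
        for _ in range(max(1, n_restarts)):
            x0 = rng.uniform(lo, hi, size=k)
            res = optimize.minimize(
                self.rmse, x0, method="L-BFGS-B", bounds=[(lo, hi)] * k, options={"ftol": 1e-10}
            )
            better = res.fun < best_rmse - 1e-12
            tie = abs(res.fun - best_rmse) <= 1e-12 and best_theta is not None and tuple(res.x) < tuple(best_theta)
            if better or tie:
                best_theta, best_rmse, ok = res.x.copy(), float(res.fun), bool(res.success)
        return FitResult(self.data.participant_id, self.variant, best_theta, best_rmse, n, n_restarts, ok)


def fit_participant(
    data: ParticipantData, variant: ModelVariant, n_restarts: int = 100, bounds=(0.0, 20.0), rng=None
) -> FitResult:
    """Functional wrapper around :class:`WeightedBayesModel`."""
    return WeightedBayesModel(data, variant).fit(n_restarts=n_restarts, bounds=bounds, rng=rng)


def fit_cohort(
    dataset: CohortDataset, variants=DEFAULT_VARIANTS, n_restarts: int = 100, bounds=(0.0, 20.0), rng=None
) -> pd.DataFrame:
    """Fit every variant to every participant; returns a long results table."""
    rng = np.random.default_rng(rng)
    rows = []
    for pid, pdata in dataset.iter_participants():
        for variant in variants:
            rows.append(fit_participant(pdata, variant, n_restarts=n_restarts, bounds=bounds, rng=rng).to_dict())
    return pd.DataFrame(rows)


def bic_matrix(fits: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long fit table into a (participants x models) BIC matrix."""
    return fits.pivot(index="participant_id", columns="variant", values="bic")


# ---------------------------------------------------------------------------
# Exclusion screens


@dataclass
class ScreenResult:
    participant_id: object
    retain: bool
    reason: str | None = None


def _ideal_predictions(data: ParticipantData) -> np.ndarray:
    return predict_weighted_bayes(data, 1.0, {r: 1.0 for r in set(data.ratios)})


def exclusion_screens(
    data: ParticipantData,
    mean_rt_ms: float | None = None,
    alpha: float = 0.05,
    n_restarts: int = 20,
    variants=DEFAULT_VARIANTS,
    rng=None,
) -> ScreenResult:
    """Apply the study's participant-level screens, in order.

    1. Bot screen: mean response time must exceed 350 ms (skipped when no
       response times are available).
    2. Accuracy criterion: at least 15 of the 22 final choices in the 60:40
       and 90:10 conditions correct (the binomial chance bound at 68%).
    3. Random-estimates criterion: regress post-draw estimates on the random
       slider start position and the ideal Bayesian estimate; exclude iff
       the cursor coefficient is significant at ``alpha`` and the Bayesian
       coefficient is not (estimates tracking the cursor but not the
       evidence). Skipped with a warning when cursor data is missing.
    4. Heuristic screen: individual BIC comparison on the 60:40 and 90:10
       data only (51:49 evidence is too weak to discriminate); exclude if a
       heuristic model fits best.
    """
    pid = data.participant_id
    if mean_rt_ms is not None and mean_rt_ms <= 350:
        return ScreenResult(pid, False, "response_time")

    strong = data.condition("60:40", "90:10")
    for label in ("60:40", "90:10"):
        cond = data.condition(label)
        if cond.n_trials and int(cond.choice_correct.sum()) < 15:
            return ScreenResult(pid, False, "accuracy")

    if data.cursor is None:
        warnings.warn("no cursor start positions; random-estimates screen skipped")
    else:
        y = data.reported.ravel()
        X = np.column_stack([data.cursor[:, 1:].ravel(), _ideal_predictions(data).ravel()])
        model = sm.OLS(y, sm.add_constant(X)).fit()
        p_cursor, p_bayes = model.pvalues[1], model.pvalues[2]
        if p_cursor < alpha and p_bayes >= alpha:
            return ScreenResult(pid, False, "random_estimates")

    rng = np.random.default_rng(rng)
    strong_retained = strong.retained()
    if strong_retained.n_trials == 0:
        return ScreenResult(pid, False, "accuracy")
    best_name, best_bic = None, np.inf
    for variant in variants:
        fit = WeightedBayesModel(strong, variant).fit(n_restarts=n_restarts, rng=rng)
        if fit.bic < best_bic:
            best_name, best_bic = variant.name, fit.bic
    if any(v.heuristic == best_name or (v.name == best_name and v.heuristic) for v in variants):
        return ScreenResult(pid, False, f"heuristic:{best_name}")
    return ScreenResult(pid, True)


def screen_cohort(dataset: CohortDataset, **kwargs) -> pd.DataFrame:
    rows = []
    for pid, pdata in dataset.iter_participants():
        res = exclusion_screens(pdata, **kwargs)
        rows.append({"participant_id": pid, "retain": res.retain, "reason": res.reason})
    return pd.DataFrame(rows)
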