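"""Noisy-sampling model of bounded-rational belief updating.

The agent cannot access the exact log-odds of its prior (or of the
likelihood); it observes a noisy internal sample r = z + v with
v ~ N(0, sigma2), while true log-odds z are themselves distributed around
the nominal value with environment variance w2. Optimal inference about the
state given the noisy sample shrinks it by gamma = w2 / (w2 + sigma2) and
leaves conditional variance Sigma2 = w2 * sigma2 / (w2 + sigma2). Converting
the resulting Gaussian belief over log-odds into a reportable probability
requires integrating the logistic function against that Gaussian, which is
approximated by dividing the mean by a correction factor rho >= 1
(rho = 1 + (3/pi^2) * Sigma2 by default; a square-root variant is
selectable, and :func:`logistic_gaussian_integral` provides the exact
integral for validation).

The net effect is exactly the weighted Bayesian model: the prior and
likelihood are multiplied by weights gamma/rho in [0, 1], plus additive
zero-mean Gaussian response noise with variance (gamma * sigma / rho)^2
summed over the prior and likelihood contributions. Larger representation
noise sigma2 therefore yields both smaller weights (more base-rate neglect)
and more variable responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import quad
from scipy.special import expit

from ._utils import clip_prob, logit
from .data import ParticipantData, predict_weighted_bayes
from .design import RATIO_LABELS
from .models import WeightedBayesParams, update_belief

#: Environment (omega^2) variances selected by the study's group-level grid
#: search; used as the fixed default when no grid is searched.
DEFAULT_W2 = {"prior": 0.2, "51:49": 0.2, "60:40": 0.2, "90:10": 0.6}


@dataclass(frozen=True)
class WeightDecomposition:
    """Shrinkage, conditional variance, mean correction, net weight and noise."""

    gamma: float
    Sigma2: float
    rho: float
    weight: float
    eps_var: float


def weight_decomposition(sigma2: float, w2: float, rho_form: str = "linear") -> WeightDecomposition:
    """Optimal weight and response-noise variance for one noisy quantity.

    gamma = w2/(w2+sigma2), Sigma2 = w2*sigma2/(w2+sigma2),
    rho = 1 + (3/pi^2)*Sigma2 ("linear", default) or sqrt of that ("sqrt"),
    weight = gamma/rho, eps_var = (gamma*sqrt(sigma2)/rho)^2.

    The noiseless limit sigma2 = 0 (including w2 = sigma2 = 0) gives
    weight 1 and eps_var 0, i.e. the ideal observer.
    """
    if sigma2 < 0 or w2 < 0:
        raise ValueError("variances must be nonnegative")
    if sigma2 == 0:
        return WeightDecomposition(1.0, 0.0, 1.0, 1.0, 0.0)
    gamma = w2 / (w2 + sigma2)
    Sigma2 = w2 * sigma2 / (w2 + sigma2)
    base = 1.0 + (3.0 / np.pi**2) * Sigma2
    if rho_form == "linear":
        rho = base
    elif rho_form == "sqrt":
        rho = float(np.sqrt(base))
    else:
        raise ValueError("rho_form must be 'linear' or 'sqrt'")
    weight = gamma / rho
    eps_var = (gamma * np.sqrt(sigma2) / rho) ** 2
    return WeightDecomposition(gamma, Sigma2, rho, weight, eps_var)


def logistic_gaussian_integral(mean: float, var: float) -> float:
    """Exact E[logistic(z)] for z ~ N(mean, var), by numeric quadrature.

    Independent oracle for the rho approximation: logit of this integral
    should be close to mean / rho.
    """
    if var == 0:
        return float(expit(mean))
    sd = np.sqrt(var)
    val, _ = quad(
        lambda z: expit(z) * np.exp(-((z - mean) ** 2) / (2 * var)) / (sd * np.sqrt(2 * np.pi)),
        mean - 12 * sd,
        mean + 12 * sd,
    )
    return float(val)


@dataclass
class NoisySamplingParams:
    """Representation-noise variances (fitted) and environment variances (fixed)."""

    sigma2_prior: float = 0.0
    sigma2_likelihood: dict = field(default_factory=lambda: {l: 0.0 for l in RATIO_LABELS})
    w2_prior: float = DEFAULT_W2["prior"]
    w2_likelihood: dict = field(default_factory=lambda: {l: DEFAULT_W2[l] for l in RATIO_LABELS})
    rho_form: str = "linear"

    def prior_decomposition(self) -> WeightDecomposition:
        return weight_decomposition(self.sigma2_prior, self.w2_prior, self.rho_form)

    def likelihood_decomposition(self, ratio: str) -> WeightDecomposition:
        return weight_decomposition(self.sigma2_likelihood[ratio], self.w2_likelihood[ratio], self.rho_form)

    def to_weighted_bayes(self) -> WeightedBayesParams:
        """The implied weighted Bayesian weights: omega1 = gamma_p/rho_p, etc."""
        return WeightedBayesParams(
            self.prior_decomposition().weight,
            {l: self.likelihood_decomposition(l).weight for l in RATIO_LABELS},
        )

    def eps_var(self, ratio: str) -> float:
        """Total response-noise variance for one update in condition `ratio`."""
        return self.prior_decomposition().eps_var + self.likelihood_decomposition(ratio).eps_var


def noisy_posterior(prior_logit: float, bead: int, ratio, params: NoisySamplingParams, rng):
    """One noisy update: (deterministic mean log-odds, sampled log-odds).

    The sampled value is both the reported estimate and the prior carried
    into the next draw; the mean is exactly the weighted-Bayesian update
    under the mapped weights.
    """
    label = getattr(ratio, "label", ratio)
    mean = update_belief(prior_logit, bead, label, params.to_weighted_bayes())
    sampled = mean + rng.normal(0.0, np.sqrt(params.eps_var(label)))
    return float(mean), float(sampled)


@dataclass
class NoisySamplingResults:
    """Per-participant fitted representation noise at fixed environment variances."""

    participant_id: object
    params: NoisySamplingParams
    rmse: float
    n: int
    n_params: int = 4

    @property
    def bic(self) -> float:
        from .fitting import bic

        return bic(self.rmse**2 * self.n, self.n, self.n_params)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "sigma2_prior": self.params.sigma2_prior,
            **{f"sigma2_{l}": self.params.sigma2_likelihood[l] for l in RATIO_LABELS},
            "rmse": self.rmse,
            "n": self.n,
        }


class NoisySamplingModel:
    """Per-participant noisy-sampling model at fixed environment variances.

    The fit minimizes the RMSE between the deterministic mean prediction
    (the weighted Bayesian model under the mapped weights) and the reported
    probabilities; the noise realization is not part of the objective.
    """

    def __init__(self, data: ParticipantData, w2=None, rho_form: str = "linear"):
        self.data = data.retained()
        self.w2 = dict(DEFAULT_W2 if w2 is None else w2)
        self.rho_form = rho_form

    def _params(self, theta) -> NoisySamplingParams:
        return NoisySamplingParams(
            sigma2_prior=theta[0],
            sigma2_likelihood=dict(zip(RATIO_LABELS, theta[1:4])),
            w2_prior=self.w2["prior"],
            w2_likelihood={l: self.w2[l] for l in RATIO_LABELS},
            rho_form=self.rho_form,
        )

    def rmse(self, theta) -> float:
        p = self._params(theta).to_weighted_bayes()
        pred = predict_weighted_bayes(self.data, p.omega1, p.omega2)
        return float(np.sqrt(np.mean((pred - self.data.reported) ** 2)))

    def fit(self, n_restarts: int = 20, bounds=(0.0, 5.0), rng=None) -> NoisySamplingResults:
        if self.data.n_trials == 0:
            raise ValueError("no retained trials to fit")
        rng = np.random.default_rng(rng)
        best = None
        lo, hi = bounds
        for _ in range(n_restarts):
            x0 = rng.uniform(lo, min(hi, 1.5), size=4)
            res = optimize.minimize(
                self.rmse, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 4, options={"ftol": 1e-10}
            )
            if best is None or res.fun < best.fun:
                best = res
        n = self.data.n_trials * 8
        return NoisySamplingResults(self.data.participant_id, self._params(best.x), float(best.fun), n)


def fit_noisy_sampling(dataset, w2_grid=None, sigma_bounds=(0.0, 5.0), n_restarts: int = 10, rng=None):
    """Grid search over environment variances with per-participant noise fits.

    ``w2_grid`` is an iterable of candidate values applied to each of the 4
    environment variances (full Cartesian product). For each grid point the
    4 sigma^2 parameters are fitted per participant by RMSE; the grid point
    with the lowest group-level BIC (pooled squared error over all trials
    and participants, free parameters = 4 per participant) is selected.

    Returns ``(fits, selected_w2, grid_table)`` where ``fits`` maps
    participant id -> :class:`NoisySamplingResults` at the selected point.
    """
    from itertools import product

    from .fitting import bic

    participants = list(dataset.iter_participants())
    if not participants:
        raise ValueError("empty dataset")
    if w2_grid is None:
        points = [tuple(DEFAULT_W2[k] for k in ("prior", *RATIO_LABELS))]
    else:
        points = list(product(list(w2_grid), repeat=4))
    rng = np.random.default_rng(rng)
    table = []
    best = None
    for point in points:
        w2 = dict(zip(("prior", *RATIO_LABELS), point))
        fits = {}
        sse, n_total = 0.0, 0
        for pid, pdata in participants:
            fit = NoisySamplingModel(pdata, w2=w2).fit(n_restarts=n_restarts, bounds=sigma_bounds, rng=rng)
            fits[pid] = fit
            sse += fit.rmse**2 * fit.n
            n_total += fit.n
        group_bic = bic(sse, n_total, 4 * len(participants))
        table.append({**{f"w2_{k}": v for k, v in w2.items()}, "group_bic": group_bic})
        if best is None or group_bic < best[0]:
            best = (group_bic, w2, fits)
    import pandas as pd

    return best[2], best[1], pd.DataFrame(table)
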