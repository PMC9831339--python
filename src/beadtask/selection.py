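"""Group-level random-effects Bayesian model selection.

Treats the model identity of each participant as a random effect drawn from
an unknown population distribution r over K models with a Dirichlet prior.
Per-participant log model evidences are approximated as -BIC/2. A
variational scheme estimates the posterior Dirichlet over r; the exceedance
probability (EP) of model k is the posterior probability that r_k is the
largest frequency. The Bayes omnibus risk (BOR) is the posterior
probability of the null that all models are equally frequent, and the
protected exceedance probability corrects the EP for it:

    PXP_k = (1 - BOR) * EP_k + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp


@dataclass
class ComparisonResult:
    """Random-effects model-selection summary for one BIC matrix."""

    models: list
    bic: pd.DataFrame
    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    protected_exceedance_prob: np.ndarray

    @property
    def winner(self) -> str:
        return self.models[int(np.argmax(self.protected_exceedance_prob))]

    def summary(self) -> str:
        lines = [
            f"Random-effects model selection over {len(self.models)} models, "
            f"{len(self.bic)} participants (BOR = {self.bor:.3f})",
            f"{'model':>32s} {'E[freq]':>8s} {'EP':>7s} {'PXP':>7s}",
        ]
        for i, m in enumerate(self.models):
            lines.append(
                f"{m:>32s} {self.expected_freq[i]:8.3f} "
                f"{self.exceedance_prob[i]:7.3f} {self.protected_exceedance_prob[i]:7.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "bor": self.bor,
            "pxp": self.protected_exceedance_prob.tolist(),
            "winner": self.winner,
        }


def _vb_dirichlet(lme: np.ndarray, alpha0: float = 1.0, max_iter: int = 500, tol: float = 1e-8):
    """Variational posterior Dirichlet(alpha) and responsibilities beta."""
    n, K = lme.shape
    alpha = np.full(K, alpha0 + n / K)
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        beta = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + beta.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    log_u = lme + digamma(alpha) - digamma(alpha.sum())
    beta = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
    return alpha, beta


def exceedance_probability(alpha: np.ndarray, n_samples: int = 200_000, rng=None) -> np.ndarray:
    """P(r_k > r_j for all j != k) under Dirichlet(alpha), by Monte Carlo."""
    rng = np.random.default_rng(0 if rng is None else rng)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_samples


def _free_energy_alternative(lme, alpha, beta, alpha0: float = 1.0) -> float:
    """Variational free energy of the random-effects (frequencies-vary) model."""
    K = lme.shape[1]
    a0 = np.full(K, alpha0)
    E_log_r = digamma(alpha) - digamma(alpha.sum())
    F = float(np.sum(beta * (lme + E_log_r)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(beta > 0, beta * np.log(beta), 0.0))
    F += ent
    F += gammaln(a0.sum()) - np.sum(gammaln(a0)) + float(np.sum((a0 - 1) * E_log_r))
    F -= gammaln(alpha.sum()) - np.sum(gammaln(alpha)) + float(np.sum((alpha - 1) * E_log_r))
    return F


def _free_energy_null(lme) -> float:
    """Evidence of the null: every model equally frequent (r = 1/K fixed)."""
    K = lme.shape[1]
    return float(np.sum(logsumexp(lme, axis=1) - np.log(K)))


def group_model_selection(
    bic_mat: pd.DataFrame, alpha0: float = 1.0, n_samples: int = 200_000, rng=None
) -> ComparisonResult:
    """Random-effects selection from a (participants x models) BIC matrix.

    Log model evidence is approximated as -BIC/2. Returns expected model
    frequencies, exceedance probabilities, the Bayes omnibus risk and the
    protected exceedance probabilities (which sum to 1).
    """
    bic_mat = pd.DataFrame(bic_mat)
    models = list(bic_mat.columns)
    K = len(models)
    if bic_mat.isna().any().any():
        raise ValueError("BIC matrix contains missing values")
    if K == 1:
        return ComparisonResult(models, bic_mat, np.array([1.0]), np.array([1.0]), np.array([1.0]), 0.0, np.array([1.0]))
    lme = -0.5 * bic_mat.to_numpy(float)
    lme = lme - lme.max(axis=1, keepdims=True)  # stabilizes exponentials only
    alpha, beta = _vb_dirichlet(lme, alpha0=alpha0)
    ef = alpha / alpha.sum()
    ep = exceedance_probability(alpha, n_samples=n_samples, rng=rng)
    F1 = _free_energy_alternative(lme, alpha, beta, alpha0=alpha0)
    F0 = _free_energy_null(lme)
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))
    pxp = (1.0 - bor) * ep + bor / K
    return ComparisonResult(models, bic_mat, alpha, ef, ep, bor, pxp)
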