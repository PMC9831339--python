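"""Noise-corrupted parameter recovery.

Agents with parameters sampled uniformly between the 10th and 90th
percentile of a fitted population are simulated on the experimental design
with increasing amounts of "late" Gaussian noise added to the reported
log-odds only (never propagated to subsequent priors), refitted with the
standard pipeline, and compared with their generating parameters as percent
deviation 100 * (recovered - true) / true. A recovery that stays unbiased
across the noise range matched to the observed response variability shows
that response-level noise alone cannot masquerade as prior underweighting.

The matched noise range is found by bootstrapping a confidence interval for
the cohort's group-median response variance and keeping the noise levels
whose simulated mean-of-median response variance falls inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import spawn_rng
from .cohort import AgentSpec, simulate_participant
from .data import ParticipantData
from .design import RATIO_LABELS, build_design
from .models import WINNING_VARIANT, WeightedBayesParams
from .stats import response_variance

DEFAULT_NOISE_GRID = tuple(np.round(np.arange(0.0, 1.51, 0.15), 2))


@dataclass
class RecoveryResult:
    """True vs recovered parameters per agent and noise level."""

    table: pd.DataFrame  # columns: agent, noise_sd, parameter, true, recovered, pct_deviation
    noise_grid: tuple
    matched_range: tuple | None = None

    def mean_abs_deviation(self, parameter: str, noise_sd=None) -> float:
        t = self.table[self.table["parameter"] == parameter]
        if noise_sd is not None:
            t = t[np.isclose(t["noise_sd"], noise_sd)]
        return float(t["pct_deviation"].abs().mean())

    def mean_deviation(self, parameter: str, noise_sd=None) -> float:
        t = self.table[self.table["parameter"] == parameter]
        if noise_sd is not None:
            t = t[np.isclose(t["noise_sd"], noise_sd)]
        return float(t["pct_deviation"].mean())

    def summary(self) -> str:
        lines = ["Parameter recovery (mean percent deviation by late-noise SD)"]
        piv = self.table.pivot_table(index="noise_sd", columns="parameter", values="pct_deviation")
        lines.append(piv.round(2).to_string())
        if self.matched_range is not None:
            lines.append(f"matched noise range: {self.matched_range}")
        return "\n".join(lines)


def _sample_population(fitted: pd.DataFrame, columns, n_agents: int, rng) -> pd.DataFrame:
    """Uniform draws between the 10th and 90th percentile of each column."""
    lo = fitted[list(columns)].quantile(0.10)
    hi = fitted[list(columns)].quantile(0.90)
    draws = {c: rng.uniform(lo[c], hi[c], size=n_agents) for c in columns}
    return pd.DataFrame(draws)


def run_recovery(
    fitted_population: pd.DataFrame,
    noise_grid=DEFAULT_NOISE_GRID,
    n_agents: int = 50,
    n_restarts: int = 20,
    seed: int = 0,
    design_seed: int = 0,
    variant=WINNING_VARIANT,
) -> RecoveryResult:
    """Simulate, corrupt and refit weighted-Bayesian agents.

    ``fitted_population`` must contain columns ``omega1`` and
    ``omega2_<ratio>`` (a fitted cohort table or any population sample);
    percentile bounds for the uniform agent draws come from it. Each agent
    keeps its parameters across noise levels so degradation is within-agent.
    """
    from .fitting import WeightedBayesModel

    rng = spawn_rng(seed, 11)
    cols = ["omega1"] + [f"omega2_{l}" for l in RATIO_LABELS]
    pop = _sample_population(fitted_population, cols, n_agents, rng)
    design = build_design(seed=design_seed)
    rows = []
    for a in range(n_agents):
        true = pop.iloc[a]
        params = WeightedBayesParams(
            float(true["omega1"]), {l: float(true[f"omega2_{l}"]) for l in RATIO_LABELS}
        )
        for noise_sd in noise_grid:
            agent = AgentSpec("weighted_bayes", params, late_noise_sd=float(noise_sd), lapse_rate=0.0)
            frame = simulate_participant(design, agent, spawn_rng(seed, 12, a, int(noise_sd * 1000)), a)
            pdata = ParticipantData.from_frame(frame)
            fit = WeightedBayesModel(pdata, variant).fit(
                n_restarts=n_restarts, rng=spawn_rng(seed, 13, a, int(noise_sd * 1000))
            )
            rec = fit.param_dict()
            for c in cols:
                tv, rv = float(true[c]), float(rec[c])
                rows.append(
                    {
                        "agent": a,
                        "noise_sd": float(noise_sd),
                        "parameter": c,
                        "true": tv,
                        "recovered": rv,
                        "pct_deviation": 100.0 * (rv - tv) / tv if tv != 0 else np.nan,
                        "abs_deviation": rv - tv,
                    }
                )
    return RecoveryResult(pd.DataFrame(rows), tuple(noise_grid))


def matched_noise_range(
    dataset,
    fitted_population: pd.DataFrame,
    noise_grid=DEFAULT_NOISE_GRID,
    n_sets: int = 10,
    n_agents_per_set: int = 267,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
    refine_step: float | None = None,
) -> tuple:
    """Noise levels reproducing the cohort's median response variance.

    Bootstraps a ``ci`` confidence interval for the group median response
    variance of ``dataset``, then simulates ``n_sets`` sets of agents at
    each noise level and keeps levels whose mean-of-medians falls inside
    the interval. Because the simulated response variance rises steeply
    with the noise SD, a coarse grid can straddle a narrow interval;
    ``refine_step`` adds a second pass on a finer grid over the coarse
    levels bracketing the interval. Returns (low_sd, high_sd); an empty
    overlap returns ``()`` with a warning.
    """
    import warnings

    rng = spawn_rng(seed, 21)
    rv = np.array([response_variance(pdata) for _, pdata in dataset.iter_participants()])
    rv = rv[~np.isnan(rv)]
    if len(rv) == 0:
        raise ValueError("no participant yields a response variance")
    boots = np.array([np.median(rng.choice(rv, size=len(rv), replace=True)) for _ in range(n_boot)])
    a = (1 - ci) / 2
    lo, hi = np.quantile(boots, [a, 1 - a])

    cols = ["omega1"] + [f"omega2_{l}" for l in RATIO_LABELS]

    def mean_of_medians(noise_sd: float) -> float:
        medians = []
        for s in range(n_sets):
            srng = spawn_rng(seed, 22, int(round(noise_sd * 1000)), s)
            pop = _sample_population(fitted_population, cols, n_agents_per_set, srng)
            vals = []
            for a_i in range(n_agents_per_set):
                params = WeightedBayesParams(
                    float(pop.iloc[a_i]["omega1"]),
                    {l: float(pop.iloc[a_i][f"omega2_{l}"]) for l in RATIO_LABELS},
                )
                agent = AgentSpec("weighted_bayes", params, late_noise_sd=float(noise_sd), lapse_rate=0.0)
                design = build_design(seed=int(srng.integers(2**31)))
                frame = simulate_participant(design, agent, srng, a_i)
                vals.append(response_variance(ParticipantData.from_frame(frame)))
            medians.append(np.nanmedian(np.asarray(vals, float)))
        return float(np.mean(medians))

    def scan(levels):
        sims = {float(sd): mean_of_medians(float(sd)) for sd in levels}
        matched = [sd for sd, mm in sims.items() if lo <= mm <= hi]
        return sims, matched

    sims, matched = scan(noise_grid)
    if not matched and refine_step:
        # bracket the interval: last level below it and first level above it
        levels = sorted(sims)
        below = [sd for sd in levels if sims[sd] < lo]
        above = [sd for sd in levels if sims[sd] > hi]
        if below and above:
            fine = np.arange(below[-1], above[0] + refine_step / 2, refine_step)
            _, matched = scan(fine)
    if not matched:
        warnings.warn("no noise level matches the observed response variance CI")
        return ()
    return (min(matched), max(matched))
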