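"""Synthetic participant cohorts with the statistical structure the analyses assume.

Agents (ideal, weighted-Bayesian, noisy-sampling, or heuristic) perform the
55-trial task on their own seeded design instance. Reported estimates can be
corrupted by "late" response noise: zero-mean Gaussian noise added to the
reported log-odds only, which does not propagate into subsequent prior
beliefs (noisy-sampling agents additionally propagate their internally
sampled posterior). Final box choices follow the sign of the final internal
log-odds except for a small lapse probability.

Questionnaire scores (PDI global score, Paranoia Checklist frequency score)
are attached via a Gaussian copula on ranks so that the cohort realizes a
target Spearman correlation between PDI and the prior weight omega1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import clip_prob, inv_logit, logit, spawn_rng
from .data import CohortDataset
from .design import RATIO_LABELS, DesignConfig, TaskDesign, build_design
from .models import HeuristicParams, WeightedBayesParams, heuristic_prediction, simulate_trajectory
from .noisy import NoisySamplingParams, noisy_posterior

AGENT_TYPES = ("ideal", "weighted_bayes", "noisy_sampling", "no_prior", "observed_proportion")


@dataclass
class AgentSpec:
    """A simulated participant: generative model plus response-level noise."""

    agent_type: str = "weighted_bayes"
    params: object = field(default_factory=WeightedBayesParams.ideal)
    late_noise_sd: float = 0.0
    lapse_rate: float = 0.015

    def __post_init__(self):
        if self.agent_type not in AGENT_TYPES:
            raise ValueError(f"unknown agent type {self.agent_type!r}")
        if self.late_noise_sd < 0:
            raise ValueError("late_noise_sd must be nonnegative")


def _trial_logits(seq, agent: AgentSpec, rng) -> np.ndarray:
    """Internal belief log-odds for one trial (9 values, pre-draw first)."""
    if agent.agent_type in ("ideal", "weighted_bayes"):
        params = WeightedBayesParams.ideal() if agent.agent_type == "ideal" else agent.params
        return simulate_trajectory(seq, params).logits
    if agent.agent_type == "noisy_sampling":
        logits = np.empty(9)
        logits[0] = 0.0
        x = 0.0
        for d, s in enumerate(seq.signed_beads):
            _, x = noisy_posterior(x, int(s), seq.ratio, agent.params, rng)
            logits[d + 1] = x
        return logits
    return heuristic_prediction(seq, agent.agent_type, agent.params.c).logits


def simulate_participant(design: TaskDesign, agent: AgentSpec, rng, participant_id=0) -> pd.DataFrame:
    """Simulate one participant; returns rows of the canonical trials table.

    Late noise perturbs the reported log-odds of post-draw estimates only;
    the internal belief used as the next draw's prior is unaffected. The
    pre-draw estimate is the unbiased 0.5. Slider cursor start positions are
    uniform on (0, 1).
    """
    rng = np.random.default_rng(rng)
    rows = []
    for i, seq in enumerate(design.trials):
        internal = _trial_logits(seq, agent, rng)
        reported = internal.copy()
        if agent.late_noise_sd > 0:
            reported[1:] = reported[1:] + rng.normal(0.0, agent.late_noise_sd, size=8)
        probs = clip_prob(inv_logit(reported))
        probs[0] = 0.5
        final = internal[-1]
        if final > 0:
            correct = True
        elif final < 0:
            correct = False
        else:
            correct = bool(rng.random() < 0.5)
        if rng.random() < agent.lapse_rate:
            correct = not correct
        row = {
            "participant_id": participant_id,
            "trial_index": i,
            "block": i // 11,
            "ratio": seq.ratio.label,
            "pair_id": seq.pair_id,
            "matched_id": seq.matched_id,
            "seq_id": seq.seq_id,
            "majority_color": seq.majority_color,
            "evidence_asymmetry": seq.evidence_asymmetry,
            "is_repeated": seq.is_repeated,
            "choice": int(correct),
            "correct": correct,
        }
        for d in range(8):
            row[f"bead_{d + 1}"] = seq.beads[d]
        for d in range(9):
            row[f"estimate_{d}"] = probs[d]
            row[f"cursor_{d}"] = rng.random()
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortSpec:
    """Population structure of a synthetic cohort.

    Defaults describe a mildly base-rate-neglecting weighted-Bayesian
    population: omega1 ~ N(0.92, 0.08) truncated to [0, 1.3] and
    omega2(60:40) ~ N(0.51, 0.18) truncated positive, with the 51:49 and
    90:10 likelihood weights scaled by fixed factors (weak evidence
    overweighted, strong evidence underweighted). For noisy-sampling
    cohorts, representation-noise variances are drawn instead and the
    weights follow from the noise.
    """

    n_participants: int = 100
    agent_type: str = "weighted_bayes"
    seed: int = 0
    omega1_mean: float = 0.92
    omega1_sd: float = 0.08
    omega1_bounds: tuple = (0.0, 1.3)
    omega2_6040_mean: float = 0.51
    omega2_6040_sd: float = 0.18
    omega2_scale_5149: float = 3.0
    omega2_scale_9010: float = 0.6
    sigma2_prior_mean: float = 0.015
    sigma2_prior_sd: float = 0.01
    sigma2_prior_bounds: tuple = (5e-4, 0.06)
    sigma2_likelihood_means: dict = field(
        default_factory=lambda: {"51:49": 0.05, "60:40": 0.18, "90:10": 1.2}
    )
    sigma2_likelihood_sd_frac: float = 0.5
    late_noise_sd: float = 0.3
    late_noise_coupling: float | None = None
    lapse_rate: float = 0.015
    pdi_spearman: float | None = -0.25
    pdi_exp_scale: float = 55.0
    groups: dict | None = None  # e.g. {"n_low": 57, "n_high": 34, "omega1_shift": 0.044}
    design_config: DesignConfig | None = None

    def __post_init__(self):
        if self.pdi_spearman is not None and not -1 <= self.pdi_spearman <= 1:
            raise ValueError("pdi_spearman must lie in [-1, 1]")
        if self.groups and self.groups.get("n_low", 0) + self.groups.get("n_high", 0) != self.n_participants:
            raise ValueError("group sizes must sum to n_participants")


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _copula_scores(rng, anchor: np.ndarray, spearman: float, marginal_ppf) -> np.ndarray:
    """Sample values with a target Spearman correlation to `anchor` ranks.

    Gaussian copula on normal scores of the ranks; the Pearson correlation
    of the latent normals is 2*sin(pi*rho_s/6).
    """
    n = len(anchor)
    r = 2.0 * np.sin(np.pi * spearman / 6.0)
    z1 = stats.norm.ppf((stats.rankdata(anchor) - 0.5) / n)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(n)
    return marginal_ppf(stats.norm.cdf(z2))


def _sample_agents(spec: CohortSpec, rng):
    n = spec.n_participants
    agents, truth = [], []
    if spec.agent_type == "weighted_bayes":
        omega1 = _truncnorm(rng, spec.omega1_mean, spec.omega1_sd, *spec.omega1_bounds, size=n)
        if spec.groups:
            shift = spec.groups.get("omega1_shift", 0.044)
            n_high = spec.groups["n_high"]
            omega1[:n_high] = _truncnorm(
                rng, spec.omega1_mean - shift, spec.omega1_sd, *spec.omega1_bounds, size=n_high
            )
        w2_6040 = _truncnorm(rng, spec.omega2_6040_mean, spec.omega2_6040_sd, 0.05, 3.0, size=n)
        for i in range(n):
            omega2 = {
                "51:49": w2_6040[i] * spec.omega2_scale_5149,
                "60:40": w2_6040[i],
                "90:10": w2_6040[i] * spec.omega2_scale_9010,
            }
            params = WeightedBayesParams(float(omega1[i]), omega2)
            agents.append(AgentSpec("weighted_bayes", params, spec.late_noise_sd, spec.lapse_rate))
            truth.append({"omega1": params.omega1, **{f"omega2_{l}": omega2[l] for l in RATIO_LABELS}})
    elif spec.agent_type == "noisy_sampling":
        s2p = _truncnorm(rng, spec.sigma2_prior_mean, spec.sigma2_prior_sd, *spec.sigma2_prior_bounds, size=n)
        s2l = {
            l: _truncnorm(rng, m, m * spec.sigma2_likelihood_sd_frac, 1e-3, 4.0, size=n)
            for l, m in spec.sigma2_likelihood_means.items()
        }
        for i in range(n):
            params = NoisySamplingParams(
                sigma2_prior=float(s2p[i]),
                sigma2_likelihood={l: float(s2l[l][i]) for l in RATIO_LABELS},
            )
            if spec.late_noise_coupling is not None:
                # report (motor) noise scales with internal imprecision: the
                # optimal weighting makes belief variance nearly invariant to
                # sigma2_prior, so interindividual response-variance spread
                # comes from this coupled late noise
                late_sd = float(np.sqrt(spec.late_noise_coupling * s2p[i]))
            else:
                late_sd = spec.late_noise_sd
            agents.append(AgentSpec("noisy_sampling", params, late_sd, spec.lapse_rate))
            mapped = params.to_weighted_bayes()
            truth.append(
                {
                    "sigma2_prior": params.sigma2_prior,
                    **{f"sigma2_{l}": params.sigma2_likelihood[l] for l in RATIO_LABELS},
                    "omega1": mapped.omega1,
                    **{f"omega2_{l}": mapped.omega2[l] for l in RATIO_LABELS},
                }
            )
    else:
        raise ValueError(f"cohort agent_type must be weighted_bayes or noisy_sampling, got {spec.agent_type!r}")
    return agents, truth


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a full synthetic cohort dataset (trials + participants tables)."""
    rng = spawn_rng(spec.seed, 1)
    agents, truth = _sample_agents(spec, rng)
    n = spec.n_participants

    omega1 = np.array([t["omega1"] for t in truth])
    pdi_ppf = lambda q: np.round(np.clip(stats.expon.ppf(q, scale=spec.pdi_exp_scale), 0, 336))
    if spec.groups:
        n_high = spec.groups["n_high"]
        pdi = np.empty(n)
        pdi[:n_high] = np.round(rng.uniform(83.0, 250.0, size=n_high))
        pdi[n_high:] = np.round(rng.uniform(0.0, 34.8, size=n - n_high))
        group = np.array(["high"] * n_high + ["low"] * (n - n_high))
    elif spec.pdi_spearman is not None:
        pdi = _copula_scores(rng, omega1, spec.pdi_spearman, pdi_ppf)
        group = np.array(["intermediate"] * n)
    else:
        pdi = pdi_ppf(rng.uniform(size=n))
        group = np.array(["intermediate"] * n)
    paranoia_ppf = lambda q: np.round(np.clip(stats.expon.ppf(q, scale=12.0), 0, 72))
    paranoia = _copula_scores(rng, pdi + rng.uniform(0, 1e-6, size=n), 0.8, paranoia_ppf)

    frames, participants = [], []
    for i in range(n):
        design = build_design(spec.design_config, seed=int(spawn_rng(spec.seed, 2, i).integers(2**31)))
        frames.append(simulate_participant(design, agents[i], spawn_rng(spec.seed, 3, i), participant_id=i))
        participants.append(
            {
                "participant_id": i,
                "agent_type": spec.agent_type,
                "late_noise_sd": agents[i].late_noise_sd,
                "pdi": float(pdi[i]),
                "paranoia_frequency": float(paranoia[i]),
                "group": group[i],
                **truth[i],
            }
        )
    return CohortDataset(pd.concat(frames, ignore_index=True), pd.DataFrame(participants))


def binarized_score(estimate: float, objective: float, rng) -> float:
    """Binarized scoring rule payout for a probability estimate: 0 or -5.

    A uniform k in (0, 1) is drawn and $5 is lost iff the squared error of
    the estimate relative to the objective probability is larger than k;
    expected payout is therefore -5 * (estimate - objective)^2, maximized
    (at 0) when the estimate equals the objective probability.
    """
    if not (0 <= estimate <= 1 and 0 <= objective <= 1):
        raise ValueError("estimate and objective must be probabilities")
    k = np.random.default_rng(rng).random() if not hasattr(rng, "random") else rng.random()
    return -5.0 if (estimate - objective) ** 2 > k else 0.0


def choice_score(correct: bool) -> float:
    """Binarized rule applied to box choices: lose $5 iff incorrect."""
    return 0.0 if correct else -5.0


def expected_payout(estimate: float, objective: float) -> float:
    """Analytic expected payout of the scoring rule: -5 * squared error."""
    return -5.0 * (estimate - objective) ** 2
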