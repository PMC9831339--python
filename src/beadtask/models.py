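"""Predictive belief-updating models.

The core model family updates beliefs additively in log-odds space:

    logit(posterior_d) = omega1 * logit(prior_d) + omega2(l) * logit(likelihood_d)

where the prior on draw d is the posterior after draw d-1, logit(likelihood)
is +/- ln(majority/minority) depending on the bead's color, omega1 is the
prior weight (omega1 < 1 produces sequential base-rate neglect: a recency
bias and prior-dependent updating) and omega2(l) scales evidence strength
per bead-ratio condition l. The ideal Bayesian observer has all weights
equal to 1 and is path independent: its final belief depends only on the
bead counts, not their order.

Two heuristic (non-updating) reference models report a fixed certainty c in
favor of the most recent bead's color (``no_prior``) or of the modal color
so far (``observed_proportion``, ties -> 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._utils import clip_prob, inv_logit, logit
from .design import RATIO_LABELS, RATIOS, BeadRatio, TrialSequence, likelihood_logit


@dataclass
class WeightedBayesParams:
    """Prior weight omega1 and per-condition likelihood weights omega2."""

    omega1: float = 1.0
    omega2: dict = field(default_factory=lambda: {l: 1.0 for l in RATIO_LABELS})

    def __post_init__(self):
        if np.isscalar(self.omega2):
            self.omega2 = {l: float(self.omega2) for l in RATIO_LABELS}

    @classmethod
    def ideal(cls) -> "WeightedBayesParams":
        return cls(1.0, {l: 1.0 for l in RATIO_LABELS})


@dataclass
class HeuristicParams:
    """Fixed reported certainty c in (0.5, 1)."""

    c: float = 0.8

    def __post_init__(self):
        if not 0.5 < self.c < 1:
            raise ValueError("certainty c must lie strictly in (0.5, 1)")


@dataclass(frozen=True)
class ModelVariant:
    """A member of the compared model family.

    ``omega1_free`` and ``omega2_structure`` define the tied/free structure:
    omega2_structure is one of 'fixed' (= 1), 'shared' (one weight for all
    conditions) or 'conditionwise' (one per bead ratio). Heuristic variants
    set ``heuristic`` to the rule name and carry a single certainty
    parameter.
    """

    name: str
    omega1_free: bool = False
    omega2_structure: str = "fixed"
    heuristic: str | None = None

    @property
    def n_params(self) -> int:
        if self.heuristic:
            return 1
        n = int(self.omega1_free)
        n += {"fixed": 0, "shared": 1, "conditionwise": 3}[self.omega2_structure]
        return n

    def unpack(self, theta) -> WeightedBayesParams:
        """Map a flat parameter vector onto model weights."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if len(theta) != self.n_params:
            raise ValueError(f"{self.name} expects {self.n_params} parameters")
        i = 0
        omega1 = 1.0
        if self.omega1_free:
            omega1 = theta[i]
            i += 1
        if self.omega2_structure == "fixed":
            omega2 = {l: 1.0 for l in RATIO_LABELS}
        elif self.omega2_structure == "shared":
            omega2 = {l: theta[i] for l in RATIO_LABELS}
        else:
            omega2 = dict(zip(RATIO_LABELS, theta[i : i + 3]))
        return WeightedBayesParams(omega1, omega2)


#: The compared family: all combinations of {omega1 fixed at 1, free} x
#: {omega2 absent (=1), shared, condition-wise}, plus the two heuristics.
#: 'prior_likelihood_conditionwise' (omega1 + three omega2(l), 4 free
#: parameters) is the study's winning model; 'ideal' is the Bayesian ideal
#: observer with no free parameters.
DEFAULT_VARIANTS = (
    ModelVariant("ideal"),
    ModelVariant("prior_only", omega1_free=True),
    ModelVariant("likelihood_shared", omega2_structure="shared"),
    ModelVariant("likelihood_conditionwise", omega2_structure="conditionwise"),
    ModelVariant("prior_likelihood_shared", omega1_free=True, omega2_structure="shared"),
    ModelVariant("prior_likelihood_conditionwise", omega1_free=True, omega2_structure="conditionwise"),
    ModelVariant("no_prior", heuristic="no_prior"),
    ModelVariant("observed_proportion", heuristic="observed_proportion"),
)

WINNING_VARIANT = DEFAULT_VARIANTS[5]
HEURISTIC_NAMES = ("no_prior", "observed_proportion")


def load_variant_registry(path=None):
    """Load a model-variant registry from YAML.

    With no path, the registry shipped with the package is used. Each entry
    gives ``name`` and optionally ``omega1_free``, ``omega2_structure`` and
    ``heuristic``.
    """
    if path is None:
        text = resources.files("beadtask").joinpath("variants.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = yaml.safe_load(text)
    return tuple(ModelVariant(**e) for e in entries)


def update_belief(prior_logit, bead, ratio, params: WeightedBayesParams):
    """One weighted-Bayesian update in log-odds space.

    ``bead`` is +1 for a majority-color bead and -1 for a minority-color
    bead (with respect to the true hidden box).
    """
    if isinstance(ratio, BeadRatio):
        ratio = ratio.label
    llr = likelihood_logit(ratio)
    return params.omega1 * np.asarray(prior_logit, float) + params.omega2[ratio] * np.asarray(bead, float) * llr


@dataclass
class BeliefTrajectory:
    """9 probability estimates (pre-draw + after each of 8 draws) and choice."""

    estimates: np.ndarray
    logits: np.ndarray
    choice_correct: bool

    @property
    def final_estimate(self) -> float:
        return float(self.estimates[-1])


def simulate_trajectory(seq: TrialSequence, params: WeightedBayesParams, start_prior: float = 0.5) -> BeliefTrajectory:
    """Deterministic belief trajectory of a weighted-Bayesian agent.

    The prior on each draw is the posterior after the previous draw;
    estimate 0 equals ``start_prior``. Returned probabilities are clipped to
    the slider range [0.001, 0.999]; raw logits are carried alongside.
    """
    if not 0 < start_prior < 1:
        raise ValueError("start_prior must lie in (0, 1)")
    logits = np.empty(9)
    logits[0] = logit(start_prior)
    x = logits[0]
    for d, s in enumerate(seq.signed_beads):
        x = update_belief(x, s, seq.ratio, params)
        logits[d + 1] = x
    probs = clip_prob(inv_logit(logits))
    probs[0] = start_prior
    return BeliefTrajectory(probs, logits, choice_correct=bool(logits[-1] > 0))


def final_logit_closed_form(seq: TrialSequence, params: WeightedBayesParams, start_prior: float = 0.5) -> float:
    """Closed form of the final log-odds: geometric discounting of evidence.

    logit(final) = omega1^8 * logit(start) + sum_d omega1^(8-d) * omega2 * s_d * LLR.
    """
    llr = seq.ratio.log_likelihood_ratio
    w2 = params.omega2[seq.ratio.label]
    d = np.arange(1, 9)
    disc = params.omega1 ** (8 - d)
    return float(params.omega1**8 * logit(start_prior) + np.sum(disc * w2 * seq.signed_beads * llr))


def heuristic_prediction(seq: TrialSequence, model: str, c: float) -> BeliefTrajectory:
    """Trajectory of a heuristic agent reporting fixed certainty c.

    ``no_prior``: c toward the last bead's color. ``observed_proportion``:
    c toward the modal color so far; exact ties -> 0.5. The pre-draw
    estimate is 0.5. Estimates are expressed as probability of the true
    (majority-color) box, so a majority bead maps to c and a minority bead
    to 1 - c.
    """
    HeuristicParams(c)
    signed = seq.signed_beads
    probs = np.empty(9)
    probs[0] = 0.5
    if model == "no_prior":
        probs[1:] = np.where(signed > 0, c, 1 - c)
    elif model == "observed_proportion":
        running = np.cumsum(signed)
        probs[1:] = np.where(running > 0, c, np.where(running < 0, 1 - c, 0.5))
    else:
        raise ValueError(f"unknown heuristic model {model!r}")
    logits = logit(clip_prob(probs))
    return BeliefTrajectory(probs, logits, choice_correct=bool(probs[-1] > 0.5))
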