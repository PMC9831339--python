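"""Shared numeric helpers: logit transforms, probability clipping, RNG spawning."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

#: Slider resolution floor/ceiling used when converting logits to reportable
#: probabilities (0.1% resolution); raw logits are kept internally.
PROB_FLOOR = 0.001
PROB_CEIL = 0.999


def logit(p):
    """Log-odds ln(p / (1 - p)); elementwise."""
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def inv_logit(x):
    """Logistic function, the inverse of :func:`logit`."""
    return expit(np.asarray(x, dtype=float))


def clip_prob(p, floor=PROB_FLOOR, ceil=PROB_CEIL):
    """Clip probabilities into the reportable slider range [floor, ceil]."""
    return np.clip(np.asarray(p, dtype=float), floor, ceil)


def safe_logit(p, floor=PROB_FLOOR, ceil=PROB_CEIL):
    """Logit after clipping away exact 0/1, which would map to infinity."""
    return logit(clip_prob(p, floor, ceil))


def spawn_rng(seed, *path):
    """Derive an independent Generator from a master seed and an integer path.

    Every stochastic component takes its seed from the master seed through a
    distinct path so that no two stages share a stream.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(p) for p in path))
    return np.random.default_rng(ss)
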