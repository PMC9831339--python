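"""Bead-sequence task design.

The task presents 55 trials, each an ordered sequence of 8 beads drawn from a
hidden box whose majority:minority color composition ("bead ratio") is 51:49,
60:40 or 90:10. Beads are coded 1 = majority color (consistent with the true
hidden box) and 0 = minority; the displayed color is a presentation attribute
assigned at random per trial.

Sequences are organized as mirror-opposite pairs (same ratio, same number of
majority beads, reversed order) so that differences in final beliefs between
the two members isolate evidence-order effects. The degree of front- vs
back-loading of majority beads is quantified by a signed evidence-asymmetry
score: the dot product of the 0/1 sequence with position weights
[-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, 3.5].

A generated design satisfies the composition constraints of the study: 55
trials in 5 blocks of 11 (ratio order 60:40, 90:10, 51:49, 60:40, 90:10), 26
distinct sequences of which 16 appear in both the 60:40 and 90:10 conditions
("matched" sequences), 6 are unique to 60:40, 4 to 51:49 and none to 90:10;
the all-majority sequence in the 90:10 condition is the single repeated
sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd

ASYMMETRY_WEIGHTS = np.array([-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, 3.5])

#: Fixed ratio order of the five 11-trial blocks.
BLOCK_RATIOS = ("60:40", "90:10", "51:49", "60:40", "90:10")

RATIO_LABELS = ("51:49", "60:40", "90:10")


class InvalidSequenceError(ValueError):
    """Raised for bead vectors that are not 8-element binary sequences."""


class DesignConstraintError(ValueError):
    """Raised when a design configuration cannot satisfy the task constraints."""


@dataclass(frozen=True)
class BeadRatio:
    """Majority:minority bead composition of the hidden box."""

    label: str
    majority_prob: float

    def __post_init__(self):
        if not 0.5 < self.majority_prob < 1:
            raise ValueError("majority_prob must lie in (0.5, 1)")

    @property
    def minority_prob(self) -> float:
        return 1.0 - self.majority_prob

    @property
    def log_likelihood_ratio(self) -> float:
        """ln(majority_prob / minority_prob): evidence strength per bead."""
        return float(np.log(self.majority_prob / self.minority_prob))

    @classmethod
    def from_label(cls, label: str) -> "BeadRatio":
        return RATIOS[label]


RATIOS = {
    "51:49": BeadRatio("51:49", 0.51),
    "60:40": BeadRatio("60:40", 0.60),
    "90:10": BeadRatio("90:10", 0.90),
}


def likelihood_logit(ratio: BeadRatio | str) -> float:
    """Natural log-odds of a single bead draw, ln(majority/minority)."""
    if isinstance(ratio, str):
        ratio = RATIOS[ratio]
    return ratio.log_likelihood_ratio


def _validate_beads(beads) -> np.ndarray:
    arr = np.asarray(beads)
    if arr.shape != (8,):
        raise InvalidSequenceError(f"expected 8 beads, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise InvalidSequenceError("beads must be 0 (minority) or 1 (majority)")
    return arr.astype(int)


def evidence_asymmetry(beads) -> float:
    """Signed front-/back-loading score of an 8-bead sequence.

    Negative values: majority beads concentrated early (front-loaded).
    Positive values: concentrated late (back-loaded). The weight vector sums
    to zero, so the all-majority sequence scores 0.
    """
    return float(_validate_beads(beads) @ ASYMMETRY_WEIGHTS)


@dataclass(frozen=True)
class TrialSequence:
    """One trial's bead order plus its design annotations."""

    beads: tuple
    ratio: BeadRatio
    majority_color: str = "blue"
    pair_id: int | None = None
    matched_id: int | None = None
    seq_id: int | None = None
    is_repeated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "beads", tuple(_validate_beads(self.beads)))

    @property
    def evidence_asymmetry(self) -> float:
        return evidence_asymmetry(self.beads)

    @property
    def n_majority(self) -> int:
        return int(sum(self.beads))

    @property
    def signed_beads(self) -> np.ndarray:
        """Beads coded +1 (majority) / -1 (minority), the model's input."""
        return np.asarray(self.beads) * 2 - 1


def mirror(seq: TrialSequence) -> TrialSequence:
    """Mirror-opposite partner: bead order reversed, everything else kept."""
    return replace(seq, beads=tuple(reversed(seq.beads)))


@dataclass
class DesignConfig:
    """Counts and sampling knobs for the design generator.

    Majority-bead counts for sampled sequences are drawn from per-set ranges
    chosen so that each condition's count distribution is close to what random
    draws from its box would produce (exact simultaneous matching across the
    shared 60:40/90:10 set is impossible, so the shared set compromises).
    """

    n_shared_pairs: int = 7
    n_6040_unique_pairs: int = 3
    n_5149_unique_pairs: int = 2
    n_repeats_all_majority: int = 7
    shared_counts: tuple = (5, 6, 7)
    unique_6040_counts: tuple = (3, 4, 5)
    unique_5149_counts: tuple = (4, 5)
    palindrome_count: int = 6


@dataclass
class TaskDesign:
    """An ordered 55-trial design: 5 blocks of 11 trials."""

    trials: list
    seed: int
    blocks: tuple = BLOCK_RATIOS

    def __len__(self):
        return len(self.trials)

    @property
    def n_unique_sequences(self) -> int:
        return len({t.beads for t in self.trials})

    @property
    def n_matched(self) -> int:
        """Sequences appearing in both the 60:40 and 90:10 conditions."""
        by_ratio = {"60:40": set(), "90:10": set()}
        for t in self.trials:
            if t.ratio.label in by_ratio:
                by_ratio[t.ratio.label].add(t.beads)
        return len(by_ratio["60:40"] & by_ratio["90:10"])

    def mirror_pairs(self):
        """Yield (front_loaded, back_loaded) trial pairs per condition.

        Palindromic sequences (their own mirror) are skipped. Pair members
        are ordered by sign of evidence asymmetry.
        """
        by_pair = {}
        for t in self.trials:
            if t.pair_id is None:
                continue
            by_pair.setdefault((t.ratio.label, t.pair_id), []).append(t)
        for members in by_pair.values():
            if len(members) != 2 or members[0].beads == members[1].beads:
                continue
            a, b = members
            if a.evidence_asymmetry > b.evidence_asymmetry:
                a, b = b, a
            yield a, b

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            row = {
                "trial_index": i,
                "block": i // 11,
                "ratio": t.ratio.label,
                "pair_id": t.pair_id,
                "matched_id": t.matched_id,
                "seq_id": t.seq_id,
                "majority_color": t.majority_color,
                "evidence_asymmetry": t.evidence_asymmetry,
                "is_repeated": t.is_repeated,
            }
            for d in range(8):
                row[f"bead_{d + 1}"] = t.beads[d]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def _pair_capacity(count: int) -> int:
    """Number of distinct non-palindromic mirror pairs with `count` majority beads."""
    n_pal = comb(4, count // 2) if count % 2 == 0 else 0
    return (comb(8, count) - n_pal) // 2


def _draw_count(rng, counts, used) -> int:
    """Pick a majority-bead count that still has fresh mirror pairs left."""
    avail = [c for c in counts if used.get(c, 0) < _pair_capacity(c)]
    if not avail:
        raise DesignConstraintError(f"mirror pairs exhausted for counts {counts}")
    c = int(rng.choice(avail))
    used[c] = used.get(c, 0) + 1
    return c


def _sample_mirror_pair(rng, count, forbidden):
    """Draw a non-palindromic sequence with `count` majority beads (and its
    mirror) whose identity is not in `forbidden`."""
    for _ in range(10_000):
        beads = np.zeros(8, dtype=int)
        beads[rng.choice(8, size=count, replace=False)] = 1
        t = tuple(beads)
        m = tuple(beads[::-1])
        if t == m or t in forbidden or m in forbidden:
            continue
        return t, m
    raise DesignConstraintError("could not sample a fresh mirror pair")


def _sample_palindrome(rng, count, forbidden):
    """Draw a palindromic sequence with `count` majority beads."""
    if count % 2:
        raise DesignConstraintError("palindrome majority count must be even")
    for _ in range(10_000):
        half = np.zeros(4, dtype=int)
        half[rng.choice(4, size=count // 2, replace=False)] = 1
        beads = tuple(half) + tuple(half[::-1])
        if beads not in forbidden and sum(beads) not in (0, 8):
            return beads
    raise DesignConstraintError("could not sample a fresh palindrome")


def build_design(config: DesignConfig | None = None, seed: int = 0) -> TaskDesign:
    """Generate a randomized task design satisfying the composition constraints.

    Sequences are sampled at random (mirror pairs jointly), block membership
    and within-block order are shuffled, and the majority color of each trial
    is assigned at random. Two calls with the same seed give the same design.
    """
    cfg = config or DesignConfig()
    if cfg.n_shared_pairs * 2 + 2 + cfg.n_6040_unique_pairs * 2 != 22:
        raise DesignConstraintError("60:40 condition must comprise 22 trials")
    if cfg.n_shared_pairs * 2 + 1 + cfg.n_repeats_all_majority != 22:
        raise DesignConstraintError("90:10 condition must comprise 22 trials")
    rng = np.random.default_rng(seed)

    taken = set()
    all_majority = (1,) * 8
    taken.add(all_majority)
    palindrome = _sample_palindrome(rng, cfg.palindrome_count, taken)
    taken.add(palindrome)

    used = {}
    shared_pairs = []
    for _ in range(cfg.n_shared_pairs):
        t, m = _sample_mirror_pair(rng, _draw_count(rng, cfg.shared_counts, used), taken)
        taken.update((t, m))
        shared_pairs.append((t, m))
    unique_6040 = []
    for _ in range(cfg.n_6040_unique_pairs):
        t, m = _sample_mirror_pair(rng, _draw_count(rng, cfg.unique_6040_counts, used), taken)
        taken.update((t, m))
        unique_6040.append((t, m))
    unique_5149 = []
    for _ in range(cfg.n_5149_unique_pairs):
        t, m = _sample_mirror_pair(rng, _draw_count(rng, cfg.unique_5149_counts, used), taken)
        taken.update((t, m))
        unique_5149.append((t, m))

    seq_ids = {}

    def sid(beads):
        return seq_ids.setdefault(beads, len(seq_ids))

    def make(beads, ratio_label, pair_id, matched, repeated=False):
        return TrialSequence(
            beads=beads,
            ratio=RATIOS[ratio_label],
            pair_id=pair_id,
            matched_id=sid(beads) if matched else None,
            seq_id=sid(beads),
            is_repeated=repeated,
        )

    # 60:40 - every shared sequence once, plus the unique pairs
    trials_6040 = []
    for pid, (t, m) in enumerate(shared_pairs):
        trials_6040 += [make(t, "60:40", pid, True), make(m, "60:40", pid, True)]
    trials_6040.append(make(palindrome, "60:40", None, True))
    trials_6040.append(make(all_majority, "60:40", None, True))
    for k, (t, m) in enumerate(unique_6040):
        pid = len(shared_pairs) + k
        trials_6040 += [make(t, "60:40", pid, False), make(m, "60:40", pid, False)]

    # 90:10 - shared pairs + palindrome + the repeated all-majority sequence
    trials_9010 = []
    for pid, (t, m) in enumerate(shared_pairs):
        trials_9010 += [make(t, "90:10", pid, True), make(m, "90:10", pid, True)]
    trials_9010.append(make(palindrome, "90:10", None, True))
    for _ in range(cfg.n_repeats_all_majority):
        trials_9010.append(make(all_majority, "90:10", None, True, repeated=True))

    # 51:49 - unique pairs + a subset of shared sequences (3 pairs + palindrome)
    trials_5149 = []
    for pid, (t, m) in enumerate(unique_5149):
        trials_5149 += [make(t, "51:49", pid, False), make(m, "51:49", pid, False)]
    chosen = rng.choice(len(shared_pairs), size=3, replace=False)
    for k, j in enumerate(chosen):
        t, m = shared_pairs[j]
        pid = len(unique_5149) + k
        trials_5149 += [make(t, "51:49", pid, False), make(m, "51:49", pid, False)]
    trials_5149.append(make(palindrome, "51:49", None, False))

    # split each 22-trial condition across its two blocks, shuffle within block
    def split(trials):
        idx = rng.permutation(len(trials))
        return [trials[i] for i in idx[:11]], [trials[i] for i in idx[11:]]

    b1, b4 = split(trials_6040)
    b2, b5 = split(trials_9010)
    b3 = [trials_5149[i] for i in rng.permutation(11)]

    ordered = []
    for block in (b1, b2, b3, b4, b5):
        for t in block:
            color = "blue" if rng.random() < 0.5 else "green"
            ordered.append(replace(t, majority_color=color))
    return TaskDesign(trials=ordered, seed=seed)


def load_config(path) -> DesignConfig:
    """Read a JSON design configuration (counts and sampling knobs)."""
    with open(path) as fh:
        raw = json.load(fh)
    known = DesignConfig().__dict__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise DesignConstraintError(f"unknown design config keys: {sorted(unknown)}")
    for key in ("shared_counts", "unique_6040_counts", "unique_5149_counts"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return DesignConfig(**raw)
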