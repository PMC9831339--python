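"""Canonical in-memory containers for participant trial data.

The pipeline's canonical on-disk format is a long-format trials table (one
row per trial) with columns ``participant_id, trial_index, ratio,
bead_1..bead_8, estimate_0..estimate_8, choice, correct`` (plus optional
``cursor_0..cursor_8`` slider start positions and design annotations).
Estimates are probabilities that the hidden box is the *true* box, i.e. the
majority-color box; beads are 1 = majority, 0 = minority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import clip_prob, safe_logit
from .design import RATIO_LABELS, RATIOS, likelihood_logit

BEAD_COLS = [f"bead_{d}" for d in range(1, 9)]
EST_COLS = [f"estimate_{d}" for d in range(9)]
CURSOR_COLS = [f"cursor_{d}" for d in range(9)]


@dataclass
class ParticipantData:
    """One participant's trials as dense arrays, ready for fitting.

    ``estimates`` has shape (n_trials, 9) with column 0 the pre-draw
    estimate that defines each trial's starting prior belief. ``beads`` is
    0/1 with shape (n_trials, 8).
    """

    participant_id: object
    beads: np.ndarray
    ratios: np.ndarray
    estimates: np.ndarray
    choice_correct: np.ndarray
    cursor: np.ndarray | None = None
    majority_color: np.ndarray | None = None
    pair_id: np.ndarray | None = None
    matched_id: np.ndarray | None = None
    seq_id: np.ndarray | None = None
    evidence_asymmetry: np.ndarray | None = None
    is_repeated: np.ndarray | None = None

    def __post_init__(self):
        self.beads = np.asarray(self.beads, dtype=int)
        self.ratios = np.asarray(self.ratios, dtype=object)
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.choice_correct = np.asarray(self.choice_correct, dtype=bool)
        if self.beads.ndim != 2 or self.beads.shape[1] != 8:
            raise ValueError("beads must have shape (n_trials, 8)")
        if self.estimates.shape != (len(self.beads), 9):
            raise ValueError("estimates must have shape (n_trials, 9)")

    @property
    def n_trials(self) -> int:
        return len(self.beads)

    @property
    def signed_beads(self) -> np.ndarray:
        return self.beads * 2 - 1

    @property
    def llr(self) -> np.ndarray:
        """Per-trial log likelihood ratio ln(majority/minority)."""
        return np.array([likelihood_logit(r) for r in self.ratios])

    def omega2_vector(self, omega2: dict) -> np.ndarray:
        return np.array([omega2[r] for r in self.ratios])

    def subset(self, mask) -> "ParticipantData":
        mask = np.asarray(mask)
        opt = {
            name: (getattr(self, name)[mask] if getattr(self, name) is not None else None)
            for name in (
                "cursor",
                "majority_color",
                "pair_id",
                "matched_id",
                "seq_id",
                "evidence_asymmetry",
                "is_repeated",
            )
        }
        return ParticipantData(
            self.participant_id,
            self.beads[mask],
            self.ratios[mask],
            self.estimates[mask],
            self.choice_correct[mask],
            **opt,
        )

    def retained(self) -> "ParticipantData":
        """Trials with a correct final choice (the analysis set)."""
        return self.subset(self.choice_correct)

    def condition(self, *labels) -> "ParticipantData":
        return self.subset(np.isin(self.ratios, labels))

    @property
    def start_logits(self) -> np.ndarray:
        """Log-odds of the pre-draw estimate (clipped away from 0/1)."""
        return safe_logit(self.estimates[:, 0])

    @property
    def reported(self) -> np.ndarray:
        """Post-draw reported probabilities, shape (n_trials, 8)."""
        return self.estimates[:, 1:]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, participant_id=None) -> "ParticipantData":
        if participant_id is not None:
            df = df[df["participant_id"] == participant_id]
        elif "participant_id" in df:
            ids = df["participant_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame contains multiple participants; pass participant_id")
            participant_id = ids[0]
        df = df.sort_values("trial_index") if "trial_index" in df else df
        opt = {}
        if set(CURSOR_COLS) <= set(df.columns):
            opt["cursor"] = df[CURSOR_COLS].to_numpy(float)
        for col, name in (
            ("majority_color", "majority_color"),
            ("pair_id", "pair_id"),
            ("matched_id", "matched_id"),
            ("seq_id", "seq_id"),
            ("evidence_asymmetry", "evidence_asymmetry"),
            ("is_repeated", "is_repeated"),
        ):
            if col in df:
                opt[name] = df[col].to_numpy()
        return cls(
            participant_id,
            df[BEAD_COLS].to_numpy(int),
            df["ratio"].to_numpy(object),
            df[EST_COLS].to_numpy(float),
            df["correct"].to_numpy(bool),
            **opt,
        )


@dataclass
class CohortDataset:
    """Per-participant trial data plus participant-level covariates."""

    trials: pd.DataFrame
    participants: pd.DataFrame

    @property
    def participant_ids(self):
        return list(self.participants["participant_id"])

    def participant(self, pid) -> ParticipantData:
        return ParticipantData.from_frame(self.trials, pid)

    def iter_participants(self):
        for pid in self.participant_ids:
            yield pid, self.participant(pid)

    def to_csv(self, trials_path, participants_path):
        self.trials.to_csv(trials_path, index=False)
        self.participants.to_csv(participants_path, index=False)

    @classmethod
    def from_csv(cls, trials_path, participants_path) -> "CohortDataset":
        return cls(pd.read_csv(trials_path), pd.read_csv(participants_path))


def predict_weighted_bayes(data: ParticipantData, omega1: float, omega2: dict) -> np.ndarray:
    """Vectorized deterministic model prediction, shape (n_trials, 8).

    Each trial's starting prior is the participant's own pre-draw estimate;
    updates iterate logit(post_d) = omega1 * logit(post_{d-1}) + omega2(l) *
    s_d * LLR(l). Returned in probability space, clipped to the reportable
    slider range so predictions are commensurate with reported estimates.
    """
    from scipy.special import expit

    w2 = data.omega2_vector(omega2)
    llr = data.llr
    signed = data.signed_beads
    x = data.start_logits.copy()
    out = np.empty((data.n_trials, 8))
    for d in range(8):
        # large weights (bounds allow up to 20) can overflow logit space;
        # the probability is saturated there anyway
        x = np.clip(omega1 * x + w2 * signed[:, d] * llr, -700.0, 700.0)
        out[:, d] = x
    return clip_prob(expit(out))


def predict_heuristic(data: ParticipantData, rule: str, c: float) -> np.ndarray:
    """Vectorized heuristic prediction, shape (n_trials, 8)."""
    signed = data.signed_beads
    if rule == "no_prior":
        return np.where(signed > 0, c, 1 - c).astype(float)
    if rule == "observed_proportion":
        running = np.cumsum(signed, axis=1)
        return np.where(running > 0, c, np.where(running < 0, 1 - c, 0.5)).astype(float)
    raise ValueError(f"unknown heuristic rule {rule!r}")
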