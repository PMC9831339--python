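"""Scoring of the PDI (Peters Delusions Inventory) and the Paranoia Checklist.

The 21-item PDI asks whether an unusual belief is endorsed (yes/no); each
endorsed item is rated 1-5 on distress, preoccupation and conviction. The
item global score is 0 if not endorsed, otherwise 1 + distress +
preoccupation + conviction (range 4-16), and the global score is the sum
over items (range 0-336). Pre-screening group cutoffs derive from published
norms (mean 58.9, SD 48.0): high > mean + 0.5 SD = 82.9, low < mean -
0.5 SD = 34.9.

The 18-item Paranoia Checklist rates each paranoid thought 1-5 on
frequency, conviction and distress; the frequency sub-scale total drives
the secondary screening cutoffs (> 17.15 high, < 6.65 low).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PDI_N_ITEMS = 21
PDI_NORM_MEAN = 58.9
PDI_NORM_SD = 48.0
PDI_HIGH_CUTOFF = PDI_NORM_MEAN + 0.5 * PDI_NORM_SD  # 82.9
PDI_LOW_CUTOFF = PDI_NORM_MEAN - 0.5 * PDI_NORM_SD  # 34.9

PARANOIA_N_ITEMS = 18
PARANOIA_HIGH_CUTOFF = 17.15
PARANOIA_LOW_CUTOFF = 6.65


class QuestionnaireError(ValueError):
    """Malformed questionnaire responses."""


@dataclass
class PDIItem:
    """One PDI item response."""

    endorsed: bool
    distress: int | None = None
    preoccupation: int | None = None
    conviction: int | None = None

    def __post_init__(self):
        subs = (self.distress, self.preoccupation, self.conviction)
        if self.endorsed:
            for v in subs:
                if v is None or not 1 <= int(v) <= 5:
                    raise QuestionnaireError("endorsed items need distress/preoccupation/conviction in 1-5")
        elif any(v is not None for v in subs):
            raise QuestionnaireError("sub-scale ratings present without endorsement")

    @property
    def global_score(self) -> int:
        if not self.endorsed:
            return 0
        return 1 + int(self.distress) + int(self.preoccupation) + int(self.conviction)


def score_pdi(items) -> int:
    """Global PDI score: sum of the 21 item global scores (0-336)."""
    items = [it if isinstance(it, PDIItem) else PDIItem(**it) for it in items]
    if len(items) != PDI_N_ITEMS:
        raise QuestionnaireError(f"PDI requires {PDI_N_ITEMS} items, got {len(items)}")
    return sum(it.global_score for it in items)


def classify(mean_pdi: float) -> str:
    """PDI group from the mean of pre-screening and experimental scores.

    Strict inequalities: exactly at a cutoff is 'intermediate'.
    """
    if not 0 <= mean_pdi <= 336:
        raise QuestionnaireError("PDI score must lie in [0, 336]")
    if mean_pdi > PDI_HIGH_CUTOFF:
        return "high"
    if mean_pdi < PDI_LOW_CUTOFF:
        return "low"
    return "intermediate"


@dataclass
class ParanoiaItem:
    """One Paranoia Checklist item: 1-5 on each sub-scale."""

    frequency: int
    conviction: int
    distress: int

    def __post_init__(self):
        for v in (self.frequency, self.conviction, self.distress):
            if not 1 <= int(v) <= 5:
                raise QuestionnaireError("Paranoia Checklist ratings must lie in 1-5")


def score_paranoia_checklist(items) -> dict:
    """Sub-scale totals and full total of the 18-item Paranoia Checklist."""
    items = [it if isinstance(it, ParanoiaItem) else ParanoiaItem(**it) for it in items]
    if len(items) != PARANOIA_N_ITEMS:
        raise QuestionnaireError(f"Paranoia Checklist requires {PARANOIA_N_ITEMS} items, got {len(items)}")
    freq = sum(it.frequency for it in items)
    conv = sum(it.conviction for it in items)
    dist = sum(it.distress for it in items)
    return {"frequency": freq, "conviction": conv, "distress": dist, "total": freq + conv + dist}


def paranoia_screen(frequency_score: float) -> str:
    """Secondary screening group from the frequency sub-scale total."""
    if frequency_score > PARANOIA_HIGH_CUTOFF:
        return "high"
    if frequency_score < PARANOIA_LOW_CUTOFF:
        return "low"
    return "intermediate"
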