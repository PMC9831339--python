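"""Model-agnostic behavioral measures and nonparametric statistics.

Four per-participant summary measures quantify evidence-order effects and
response variability without reference to any fitted model:

* **mean final estimate difference** — mean over mirror-opposite sequence
  pairs of (back-loaded minus front-loaded) final probability estimate for
  the true box; positive values indicate recency bias.
* **evidence asymmetry slope** — OLS slope of per-pair final-estimate
  differences on the pair's absolute evidence asymmetry, pooled across
  conditions.
* **prior-dependent updating slope** — OLS slope of the logit belief update
  in the direction of the current bead on the logit prior signed with
  respect to that bead's color; negative slopes mean smaller updates to
  prior-consistent evidence (the signature of prior underweighting).
* **response variance** — variance of logit estimates across repeated
  identical sequence fragments (same condition, same colored bead order,
  starting at bead 1), medianed over fragments within condition and
  averaged over conditions; an index of unstructured response variability.

Estimates of exactly 0 or 1 are excluded from all logit computations, and
trials with incorrect final choices are excluded throughout. For the
pair-based and update-based measures, the estimates of the single repeated
sequence are first averaged within participant; the response-variance
measure necessarily uses the raw repeats.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import logit
from .data import ParticipantData

__all__ = [
    "final_estimate_difference",
    "evidence_asymmetry_slope",
    "prior_dependent_slope",
    "response_variance",
    "behavioral_summary",
    "summarize_cohort",
    "signrank_test",
    "ranksum_test",
    "cliffs_delta",
    "spearman",
    "partial_spearman",
]


def _collapse_repeated(data: ParticipantData) -> ParticipantData:
    """Average estimates of the repeated sequence into a single pseudo-trial."""
    if data.is_repeated is None or not np.any(data.is_repeated):
        return data
    rep = np.asarray(data.is_repeated, dtype=bool)
    keep = data.subset(~rep)
    rep_data = data.subset(rep)
    mean_est = rep_data.estimates.mean(axis=0, keepdims=True)
    merged = ParticipantData(
        data.participant_id,
        np.vstack([keep.beads, rep_data.beads[:1]]),
        np.concatenate([keep.ratios, rep_data.ratios[:1]]),
        np.vstack([keep.estimates, mean_est]),
        np.concatenate([keep.choice_correct, [True]]),
        pair_id=None if keep.pair_id is None else np.concatenate([keep.pair_id, rep_data.pair_id[:1]]),
        evidence_asymmetry=None
        if keep.evidence_asymmetry is None
        else np.concatenate([keep.evidence_asymmetry, rep_data.evidence_asymmetry[:1]]),
        is_repeated=np.zeros(keep.n_trials + 1, dtype=bool),
    )
    return merged


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x, with intercept."""
    if len(x) < 2 or np.ptp(x) == 0:
        return np.nan
    return float(np.polyfit(x, y, 1)[0])


def final_estimate_difference(data: ParticipantData):
    """Per-mirror-pair final-estimate differences and their mean.

    Returns a DataFrame with one row per retained pair (columns ``ratio``,
    ``abs_asymmetry``, ``difference``) and the mean difference (NaN when no
    pair survives). A pair is retained only when both members end in a
    correct choice; palindromic sequences have no distinct partner and are
    skipped.
    """
    data = _collapse_repeated(data)
    if data.pair_id is None:
        raise ValueError("pair annotations required for mirror-pair measures")
    rows = []
    df_idx = {}
    for i in range(data.n_trials):
        pid = data.pair_id[i]
        if pid is None or (isinstance(pid, float) and np.isnan(pid)):
            continue
        df_idx.setdefault((data.ratios[i], pid), []).append(i)
    for (ratio, pid), idx in df_idx.items():
        if len(idx) != 2:
            continue
        a, b = idx
        if tuple(data.beads[a]) == tuple(data.beads[b]):
            continue
        if not (data.choice_correct[a] and data.choice_correct[b]):
            continue
        asym_a = float(data.evidence_asymmetry[a])
        front, back = (a, b) if asym_a < float(data.evidence_asymmetry[b]) else (b, a)
        diff = data.estimates[back, 8] - data.estimates[front, 8]
        rows.append(
            {
                "ratio": ratio,
                "pair_id": pid,
                "abs_asymmetry": abs(float(data.evidence_asymmetry[back])),
                "difference": float(diff),
            }
        )
    pairs = pd.DataFrame(rows, columns=["ratio", "pair_id", "abs_asymmetry", "difference"])
    mean = float(pairs["difference"].mean()) if len(pairs) else np.nan
    return pairs, mean


def evidence_asymmetry_slope(pairs: pd.DataFrame) -> float:
    """OLS slope of pair differences on |evidence asymmetry|, pooled."""
    if len(pairs) < 2:
        return np.nan
    return _ols_slope(pairs["abs_asymmetry"].to_numpy(float), pairs["difference"].to_numpy(float))


def prior_dependent_slope(data: ParticipantData, by_condition: bool = False):
    """Slope of the logit belief update on the signed logit prior.

    For each draw, let s = +1 if the current bead matches the color the
    prior favors, else -1. The predictor is s * logit(prior) (the prior
    with respect to the current bead's color) and the response is the logit
    update in the direction of the evidence, s * (logit(post) -
    logit(prior)). Estimates of exactly 0 or 1 — and saturated reports at
    the slider's resolution bounds — are dropped, since their log-odds are
    uninformative. The pooled slope adjusts for bead-ratio condition
    (condition intercepts), because evidence strength sets both the typical
    prior and the typical update size; the ideal observer then has slope 0
    exactly, and prior underweighting gives negative slopes (smaller
    updates to prior-consistent evidence).
    """
    from ._utils import PROB_CEIL, PROB_FLOOR

    data = _collapse_repeated(data).retained()
    xs, us, conds = [], [], []
    for i in range(data.n_trials):
        est = data.estimates[i]
        # tolerance absorbs float error from averaging repeated trials
        valid = (est > PROB_FLOOR + 1e-9) & (est < PROB_CEIL - 1e-9)
        lg = np.where(valid, logit(np.clip(est, 1e-12, 1 - 1e-12)), np.nan)
        signed = data.signed_beads[i]
        for d in range(8):
            if not (valid[d] and valid[d + 1]):
                continue
            s = signed[d]
            xs.append(s * lg[d])
            us.append(s * (lg[d + 1] - lg[d]))
            conds.append(data.ratios[i])
    xs, us, conds = np.array(xs), np.array(us), np.array(conds)
    if by_condition:
        return {c: _ols_slope(xs[conds == c], us[conds == c]) for c in np.unique(conds)}
    levels = np.unique(conds)
    if len(xs) < len(levels) + 1 or np.ptp(xs) == 0:
        return np.nan
    A = np.column_stack([(conds == c).astype(float) for c in levels] + [xs])
    coef, *_ = np.linalg.lstsq(A, us, rcond=None)
    return float(coef[-1])


def response_variance(data: ParticipantData, min_instances: int = 3) -> float:
    """Fragment-matched response variance in logit^2 units.

    Fragments are prefixes (lengths 1..8) identical in bead-ratio condition
    and exact colored bead order, across a participant's retained trials.
    For each fragment with at least ``min_instances`` instantiations, the
    sample variance (n-1 denominator) of the logit estimate at the
    fragment's terminal draw is computed; per condition the median over
    fragments is taken and the conditions' medians are averaged. NaN when
    no condition has a qualifying fragment.
    """
    data = data.retained()
    frags = {}
    for i in range(data.n_trials):
        est = data.estimates[i]
        # fragment identity uses the displayed colors: translate the 0/1
        # majority coding through the trial's majority color when available,
        # and express estimates in a fixed color frame (p(blue box)) so that
        # instantiations with different hidden boxes are comparable
        if data.majority_color is not None:
            mc = data.majority_color[i]
            other = "green" if mc == "blue" else "blue"
            colored = tuple(mc if b == 1 else other for b in data.beads[i])
            p_blue = est if mc == "blue" else 1.0 - est
        else:
            colored = tuple(data.beads[i])
            p_blue = est
        for L in range(1, 9):
            key = (data.ratios[i], colored[:L])
            p = p_blue[L]
            if p <= 0 or p >= 1:
                continue
            frags.setdefault(key, []).append(logit(p))
    per_condition = {}
    for (ratio, prefix), vals in frags.items():
        if len(vals) >= min_instances:
            per_condition.setdefault(ratio, []).append(float(np.var(vals, ddof=1)))
    if not per_condition:
        return np.nan
    medians = [float(np.median(v)) for v in per_condition.values()]
    return float(np.mean(medians))


def behavioral_summary(data: ParticipantData) -> dict:
    """All four model-agnostic measures for one participant."""
    pairs, mean_diff = final_estimate_difference(data)
    return {
        "mean_final_estimate_difference": mean_diff,
        "evidence_asymmetry_slope": evidence_asymmetry_slope(pairs),
        "prior_dependent_slope": prior_dependent_slope(data),
        "response_variance": response_variance(data),
    }


def summarize_cohort(dataset) -> pd.DataFrame:
    """One row of behavioral measures per participant."""
    rows = []
    for pid, pdata in dataset.iter_participants():
        rows.append({"participant_id": pid, **behavioral_summary(pdata)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nonparametric inference


def signrank_test(x, m0: float = 0.0):
    """Two-sided Wilcoxon signed-rank test of the median against m0."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("empty input")
    d = x - m0
    if np.all(d == 0):
        return 0.0, 1.0
    res = sps.wilcoxon(d[d != 0])
    return float(res.statistic), float(res.pvalue)


def ranksum_test(x, y):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between groups."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size: P(x > y) - P(x < y), in [-1, 1]."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(x) * len(y)))


def spearman(x, y):
    """Spearman rank correlation and two-sided p-value."""
    res = sps.spearmanr(x, y, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


def partial_spearman(x, y, Z):
    """Partial Spearman correlation of x and y controlling for Z.

    Rank-transforms all variables, residualizes the ranks of x and y on the
    ranks of Z (with intercept), and returns the Pearson correlation of the
    residuals with its two-sided p-value.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[0] != len(x):
        Z = Z.T
    mask = ~np.isnan(x) & ~np.isnan(y) & ~np.isnan(Z).any(axis=1)
    x, y, Z = x[mask], y[mask], Z[mask]
    if len(x) < Z.shape[1] + 3:
        raise ValueError("too few complete observations")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rZ = np.column_stack([sps.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    A = np.column_stack([np.ones(len(x)), rZ])
    res_x = rx - A @ np.linalg.lstsq(A, rx, rcond=None)[0]
    res_y = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
    r, p = sps.pearsonr(res_x, res_y)
    return float(r), float(p)
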