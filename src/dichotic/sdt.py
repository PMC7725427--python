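"""Signal-detection evaluation of screening tests.

Hits and false alarms here are properties of the *screen*, not the subject:
accepting a subject at a given pass threshold while they used headphones is
a hit; accepting them at the same threshold while they used loudspeakers is
a false alarm.  Sweeping the above-chance thresholds (6, 5, 4, 3 correct
out of 6) traces a receiver operating characteristic (ROC); the area under
it (AUC, trapezoidal with the degenerate accept-none (0,0) and accept-all
(1,1) anchors) summarises how well a test distinguishes equipment, and

    d' = Phi^{-1}(hit) - Phi^{-1}(false alarm)

gives per-threshold sensitivity in standard-normal units.  Differences in
AUC between tests are assessed by bootstrap resampling over subjects and by
a per-subject label-swap permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .protocol import PASS_THRESHOLDS

__all__ = [
    "ScoreHistogram",
    "ROCCurve",
    "ResamplingResult",
    "load_subject_table",
    "subject_scores",
    "pass_rates",
    "roc_curve",
    "roc_curve_combined",
    "auc",
    "dprime",
    "both_scores",
    "score_histogram",
    "bootstrap_auc_diff",
    "permutation_auc_diff",
]

MAX_SCORE = 6

_TABLE_COLUMNS = ("subject_id", "test", "equipment", "n_correct")


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreHistogram:
    """Proportion of subjects at each score 0..6 for one condition."""

    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (MAX_SCORE + 1,):
            raise ValueError("a score histogram has exactly 7 bins (scores 0..6)")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("histogram must be non-negative and sum to 1")
        object.__setattr__(self, "proportions", p)

    @classmethod
    def from_scores(cls, scores: Sequence[int]) -> "ScoreHistogram":
        counts = np.bincount(np.asarray(scores, dtype=int), minlength=MAX_SCORE + 1)
        if counts.size > MAX_SCORE + 1:
            raise ValueError("scores must lie in 0..6")
        return cls(counts / counts.sum())


@dataclass(frozen=True)
class ROCCurve:
    """(false alarm, hit) operating points, sorted by false-alarm rate.

    Includes the accept-none (0,0) and accept-all (1,1) anchors; interior
    points carry their pass-threshold labels.
    """

    false_alarms: np.ndarray
    hits: np.ndarray
    thresholds: tuple

    def __post_init__(self) -> None:
        fa = np.asarray(self.false_alarms, dtype=float)
        hit = np.asarray(self.hits, dtype=float)
        if fa.shape != hit.shape or fa.ndim != 1:
            raise ValueError("hit and false-alarm arrays must align")
        if np.any((fa < 0) | (fa > 1) | (hit < 0) | (hit > 1)):
            raise ValueError("rates must lie in [0, 1]")
        object.__setattr__(self, "false_alarms", fa)
        object.__setattr__(self, "hits", hit)


@dataclass(frozen=True)
class ResamplingResult:
    """Outcome of a bootstrap or permutation comparison of two AUCs."""

    observed_diff: float
    p_value: float
    n_iterations: int
    prop_first_larger: float
    prop_second_larger: float
    diff_mean: float = float("nan")
    diff_sd: float = float("nan")


# --------------------------------------------------------------------------
# Subject tables
# --------------------------------------------------------------------------

def load_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format subject table CSV and validate it."""
    table = pd.read_csv(path)
    return validate_subject_table(table)


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"subject table lacks columns: {sorted(missing)}")
    scores = table["n_correct"]
    if not np.array_equal(scores, scores.astype(int)) or \
            scores.min() < 0 or scores.max() > MAX_SCORE:
        raise ValueError("n_correct must be integers in 0..6")
    return table


def subject_scores(table: pd.DataFrame, test: str) -> tuple[np.ndarray, np.ndarray]:
    """Aligned per-subject (headphone, loudspeaker) score arrays for one test."""
    sub = table[table["test"] == test]
    if sub.empty:
        raise ValueError(f"no rows for test {test!r}")
    wide = sub.pivot_table(index="subject_id", columns="equipment",
                           values="n_correct", aggfunc="first")
    for equipment in ("headphones", "loudspeakers"):
        if equipment not in wide.columns or wide[equipment].isna().any():
            raise ValueError(f"missing {equipment} scores for test {test!r}")
    return (wide["headphones"].to_numpy(dtype=int),
            wide["loudspeakers"].to_numpy(dtype=int))


# --------------------------------------------------------------------------
# ROC / AUC / d'
# --------------------------------------------------------------------------

def pass_rates(table: pd.DataFrame, test: str, threshold: int) -> tuple[float, float]:
    """(hit, false alarm) rates for one test at one pass threshold."""
    if threshold not in PASS_THRESHOLDS:
        raise ValueError(f"threshold must be one of {PASS_THRESHOLDS}")
    h, l = subject_scores(table, test)
    if h.size == 0:
        raise ValueError("empty subject table")
    return float(np.mean(h >= threshold)), float(np.mean(l >= threshold))


def _curve_from_scores(h: np.ndarray, l: np.ndarray) -> ROCCurve:
    hits = [0.0] + [float(np.mean(h >= t)) for t in PASS_THRESHOLDS] + [1.0]
    fas = [0.0] + [float(np.mean(l >= t)) for t in PASS_THRESHOLDS] + [1.0]
    return ROCCurve(np.array(fas), np.array(hits),
                    (None, *PASS_THRESHOLDS, None))


def roc_curve(table: pd.DataFrame, test: str) -> ROCCurve:
    """ROC over pass thresholds 6, 5, 4, 3 for one test, with anchors."""
    h, l = subject_scores(table, test)
    return _curve_from_scores(h, l)


def roc_curve_combined(table: pd.DataFrame, test_a: str, test_b: str) -> ROCCurve:
    """ROC of the "Both" rule: pass iff at or above threshold on both tests."""
    ha, la = subject_scores(table, test_a)
    hb, lb = subject_scores(table, test_b)
    hits = [0.0] + [float(np.mean((ha >= t) & (hb >= t))) for t in PASS_THRESHOLDS] + [1.0]
    fas = [0.0] + [float(np.mean((la >= t) & (lb >= t))) for t in PASS_THRESHOLDS] + [1.0]
    return ROCCurve(np.array(fas), np.array(hits), (None, *PASS_THRESHOLDS, None))


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC, anchors included.

    Raises ``ValueError`` if the curve is not monotone non-decreasing in
    both coordinates as the threshold drops.
    """
    fa, hit = curve.false_alarms, curve.hits
    if np.any(np.diff(fa) < -1e-12) or np.any(np.diff(hit) < -1e-12):
        raise ValueError("ROC points must be non-decreasing in both rates")
    return float(np.trapezoid(hit, fa))


def dprime(hit: float, false_alarm: float, n_subjects: int | None = None) -> float:
    """Sensitivity index d' = Phi^{-1}(hit) - Phi^{-1}(false alarm).

    With ``n_subjects`` given, extreme rates are clipped to 1/(2N) and
    1 - 1/(2N) before quantile inversion; without it, rates of exactly 0 or
    1 yield infinite d'.
    """
    if not (0 <= hit <= 1 and 0 <= false_alarm <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_subjects is not None:
        lo, hi = 1.0 / (2 * n_subjects), 1.0 - 1.0 / (2 * n_subjects)
        hit = min(max(hit, lo), hi)
        false_alarm = min(max(false_alarm, lo), hi)
    return float(norm.ppf(hit) - norm.ppf(false_alarm))


def both_scores(table: pd.DataFrame, test_a: str, test_b: str,
                threshold: int) -> pd.DataFrame:
    """Per-subject "Both" pass indicators, one column per equipment condition."""
    ha, la = subject_scores(table, test_a)
    hb, lb = subject_scores(table, test_b)
    subjects = sorted(table.loc[table["test"] == test_a, "subject_id"].unique())
    return pd.DataFrame({
        "headphones": (ha >= threshold) & (hb >= threshold),
        "loudspeakers": (la >= threshold) & (lb >= threshold),
    }, index=pd.Index(subjects, name="subject_id"))


def score_histogram(table: pd.DataFrame, test: str, equipment: str) -> ScoreHistogram:
    """Observed score distribution (proportions over 0..6) for one condition."""
    sub = table[(table["test"] == test) & (table["equipment"] == equipment)]
    if sub.empty:
        raise ValueError(f"no rows for ({test!r}, {equipment!r})")
    return ScoreHistogram.from_scores(sub["n_correct"].to_numpy())


# --------------------------------------------------------------------------
# Resampling inference on AUC differences
# --------------------------------------------------------------------------

def _auc_matrix(h: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Vectorised trapezoidal AUC for stacked score matrices (m, n) -> (m,)."""
    parts_h = [np.zeros(h.shape[0])]
    parts_f = [np.zeros(h.shape[0])]
    for t in PASS_THRESHOLDS:
        parts_h.append(np.mean(h >= t, axis=1))
        parts_f.append(np.mean(l >= t, axis=1))
    parts_h.append(np.ones(h.shape[0]))
    parts_f.append(np.ones(h.shape[0]))
    hits = np.column_stack(parts_h)
    fas = np.column_stack(parts_f)
    return np.trapezoid(hits, fas, axis=1)


def _paired_scores(table: pd.DataFrame, test_a: str, test_b: str):
    ha, la = subject_scores(table, test_a)
    hb, lb = subject_scores(table, test_b)
    if ha.size != hb.size:
        raise ValueError("tests cover different subject sets")
    if ha.size < 2:
        raise ValueError("at least two subjects are required")
    return ha, la, hb, lb


def bootstrap_auc_diff(table: pd.DataFrame, test_a: str, test_b: str,
                       n_resamples: int = 10_000, seed=None) -> ResamplingResult:
    """Bootstrap the AUC difference (test_a - test_b) over subjects.

    Whole subjects (all four condition scores together) are resampled with
    replacement at the original cohort size.  The two-sided p-value is twice
    the smaller directional exceedance proportion (resampled differences
    strictly above / below zero; exact zeros count in neither direction),
    floored at 1/n_resamples and capped at 1.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    ha, la, hb, lb = _paired_scores(table, test_a, test_b)
    n = ha.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(n, size=(n_resamples, n))
    diffs = _auc_matrix(ha[idx], la[idx]) - _auc_matrix(hb[idx], lb[idx])
    prop_pos = float(np.mean(diffs > 0))
    prop_neg = float(np.mean(diffs < 0))
    p = min(1.0, max(2.0 * min(prop_pos, prop_neg), 1.0 / n_resamples))
    observed = (_auc_matrix(ha[None], la[None])[0]
                - _auc_matrix(hb[None], lb[None])[0])
    return ResamplingResult(observed_diff=float(observed), p_value=p,
                            n_iterations=n_resamples,
                            prop_first_larger=prop_pos,
                            prop_second_larger=prop_neg,
                            diff_mean=float(np.mean(diffs)),
                            diff_sd=float(np.std(diffs)))


def permutation_auc_diff(table: pd.DataFrame, test_a: str, test_b: str,
                         n_perms: int = 10_000, seed=None) -> ResamplingResult:
    """Label-swap permutation test of the AUC difference (test_a - test_b).

    Under the null that the two tests are exchangeable, each permutation
    independently swaps (or keeps) the two tests' headphone scores per
    subject, and likewise the loudspeaker scores.  The two-sided p-value is
    twice the smaller directional proportion of null differences at least as
    extreme as the observed one (ties count as extreme), capped at 1 and
    floored at 1/n_perms.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be at least 1")
    ha, la, hb, lb = _paired_scores(table, test_a, test_b)
    n = ha.size
    rng = np.random.default_rng(seed)
    swap_h = rng.random((n_perms, n)) < 0.5
    swap_l = rng.random((n_perms, n)) < 0.5
    ha_p = np.where(swap_h, hb, ha)
    hb_p = np.where(swap_h, ha, hb)
    la_p = np.where(swap_l, lb, la)
    lb_p = np.where(swap_l, la, lb)
    null = _auc_matrix(ha_p, la_p) - _auc_matrix(hb_p, lb_p)
    observed = (_auc_matrix(ha[None], la[None])[0]
                - _auc_matrix(hb[None], lb[None])[0])
    prop_ge = float(np.mean(null >= observed))
    prop_le = float(np.mean(null <= observed))
    p = min(1.0, max(2.0 * min(prop_ge, prop_le), 1.0 / n_perms))
    return ResamplingResult(observed_diff=float(observed), p_value=p,
                            n_iterations=n_perms,
                            prop_first_larger=prop_ge,
                            prop_second_larger=prop_le,
                            diff_mean=float(np.mean(null)),
                            diff_sd=float(np.std(null)))
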