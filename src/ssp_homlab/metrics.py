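"""Accuracy measures and statistical machinery for SSP evaluation.

Two per-protein accuracies are computed: the residue fraction Q and the
segment-overlap score SOV (the 1999 revision, the field standard).  Over a
set of query proteins they are aggregated as the residue micro-average

    Q_micro = sum_q Nres_a(q) / sum_q len_q

and the length-weighted SOV

    SOV_bar = sum_q len_q * SOV_q / sum_q len_q,

both of which avoid over-weighting short proteins relative to the
conventional per-protein arithmetic mean.

Group comparisons follow a normality-gated cascade: Shapiro-Wilk on each
sample, then an F test for variance equality, then Student's t (equal
variances) or Welch's t.  Pearson's r is used for entropy/accuracy trends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .alphabet import ss8_to_ss3  # noqa: F401  (re-exported: part of this module's API)


@dataclass(frozen=True)
class PerProteinScore:
    q_id: str
    length: int
    n_correct: int
    q: float
    sov: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.length:
            raise ValueError("correct-residue count out of range")


@dataclass
class EvalReport:
    """Aggregated accuracies for one query group in one repeat."""

    group: str
    scores: list[PerProteinScore]
    repeat: int = 0

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def micro_q(self) -> float:
        return micro_q(self.scores)

    @property
    def weighted_sov(self) -> float:
        return weighted_sov(self.scores)


def q_accuracy(pred: str, true: str) -> tuple[int, float]:
    """Positional match count and fraction."""
    if len(pred) != len(true):
        raise ValueError("prediction/truth length mismatch")
    if not true:
        raise ValueError("empty strings")
    n_correct = sum(p == t for p, t in zip(pred, true))
    return n_correct, n_correct / len(true)


def _segments(s: str, state: str) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` as (start, end) half-open intervals."""
    out = []
    start = None
    for i, c in enumerate(s):
        if c == state and start is None:
            start = i
        elif c != state and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(s)))
    return out


def sov(pred: str, true: str, states: Optional[str] = None) -> float:
    """Segment-overlap score (SOV'99) in [0, 100], pooled over states.

    For every observed segment s1 and each predicted segment s2 of the same
    state that overlaps it, the pair contributes
    ``(minov + delta) / maxov * len(s1)`` where minov is the overlap, maxov
    the span of the union, and the allowance
    ``delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2)``.
    The normaliser counts len(s1) once per overlapping pair, and once for
    each observed segment with no overlapping partner.
    """
    if len(pred) != len(true):
        raise ValueError("prediction/truth length mismatch")
    if states is None:
        states = "".join(sorted(set(true) | set(pred)))
    total = 0.0
    norm = 0
    for state in states:
        true_segs = _segments(true, state)
        pred_segs = _segments(pred, state)
        for t0, t1 in true_segs:
            len1 = t1 - t0
            overlapped = False
            for p0, p1 in pred_segs:
                minov = min(t1, p1) - max(t0, p0)
                if minov <= 0:
                    continue
                overlapped = True
                maxov = max(t1, p1) - min(t0, p0)
                len2 = p1 - p0
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                total += (minov + delta) / maxov * len1
                norm += len1
            if not overlapped:
                norm += len1
    if norm == 0:
        return 100.0  # no segments of any scored state on either side
    return 100.0 * total / norm


def micro_q(scores: Sequence[PerProteinScore]) -> float:
    """Residue micro-average: pooled correct residues over pooled length."""
    if not scores:
        raise ValueError("empty score collection")
    return sum(s.n_correct for s in scores) / sum(s.length for s in scores)


def weighted_sov(scores: Sequence[PerProteinScore]) -> float:
    """Length-weighted mean SOV over proteins."""
    if not scores:
        raise ValueError("empty score collection")
    return sum(s.length * s.sov for s in scores) / sum(s.length for s in scores)


def score_protein(q_id: str, pred: str, true: str, states: str = "HEC") -> PerProteinScore:
    n_correct, q = q_accuracy(pred, true)
    return PerProteinScore(
        q_id=q_id, length=len(true), n_correct=n_correct, q=q,
        sov=sov(pred, true, states),
    )


# ---------------------------------------------------------------------------
# Statistics

@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    shapiro_p: tuple[float, float] = (float("nan"), float("nan"))


def compare_groups(x: Sequence[float], y: Sequence[float], alpha: float = 0.05):
    """Normality-gated two-sample comparison; returns (test name, stat, p).

    Shapiro-Wilk on each sample decides normality; for normal samples an F
    test decides between Student's and Welch's t.  Non-normal samples fall
    back to Welch's t (robust default), with the test name recording that
    normality failed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        # Degenerate identical constants: no evidence of difference.
        return GroupComparison("student-t", 0.0, 1.0, (1.0, 1.0))
    sw_x = 1.0 if np.ptp(x) == 0 else stats.shapiro(x).pvalue
    sw_y = 1.0 if np.ptp(y) == 0 else stats.shapiro(y).pvalue
    normal = sw_x > alpha and sw_y > alpha
    if normal:
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vy == 0 and vx == 0:
            equal_var = True
        else:
            f_stat = vx / vy if vy > 0 else np.inf
            dfx, dfy = x.size - 1, y.size - 1
            p_f = 2 * min(
                stats.f.cdf(f_stat, dfx, dfy), stats.f.sf(f_stat, dfx, dfy)
            )
            equal_var = p_f > alpha
        if equal_var:
            res = stats.ttest_ind(x, y, equal_var=True)
            return GroupComparison("student-t", float(res.statistic), float(res.pvalue), (sw_x, sw_y))
        res = stats.ttest_ind(x, y, equal_var=False)
        return GroupComparison("welch-t", float(res.statistic), float(res.pvalue), (sw_x, sw_y))
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison("welch-t-nonnormal", float(res.statistic), float(res.pvalue), (sw_x, sw_y))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance sample")
    return float(stats.pearsonr(x, y).statistic)
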