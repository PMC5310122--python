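"""Scoring called intervals against planted truth, and threshold sweeps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import FilterConfig, QtlInterval, call_qtl_sites, merge_intervals

__all__ = ["TruthQtl", "TruthSet", "RecoveryReport", "match_intervals", "threshold_sweep"]


@dataclass(frozen=True)
class TruthQtl:
    chrom: str
    pos: int
    effect: float


@dataclass(frozen=True)
class TruthSet:
    qtls: tuple[TruthQtl, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtls", tuple(
            q if isinstance(q, TruthQtl) else TruthQtl(*q) for q in self.qtls
        ))

    def __len__(self) -> int:
        return len(self.qtls)


@dataclass(frozen=True)
class RecoveryReport:
    tp: int
    fp: int
    fn: int
    matches: tuple[tuple[int, int], ...]  # (truth index, interval index)

    @property
    def power(self) -> float:
        return self.tp / max(1, self.tp + self.fn)

    @property
    def fdr(self) -> float:
        return self.fp / max(1, self.tp + self.fp)


def _distance(iv: QtlInterval, pos: int) -> int:
    if iv.start <= pos <= iv.end:
        return 0
    return min(abs(iv.start - pos), abs(iv.end - pos))


def match_intervals(
    intervals: list[QtlInterval], truth: TruthSet, tolerance: int = 50_000,
) -> RecoveryReport:
    """One-to-one truth/interval assignment by genomic proximity.

    A truth QTL can match an interval on the same chromosome overlapping
    [pos - tolerance, pos + tolerance].  Among assignments with the maximum
    number of matches the one minimising total truth-to-interval distance is
    taken (Hungarian algorithm), so the result equals exhaustive enumeration
    and is invariant to input ordering.  Unmatched intervals are false
    positives, unmatched truths false negatives.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    n_t, n_i = len(truth), len(intervals)
    matches: list[tuple[int, int]] = []
    if n_t and n_i:
        from scipy.optimize import linear_sum_assignment

        big = 10.0**15  # dominates any genomic distance: minimising cost
        cost = np.full((n_t, n_i), big)
        for ti, tq in enumerate(truth.qtls):
            for ii, iv in enumerate(intervals):
                if iv.chrom != tq.chrom:
                    continue
                if iv.end >= tq.pos - tolerance and iv.start <= tq.pos + tolerance:
                    cost[ti, ii] = _distance(iv, tq.pos)
        rows, cols = linear_sum_assignment(cost)
        matches = [(int(t), int(i)) for t, i in zip(rows, cols) if cost[t, i] < big]
    tp = len(matches)
    return RecoveryReport(tp, n_i - tp, n_t - tp, tuple(sorted(matches)))


def threshold_sweep(
    deltas: list[pd.DataFrame],
    truth: TruthSet,
    thresholds: list[float],
    base_cfg: FilterConfig = FilterConfig(),
    max_gap: int = 25_000,
    min_sites: int = 3,
    tolerance: int = 50_000,
) -> pd.DataFrame:
    """Re-run call/merge/match over a grid of delta-AF thresholds."""
    if not thresholds:
        raise ValueError("threshold grid must be non-empty")
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    rows = []
    for thr in sorted(thresholds):
        cfg = FilterConfig(base_cfg.min_depth, base_cfg.af_band, thr)
        calls = call_qtl_sites(deltas, cfg)
        intervals = merge_intervals(calls, max_gap=max_gap, min_sites=min_sites)
        rep = match_intervals(intervals, truth, tolerance=tolerance)
        rows.append((thr, rep.power, rep.fdr, len(intervals)))
    return pd.DataFrame(rows, columns=["threshold", "power", "fdr", "n_intervals"])
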