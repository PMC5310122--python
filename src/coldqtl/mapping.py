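"""Allele-frequency-change QTL calling from pooled allele counts.

The caller applies three threshold rules, all inclusive:

1. coverage — a site needs >= ``min_depth`` reads in the initial pool and in
   every selected pool;
2. segregation band — the initial-pool parent-A frequency must lie inside
   ``af_band`` (default [0.30, 0.70]);
3. change — every replicate's frequency change from initial to selected must
   be at least ``delta_threshold`` in magnitude and all replicates must agree
   in sign.

Called sites are then clustered into intervals (same direction, inter-site
gap <= max_gap, >= min_sites members) and flagged as subtelomeric when they
fall within a terminal window of their chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .poolseq import PoolCounts

__all__ = [
    "FilterConfig",
    "QtlSiteCall",
    "QtlInterval",
    "allele_frequency",
    "filter_sites",
    "delta_af",
    "call_qtl_sites",
    "merge_intervals",
    "annotate_subtelomeric",
    "map_qtls",
    "write_intervals_tsv",
    "write_intervals_bed",
]


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 30
    af_band: tuple[float, float] = (0.30, 0.70)
    delta_threshold: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.af_band
        if not 0 <= lo <= hi <= 1:
            raise ValueError("af_band must satisfy 0 <= low <= high <= 1")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.delta_threshold <= 1:
            raise ValueError("delta_threshold must be in (0, 1]")


@dataclass(frozen=True)
class QtlSiteCall:
    chrom: str
    pos: int
    delta_af: tuple[float, ...]  # one signed value per replicate
    direction: int  # +1: parent-A allele rises; -1: falls

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class QtlInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_sites: int
    mean_abs_delta: float
    direction: int
    subtelomeric: bool | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")


# ---------------------------------------------------------------------------
# per-pool frequencies


def allele_frequency(counts: PoolCounts) -> pd.DataFrame:
    """Per-site parent-A frequency and depth; af is NaN where depth is 0."""
    df = counts.df
    depth = (df["count_A"] + df["count_B"]).to_numpy()
    with np.errstate(invalid="ignore"):
        af = np.where(depth > 0, df["count_A"].to_numpy() / np.maximum(depth, 1), np.nan)
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["pos"], "af": af, "depth": depth})


def _indexed(records: pd.DataFrame) -> pd.DataFrame:
    df = records.set_index(["chrom", "pos"])
    if df.index.has_duplicates:
        raise ValueError("duplicate (chrom, pos) sites in frequency records")
    return df


def filter_sites(
    initial: pd.DataFrame, selected_pools: list[pd.DataFrame], cfg: FilterConfig,
) -> pd.DataFrame:
    """Sites retained by the coverage and initial-band rules (outer-join).

    Missing sites count as depth 0.  Returns a frame indexed by (chrom, pos)
    with columns af_initial, depth_initial, af_sel_r<k>, depth_sel_r<k>.
    """
    if not selected_pools:
        raise ValueError("need at least one selected pool")
    init = _indexed(initial).rename(columns={"af": "af_initial", "depth": "depth_initial"})
    universe = init.index
    frames = [init]
    for r, sel in enumerate(selected_pools, start=1):
        s = _indexed(sel).rename(columns={"af": f"af_sel_r{r}", "depth": f"depth_sel_r{r}"})
        universe = universe.union(s.index)
        frames.append(s)
    if len(universe) == 0:
        raise ValueError("empty site universe")
    joined = pd.concat([f.reindex(universe) for f in frames], axis=1)
    depth_cols = ["depth_initial"] + [f"depth_sel_r{r}" for r in range(1, len(selected_pools) + 1)]
    joined[depth_cols] = joined[depth_cols].fillna(0).astype(np.int64)
    lo, hi = cfg.af_band
    keep = np.ones(len(joined), dtype=bool)
    for c in depth_cols:
        keep &= joined[c].to_numpy() >= cfg.min_depth
    af0 = joined["af_initial"].to_numpy()
    keep &= np.isfinite(af0) & (af0 >= lo) & (af0 <= hi)
    out = joined[keep].sort_index()
    return out


def delta_af(initial: pd.DataFrame, selected: pd.DataFrame) -> pd.DataFrame:
    """Signed per-site frequency change, selected minus initial (parent-A).

    Both inputs are (chrom, pos, af, ...) frames over the same retained
    sites; a site missing from either is an error.
    """
    a = _indexed(initial[["chrom", "pos", "af"]])
    b = _indexed(selected[["chrom", "pos", "af"]])
    if not a.index.equals(b.index):
        missing = a.index.symmetric_difference(b.index)
        raise ValueError(f"pools disagree on {len(missing)} sites (e.g. {missing[:3].tolist()})")
    out = pd.DataFrame(index=a.index)
    out["delta_af"] = b["af"] - a["af"]
    return out.reset_index()


def call_qtl_sites(deltas: list[pd.DataFrame], cfg: FilterConfig) -> list[QtlSiteCall]:
    """Sites where every replicate moved >= delta_threshold in one direction."""
    if not deltas:
        raise ValueError("need at least one replicate delta table")
    idx_frames = [_indexed(d[["chrom", "pos", "delta_af"]]) for d in deltas]
    base = idx_frames[0].index
    for f in idx_frames[1:]:
        if not f.index.equals(base):
            raise ValueError("replicate delta tables must share one retained site set")
    mat = np.column_stack([f["delta_af"].to_numpy() for f in idx_frames])
    thr = cfg.delta_threshold
    up = np.all(mat >= thr, axis=1)
    down = np.all(mat <= -thr, axis=1)
    calls = []
    for (chrom, pos), row, is_up in zip(base[up | down], mat[up | down], up[up | down]):
        calls.append(QtlSiteCall(str(chrom), int(pos), tuple(float(x) for x in row),
                                 1 if is_up else -1))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def merge_intervals(
    calls: list[QtlSiteCall], max_gap: int = 25_000, min_sites: int = 3,
    condition: str = "",
) -> list[QtlInterval]:
    """Cluster same-direction calls with inter-site gaps <= max_gap.

    Clusters with fewer than ``min_sites`` member sites are discarded;
    interval bounds are the first and last member positions (1-based,
    inclusive).
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos))
    intervals: list[QtlInterval] = []
    cluster: list[QtlSiteCall] = []

    def flush() -> None:
        if len(cluster) >= min_sites:
            deltas = [abs(d) for c in cluster for d in c.delta_af]
            intervals.append(QtlInterval(
                cluster[0].chrom, cluster[0].pos, cluster[-1].pos,
                len(cluster), float(np.mean(deltas)), cluster[0].direction,
                condition=condition,
            ))

    for call in ordered:
        if cluster and (
            call.chrom != cluster[-1].chrom
            or call.direction != cluster[-1].direction
            or call.pos - cluster[-1].pos > max_gap
        ):
            flush()
            cluster = []
        cluster.append(call)
    if cluster:
        flush()
    return intervals


def annotate_subtelomeric(
    intervals: list[QtlInterval], chrom_lengths: dict[str, int], window: int = 30_000,
) -> list[QtlInterval]:
    """Flag intervals lying within ``window`` bp of either chromosome end.

    Subtelomeric iff start <= window or end >= length - window + 1 (inclusive).
    """
    out = []
    for iv in intervals:
        if iv.chrom not in chrom_lengths:
            raise KeyError(f"no length for chromosome {iv.chrom!r}")
        length = chrom_lengths[iv.chrom]
        if iv.end > length:
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end {length}")
        flag = iv.start <= window or iv.end >= length - window + 1
        out.append(replace(iv, subtelomeric=flag))
    return out


# ---------------------------------------------------------------------------
# orchestration and export


def map_qtls(
    initial_counts: pd.DataFrame | PoolCounts,
    selected_counts: list[PoolCounts],
    cfg: FilterConfig,
    chrom_lengths: dict[str, int] | None = None,
    max_gap: int = 25_000,
    min_sites: int = 3,
    subtelomere_window: int = 30_000,
    condition: str = "",
    initial_counts_per_replicate: list[PoolCounts] | None = None,
):
    """Full caller: filter -> delta per replicate -> call -> merge -> annotate.

    ``initial_counts_per_replicate`` supplies one baseline sequencing library
    per replicate (paired design); otherwise the single ``initial_counts``
    library serves every replicate.  The first baseline library also defines
    the 30-70% segregation band.  Returns (retained, deltas, calls, intervals).
    """
    if initial_counts_per_replicate is not None:
        if len(initial_counts_per_replicate) != len(selected_counts):
            raise ValueError("need one baseline library per replicate")
        baselines = [allele_frequency(c) for c in initial_counts_per_replicate]
    else:
        if isinstance(initial_counts, PoolCounts):
            initial_counts = allele_frequency(initial_counts)
        baselines = [initial_counts] * len(selected_counts)
    selected = [allele_frequency(c) for c in selected_counts]
    retained = filter_sites(baselines[0], selected + baselines[1:], cfg)
    keep = retained.index
    deltas = []
    for base, sel in zip(baselines, selected):
        b = _indexed(base).reindex(keep).reset_index()
        s = _indexed(sel).reindex(keep).reset_index()
        deltas.append(delta_af(b[["chrom", "pos", "af"]], s[["chrom", "pos", "af"]]))
    calls = call_qtl_sites(deltas, cfg)
    intervals = merge_intervals(calls, max_gap=max_gap, min_sites=min_sites, condition=condition)
    if chrom_lengths is not None:
        intervals = annotate_subtelomeric(intervals, chrom_lengths, window=subtelomere_window)
    return retained, deltas, calls, intervals


def intervals_frame(intervals: list[QtlInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (iv.chrom, iv.start, iv.end, iv.n_sites, iv.mean_abs_delta, iv.direction,
             iv.subtelomeric, iv.condition)
            for iv in intervals
        ],
        columns=["chrom", "start", "end", "n_sites", "mean_abs_delta", "direction",
                 "subtelomeric", "condition"],
    )


def write_intervals_tsv(intervals: list[QtlInterval], path: str | Path) -> None:
    """1-based inclusive interval report."""
    intervals_frame(intervals).to_csv(path, sep="\t", index=False)


def write_intervals_bed(intervals: list[QtlInterval], path: str | Path) -> None:
    """BED (0-based half-open); score = 1000 * mean |dAF|, capped at 1000."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(min(1000, round(1000 * iv.mean_abs_delta)))
            name = iv.condition or "qtl"
            strand = "+" if iv.direction > 0 else "-"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t{strand}\n")
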