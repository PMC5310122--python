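"""Pooled-sequencing simulation and allele-count table I/O.

Converts a population's true per-site parent-A allele frequencies into read
counts: depth ~ Poisson(mean) (or negative binomial when overdispersed) and
count_A ~ Binomial(depth, p') with the symmetric miscall model
p' = p(1-e) + (1-p)e.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoolSpec",
    "PoolCounts",
    "simulate_pool_counts",
    "write_counts_table",
    "read_counts_table",
    "read_vcf_counts",
]

_COLUMNS = ["chrom", "pos", "count_A", "count_B"]


@dataclass(frozen=True)
class PoolSpec:
    """Sequencing model for one pool.

    ``overdispersion`` (when set) switches the depth model to a negative
    binomial with variance mean + mean^2/overdispersion.
    """

    pool_id: str
    mean_depth: float = 100.0
    error_rate: float = 0.005
    seed: int = 0
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")


@dataclass
class PoolCounts:
    """Per-site allele counts for one pool (columns chrom, pos, count_A, count_B)."""

    df: pd.DataFrame
    pool_id: str = "pool"

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["count_A"] = df["count_A"].astype(np.int64)
        df["count_B"] = df["count_B"].astype(np.int64)
        if (df["count_A"] < 0).any() or (df["count_B"] < 0).any():
            raise ValueError("counts must be non-negative")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) sites")
        self.df = df.reset_index(drop=True)

    @property
    def depth(self) -> pd.Series:
        return self.df["count_A"] + self.df["count_B"]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoolCounts):
            return NotImplemented
        a = self.df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        b = other.df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        return self.pool_id == other.pool_id and a.equals(b)


def simulate_pool_counts(true_freqs: pd.DataFrame, spec: PoolSpec) -> PoolCounts:
    """Sample read counts at every site of ``true_freqs`` (chrom, pos, freq)."""
    p = np.asarray(true_freqs["freq"], dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("true frequencies must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n = len(p)
    if spec.overdispersion is None:
        depth = rng.poisson(spec.mean_depth, size=n)
    else:
        k = spec.overdispersion
        depth = rng.negative_binomial(k, k / (k + spec.mean_depth), size=n)
    e = spec.error_rate
    p_obs = p * (1 - e) + (1 - p) * e
    count_a = rng.binomial(depth, p_obs)
    df = pd.DataFrame(
        {
            "chrom": true_freqs["chrom"].to_numpy(),
            "pos": true_freqs["pos"].to_numpy(),
            "count_A": count_a,
            "count_B": depth - count_a,
        }
    )
    return PoolCounts(df, spec.pool_id)


def write_counts_table(counts: PoolCounts, path: str | Path) -> None:
    """Canonical TSV, header chrom/pos/count_A/count_B, sorted by chrom, pos."""
    df = counts.df.sort_values(["chrom", "pos"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path, pool_id: str | None = None) -> PoolCounts:
    """Parse a counts TSV; malformed rows raise with the offending line number."""
    path = Path(path)
    rows = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != _COLUMNS:
            expected = "\t".join(_COLUMNS)
            raise ValueError(f"{path}:1: expected header {expected!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                pos, ca, cb = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer field") from None
            if ca < 0 or cb < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if (chrom, pos) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate site {chrom}:{pos}")
            seen.add((chrom, pos))
            rows.append((chrom, pos, ca, cb))
    df = pd.DataFrame(rows, columns=_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=t) for c, t in zip(_COLUMNS, [str, np.int64, np.int64, np.int64])}
    )
    return PoolCounts(df, pool_id or path.stem)


def read_vcf_counts(path: str | Path, sample: str | None = None, pool_id: str | None = None) -> PoolCounts:
    """Read per-sample allelic depths (FORMAT/AD) from a biallelic VCF.

    REF is taken as the parent-A allele.  One sample = one pool; ``sample``
    defaults to the only sample in the file.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise ValueError(f"VCF has {len(samples)} samples; specify one")
            sample = samples[0]
        elif sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.chrom}:{rec.pos}: site is not biallelic")
            ad = rec.samples[sample].get("AD")
            if ad is None or len(ad) < 2:
                raise ValueError(f"{rec.chrom}:{rec.pos}: missing FORMAT/AD")
            rows.append((rec.chrom, rec.pos, int(ad[0]), int(ad[1])))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return PoolCounts(df, pool_id or sample)
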