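"""Marker maps: biallelic marker positions with genetic (cM) coordinates.

A :class:`MarkerMap` is the coordinate backbone for the cross simulator and
the QTL caller.  Markers live on named chromosomes at 1-based physical
positions (bp) and carry a genetic position in centimorgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MarkerMap", "build_marker_map", "read_marker_map", "write_marker_map"]


@dataclass(frozen=True)
class MarkerMap:
    """Ordered chromosomes, each with sorted marker positions (bp) and cM.

    Parameters
    ----------
    chrom_names
        Chromosome names, in genome order.  Must be unique.
    chrom_lengths
        Physical length in bp of each chromosome.
    positions
        Per chromosome, strictly increasing 1-based marker positions (bp).
    cm
        Per chromosome, non-decreasing genetic positions in centimorgans.
    chrom_cm
        Total genetic length (cM) of each chromosome; defaults to the last
        marker's cM position when not given.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: np.ndarray
    positions: tuple[np.ndarray, ...]
    cm: tuple[np.ndarray, ...]
    chrom_cm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if np.any(lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if not (len(names) == len(lengths) == len(self.positions) == len(self.cm)):
            raise ValueError("per-chromosome field lengths disagree")
        positions = tuple(np.asarray(p, dtype=np.int64) for p in self.positions)
        cms = tuple(np.asarray(c, dtype=np.float64) for c in self.cm)
        for name, length, pos, cm in zip(names, lengths, positions, cms):
            if len(pos) != len(cm):
                raise ValueError(f"{name}: positions and cM differ in length")
            if len(pos) and (pos[0] < 1 or pos[-1] > length):
                raise ValueError(f"{name}: marker positions outside [1, {length}]")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{name}: marker positions not strictly increasing")
            if np.any(cm < 0) or np.any(np.diff(cm) < 0):
                raise ValueError(f"{name}: genetic positions must be non-decreasing and >= 0")
        chrom_cm = self.chrom_cm
        if chrom_cm is None:
            chrom_cm = np.array([c[-1] if len(c) else 0.0 for c in cms])
        chrom_cm = np.asarray(chrom_cm, dtype=np.float64)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "cm", cms)
        object.__setattr__(self, "chrom_cm", chrom_cm)

    # -- derived geometry -------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions))

    @property
    def offsets(self) -> np.ndarray:
        """Start index of each chromosome in the concatenated marker vector."""
        counts = [len(p) for p in self.positions]
        return np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    def chrom_slice(self, i: int) -> slice:
        off = self.offsets
        return slice(int(off[i]), int(off[i + 1]))

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def global_index(self, chrom: str, marker_index: int) -> int:
        i = self.chrom_index(chrom)
        if not 0 <= marker_index < len(self.positions[i]):
            raise IndexError(f"marker index {marker_index} out of range on {chrom}")
        return int(self.offsets[i]) + marker_index

    def site_frame(self) -> pd.DataFrame:
        """All markers as a DataFrame with columns chrom, pos, cM."""
        return pd.DataFrame(
            {
                "chrom": np.repeat(self.chrom_names, [len(p) for p in self.positions]),
                "pos": np.concatenate(self.positions) if self.n_markers else np.array([], dtype=np.int64),
                "cM": np.concatenate(self.cm) if self.n_markers else np.array([]),
            }
        )

    def chrom_length_dict(self) -> dict[str, int]:
        return {n: int(l) for n, l in zip(self.chrom_names, self.chrom_lengths)}

    @property
    def total_cm(self) -> float:
        return float(self.chrom_cm.sum())


def build_marker_map(
    chrom_lengths: list[int],
    markers_per_chrom: int,
    cM_per_Mb: float,
    seed: int,
    chrom_names: list[str] | None = None,
) -> MarkerMap:
    """Place markers uniformly at random on each chromosome.

    Positions are sampled without replacement (so exactly ``markers_per_chrom``
    distinct sites per chromosome), sorted, and mapped to genetic coordinates
    with a constant rate: cM = bp * cM_per_Mb / 1e6.  Deterministic for a
    fixed seed.
    """
    if markers_per_chrom < 1:
        raise ValueError("markers_per_chrom must be >= 1")
    if cM_per_Mb <= 0:
        raise ValueError("cM_per_Mb must be positive")
    lengths = [int(l) for l in chrom_lengths]
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if chrom_names is None:
        chrom_names = [f"chr{i + 1:02d}" for i in range(len(lengths))]
    if len(set(chrom_names)) != len(chrom_names):
        raise ValueError("duplicate chromosome names")
    rng = np.random.default_rng(seed)
    positions, cms = [], []
    for length in lengths:
        if markers_per_chrom > length:
            raise ValueError("more markers than available positions")
        pos = np.sort(rng.choice(length, size=markers_per_chrom, replace=False)) + 1
        positions.append(pos.astype(np.int64))
        cms.append(pos * cM_per_Mb / 1e6)
    chrom_cm = np.array(lengths, dtype=np.float64) * cM_per_Mb / 1e6
    return MarkerMap(tuple(chrom_names), np.array(lengths), tuple(positions), tuple(cms), chrom_cm)


def write_marker_map(mm: MarkerMap, path: str | Path) -> None:
    """TSV with header chrom, pos, cM (chromosome lengths as # header lines)."""
    with open(path, "w") as fh:
        for name, length in zip(mm.chrom_names, mm.chrom_lengths):
            fh.write(f"#length\t{name}\t{length}\n")
        fh.write("chrom\tpos\tcM\n")
        for i, name in enumerate(mm.chrom_names):
            for p, c in zip(mm.positions[i], mm.cm[i]):
                fh.write(f"{name}\t{p}\t{c:.10g}\n")


def read_marker_map(path: str | Path) -> MarkerMap:
    lengths: dict[str, int] = {}
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#length\t"):
                _, name, length = line.split("\t")
                lengths[name] = int(length)
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != ["chrom", "pos", "cM"]:
                    raise ValueError(f"{path}:{lineno}: expected header 'chrom\\tpos\\tcM'")
                header_seen = True
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            rows.append((fields[0], int(fields[1]), float(fields[2])))
    if not header_seen:
        raise ValueError(f"{path}: missing header line")
    names: list[str] = []
    for chrom, _, _ in rows:
        if chrom not in names:
            names.append(chrom)
    positions = []
    cms = []
    chrom_lengths = []
    for name in names:
        sub = [(p, c) for ch, p, c in rows if ch == name]
        pos = np.array([p for p, _ in sub], dtype=np.int64)
        cm = np.array([c for _, c in sub])
        positions.append(pos)
        cms.append(cm)
        chrom_lengths.append(lengths.get(name, int(pos.max())))
    return MarkerMap(tuple(names), np.array(chrom_lengths), tuple(positions), tuple(cms))
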