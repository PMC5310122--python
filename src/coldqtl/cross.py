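"""Forward simulation of a two-parent advanced intercross and batch selection.

Two nearly-isogenic diploid founders differ at every marker (allele code 0 =
parent A, the superior strain; 1 = parent B).  Meiosis follows the Haldane
model: per chromosome the crossover count is Poisson with mean equal to the
genetic length in Morgans and crossover positions are uniform in genetic
coordinates (no interference, no obligate chiasma).  Intercrossing proceeds
by panmictic random pairing of distinct parents; serial-dilution selection is
purely asexual, amplifying lineages as exp(mu * g * ln2) per round with an
optional multinomial bottleneck.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .markers import MarkerMap

__all__ = [
    "DiploidIndividual",
    "Population",
    "TraitArchitecture",
    "PlantedQtl",
    "SelectionConfig",
    "ExtinctionError",
    "make_parents",
    "make_f1",
    "meiosis",
    "simulate_gametes",
    "advance_intercross",
    "trait_value",
    "trait_values",
    "serial_dilution_selection",
    "allele_dosage_frequencies",
    "allele_frequency_table",
]


class ExtinctionError(RuntimeError):
    """Raised when every lineage weight reaches zero during selection."""


@dataclass(frozen=True)
class DiploidIndividual:
    """A pair of haplotypes over the concatenated marker vector of a map."""

    hap1: np.ndarray
    hap2: np.ndarray
    id: str = "ind"

    def __post_init__(self) -> None:
        h1 = np.asarray(self.hap1, dtype=np.uint8)
        h2 = np.asarray(self.hap2, dtype=np.uint8)
        if h1.shape != h2.shape or h1.ndim != 1:
            raise ValueError("haplotypes must be 1-D and of equal length")
        if h1.size and (h1.max() > 1 or h2.max() > 1):
            raise ValueError("allele codes must be 0 or 1")
        object.__setattr__(self, "hap1", h1)
        object.__setattr__(self, "hap2", h2)

    def dosage(self) -> np.ndarray:
        """Number of parent-A allele copies (0, 1 or 2) at each marker."""
        return (2 - self.hap1.astype(np.int64) - self.hap2.astype(np.int64)).astype(np.int64)


@dataclass
class Population:
    """A weighted collection of diploid individuals on one marker map.

    Haplotypes are stored as two (n, m) uint8 matrices for vectorised
    meiosis and bookkeeping; ``individual(i)`` yields an object view.
    """

    mm: MarkerMap
    hap1: np.ndarray
    hap2: np.ndarray
    weights: np.ndarray
    generation_label: str = "F1"
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.hap1 = np.ascontiguousarray(self.hap1, dtype=np.uint8)
        self.hap2 = np.ascontiguousarray(self.hap2, dtype=np.uint8)
        if self.hap1.shape != self.hap2.shape or self.hap1.ndim != 2:
            raise ValueError("haplotype matrices must be 2-D and of equal shape")
        if self.hap1.shape[1] != self.mm.n_markers:
            raise ValueError("haplotype width does not match marker count")
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.hap1.shape[0],):
            raise ValueError("one weight per individual required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.n and self.weights.sum() <= 0:
            raise ValueError("weights must sum to a positive value")

    @property
    def n(self) -> int:
        return self.hap1.shape[0]

    def individual(self, i: int) -> DiploidIndividual:
        label = self.ids[i] if self.ids else f"{self.generation_label}_{i}"
        return DiploidIndividual(self.hap1[i], self.hap2[i], label)

    @classmethod
    def from_individuals(
        cls, mm: MarkerMap, individuals: list[DiploidIndividual],
        weights: np.ndarray | None = None, generation_label: str = "F1",
    ) -> "Population":
        if not individuals:
            raise ValueError("population must be non-empty")
        h1 = np.stack([ind.hap1 for ind in individuals])
        h2 = np.stack([ind.hap2 for ind in individuals])
        w = np.ones(len(individuals)) if weights is None else np.asarray(weights, float)
        return cls(mm, h1, h2, w, generation_label, [ind.id for ind in individuals])

    def dosage_matrix(self) -> np.ndarray:
        """(n, m) matrix of parent-A allele dosages."""
        return 2 - self.hap1.astype(np.int64) - self.hap2.astype(np.int64)


@dataclass(frozen=True)
class PlantedQtl:
    chrom: str
    marker_index: int
    effect: float  # additive effect (h^-1) per parent-A allele copy


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive genetic architecture for the growth-rate trait (h^-1)."""

    qtls: tuple[PlantedQtl, ...] = ()
    mu0: float = 0.1
    sigma_e: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")
        object.__setattr__(self, "qtls", tuple(
            q if isinstance(q, PlantedQtl) else PlantedQtl(*q) for q in self.qtls
        ))

    def qtl_indices(self, mm: MarkerMap) -> np.ndarray:
        return np.array([mm.global_index(q.chrom, q.marker_index) for q in self.qtls], dtype=np.int64)

    def effects(self) -> np.ndarray:
        return np.array([q.effect for q in self.qtls])

    def genetic_values(self, pop: Population) -> np.ndarray:
        idx = self.qtl_indices(pop.mm)
        if idx.size == 0:
            return np.full(pop.n, self.mu0)
        dos = pop.dosage_matrix()[:, idx]
        return self.mu0 + dos @ self.effects()


@dataclass(frozen=True)
class SelectionConfig:
    """Batch serial-dilution selection: growth amplification + bottleneck.

    ``generations_per_round`` defaults to 6.25 so the default 8 rounds give
    ~50 generations of clonal amplification.  ``bottleneck_size=None``
    disables the multinomial resampling step (deterministic weight updates).
    """

    rounds: int = 8
    generations_per_round: float = 6.25
    bottleneck_size: int | None = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.generations_per_round <= 0:
            raise ValueError("generations_per_round must be positive")
        if self.bottleneck_size is not None and self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1 (or None to disable)")


# ---------------------------------------------------------------------------
# founders


def make_parents(mm: MarkerMap) -> tuple[DiploidIndividual, DiploidIndividual]:
    """Homozygous-divergent founders: A is 0/0 and B is 1/1 at every marker."""
    m = mm.n_markers
    zero = np.zeros(m, dtype=np.uint8)
    one = np.ones(m, dtype=np.uint8)
    return (
        DiploidIndividual(zero, zero.copy(), "parentA"),
        DiploidIndividual(one, one.copy(), "parentB"),
    )


def make_f1(mm: MarkerMap, n: int) -> Population:
    """F1 hybrid population: n copies of the fully heterozygous genotype."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = mm.n_markers
    h1 = np.zeros((n, m), dtype=np.uint8)
    h2 = np.ones((n, m), dtype=np.uint8)
    return Population(mm, h1, h2, np.ones(n), "F1")


# ---------------------------------------------------------------------------
# meiosis


def _meiose_batch(
    hap_a: np.ndarray, hap_b: np.ndarray, mm: MarkerMap, rng: np.random.Generator,
    return_crossovers: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """One gamete per row of (hap_a, hap_b) under the Haldane model.

    Per chromosome: crossover count ~ Poisson(length in Morgans), positions
    uniform on [0, length], independent fair starting phase.
    """
    n = hap_a.shape[0]
    gametes = np.empty_like(hap_a)
    crossovers = np.zeros((n, mm.n_chromosomes), dtype=np.int64) if return_crossovers else None
    for ci in range(mm.n_chromosomes):
        sl = mm.chrom_slice(ci)
        g = mm.cm[ci] / 100.0  # marker positions in Morgans
        length_m = mm.chrom_cm[ci] / 100.0
        m = len(g)
        start = rng.integers(0, 2, size=n)
        k = rng.poisson(length_m, size=n)
        if crossovers is not None:
            crossovers[:, ci] = k
        total = int(k.sum())
        if total and m:
            pos = rng.uniform(0.0, length_m, size=total)
            gid = np.repeat(np.arange(n), k)
            # interval index: crossover at pos switches phase for markers with g > pos
            idx = np.searchsorted(g, pos, side="left")
            counts = np.zeros((n, m + 1), dtype=np.int32)
            np.add.at(counts, (gid, idx), 1)
            phase = (start[:, None] + np.cumsum(counts[:, :m], axis=1)) % 2
        else:
            phase = np.broadcast_to(start[:, None] % 2, (n, m))
        gametes[:, sl] = np.where(phase == 0, hap_a[:, sl], hap_b[:, sl])
    if return_crossovers:
        return gametes, crossovers
    return gametes


def meiosis(parent: DiploidIndividual, mm: MarkerMap, seed: int | np.random.Generator) -> np.ndarray:
    """A single gamete (1-D allele vector) from one diploid parent."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _meiose_batch(parent.hap1[None, :], parent.hap2[None, :], mm, rng)[0]


def simulate_gametes(
    parent: DiploidIndividual, mm: MarkerMap, n: int, seed: int | np.random.Generator,
    return_crossovers: bool = False,
):
    """n independent gametes from one parent; optionally per-chromosome
    crossover counts (for map-length diagnostics)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h1 = np.broadcast_to(parent.hap1, (n, parent.hap1.size))
    h2 = np.broadcast_to(parent.hap2, (n, parent.hap2.size))
    return _meiose_batch(np.ascontiguousarray(h1), np.ascontiguousarray(h2), mm, rng,
                         return_crossovers=return_crossovers)


# ---------------------------------------------------------------------------
# intercross


_GEN_RE = re.compile(r"^F(\d+)$")


def _parse_generation(label: str) -> int:
    m = _GEN_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse generation from label {label!r}; expected 'F<k>'")
    return int(m.group(1))


def advance_intercross(
    pop: Population, target_generation: int, pop_size: int, mm: MarkerMap, seed: int,
) -> Population:
    """Random intercross to the target generation (e.g. F1 -> F13).

    Each offspring draws two distinct parents with weight-proportional
    probability and receives one gamete from each.  Offspring carry equal
    weights.  Returns the input unchanged when already at the target.
    """
    current = _parse_generation(pop.generation_label)
    if target_generation < current:
        raise ValueError("target generation precedes the population's generation")
    if target_generation == current:
        return pop
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2 to draw distinct parents")
    if pop.n < 2:
        raise ValueError("need at least 2 individuals to intercross")
    rng = np.random.default_rng(seed)
    h1, h2, w = pop.hap1, pop.hap2, pop.weights
    for gen in range(current, target_generation):
        p = w / w.sum()
        i1 = rng.choice(len(p), size=pop_size, p=p)
        i2 = rng.choice(len(p), size=pop_size, p=p)
        # enforce distinct parents by redrawing clashes
        clash = i1 == i2
        while clash.any():
            i2[clash] = rng.choice(len(p), size=int(clash.sum()), p=p)
            clash = i1 == i2
        g1 = _meiose_batch(h1[i1], h2[i1], mm, rng)
        g2 = _meiose_batch(h1[i2], h2[i2], mm, rng)
        h1, h2 = g1, g2
        w = np.ones(pop_size)
    return Population(mm, h1, h2, w, f"F{target_generation}")


# ---------------------------------------------------------------------------
# trait


def trait_values(
    pop: Population, arch: TraitArchitecture, seed: int | np.random.Generator,
) -> np.ndarray:
    """Growth rate mu per individual: mu0 + sum(a_k * dosage_k) + N(0, sigma_e^2)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = arch.genetic_values(pop)
    if arch.sigma_e > 0:
        mu = mu + rng.normal(0.0, arch.sigma_e, size=pop.n)
    return mu


def trait_value(ind: DiploidIndividual, arch: TraitArchitecture, seed: int | np.random.Generator,
                mm: MarkerMap | None = None) -> float:
    """Trait value of a single individual (requires the map for QTL lookup)."""
    if mm is None:
        raise ValueError("mm (marker map) is required")
    pop = Population(mm, ind.hap1[None, :], ind.hap2[None, :], np.ones(1), "F1")
    return float(trait_values(pop, arch, seed)[0])


# ---------------------------------------------------------------------------
# selection


def serial_dilution_selection(
    pop: Population, arch: TraitArchitecture, cfg: SelectionConfig,
) -> Population:
    """Asexual batch serial-dilution selection on growth rate.

    Per round each lineage's weight is multiplied by exp(mu_i * g * ln2)
    (g = generations per round; a lineage at rate 1/g h^-1 doubles g times),
    with a fresh environmental deviate per lineage per round, followed by a
    multinomial bottleneck to ``bottleneck_size`` unless disabled.
    """
    rng = np.random.default_rng(cfg.seed)
    h1, h2 = pop.hap1, pop.hap2
    w = pop.weights.astype(np.float64).copy()
    ids = list(pop.ids) if pop.ids else None
    for _ in range(cfg.rounds):
        mu = arch.mu0 + _genetic_part(h1, h2, pop.mm, arch)
        if arch.sigma_e > 0:
            mu = mu + rng.normal(0.0, arch.sigma_e, size=len(w))
        # subtract the max exponent for overflow safety; weights are relative
        expo = mu * cfg.generations_per_round * math.log(2.0)
        w = w * np.exp(expo - expo.max())
        if w.sum() <= 0:
            raise ExtinctionError("all lineage weights vanished during selection")
        if cfg.bottleneck_size is not None:
            counts = rng.multinomial(cfg.bottleneck_size, w / w.sum())
            keep = counts > 0
            h1, h2, w = h1[keep], h2[keep], counts[keep].astype(np.float64)
            if ids is not None:
                ids = [ids[i] for i in np.flatnonzero(keep)]
            if len(w) == 0:
                raise ExtinctionError("bottleneck removed every lineage")
    label = f"SP({pop.generation_label}+{cfg.rounds}r)"
    return Population(pop.mm, h1, h2, w, label, ids)


def _genetic_part(h1: np.ndarray, h2: np.ndarray, mm: MarkerMap, arch: TraitArchitecture) -> np.ndarray:
    idx = arch.qtl_indices(mm)
    if idx.size == 0:
        return np.zeros(h1.shape[0])
    dos = 2 - h1[:, idx].astype(np.int64) - h2[:, idx].astype(np.int64)
    return dos @ arch.effects()


# ---------------------------------------------------------------------------
# truth allele frequencies


def allele_dosage_frequencies(pop: Population) -> np.ndarray:
    """Weighted parent-A allele frequency per marker: sum(w*d) / (2*sum(w))."""
    if pop.n == 0:
        raise ValueError("population is empty")
    w = pop.weights
    dos = pop.dosage_matrix()
    return (w @ dos) / (2.0 * w.sum())


def allele_frequency_table(pop: Population):
    """True frequencies as a DataFrame with columns chrom, pos, freq."""
    df = pop.mm.site_frame()[["chrom", "pos"]].copy()
    df["freq"] = allele_dosage_frequencies(pop)
    return df
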