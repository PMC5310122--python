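"""End-to-end pipeline: simulate cross -> select -> pool-seq -> map -> score.

Configuration is a single validated schema (:class:`RunConfig`, unknown keys
rejected).  Every stochastic stage draws from a substream spawned off the
top-level seed, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cross import (
    PlantedQtl,
    SelectionConfig,
    TraitArchitecture,
    advance_intercross,
    allele_frequency_table,
    make_f1,
    serial_dilution_selection,
)
from .evaluate import TruthQtl, TruthSet, match_intervals
from .mapping import FilterConfig, map_qtls, write_intervals_bed, write_intervals_tsv
from .markers import build_marker_map, write_marker_map
from .poolseq import PoolSpec, simulate_pool_counts, write_counts_table

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("coldqtl")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MapConfig(_Model):
    n_chromosomes: int = 16
    chrom_length: int = 1_000_000
    markers_per_chrom: int = 100
    cM_per_Mb: float = 380.0  # ~0.38 cM/kb, the yeast genome-wide average rate


class CrossConfig(_Model):
    f1_size: int = 200
    target_generation: int = 13
    pop_size: int = 5000


class QtlSpec(_Model):
    chrom: str
    marker_index: int
    effect: float


class TraitConfig(_Model):
    qtls: list[QtlSpec] = Field(default_factory=list)
    mu0: float = 0.10
    sigma_e: float = 0.01


class SelectionStage(_Model):
    rounds: int = 8
    generations_per_round: float = 6.25
    bottleneck_size: int | None = 5000
    n_replicates: int = 2


class PoolConfig(_Model):
    # the baseline pool is sequenced once per replicate (paired libraries),
    # at higher depth than the selected pools: baseline noise enters every
    # replicate's delta-AF and would otherwise dominate the false-call rate
    initial_mean_depth: float = 200.0
    selected_mean_depth: float = 100.0
    error_rate: float = 0.005
    shared_initial_library: bool = False


class CallerConfig(_Model):
    min_depth: int = 30
    af_low: float = 0.30
    af_high: float = 0.70
    delta_threshold: float = 0.1
    max_gap: int = 25_000
    min_sites: int = 3
    subtelomere_window: int = 30_000


class EvalConfig(_Model):
    match_tolerance: int = 50_000


class RunConfig(_Model):
    seed: int = 0
    condition: str = "15C-SM"
    map: MapConfig = Field(default_factory=MapConfig)
    cross: CrossConfig = Field(default_factory=CrossConfig)
    trait: TraitConfig = Field(default_factory=TraitConfig)
    selection: SelectionStage = Field(default_factory=SelectionStage)
    pools: PoolConfig = Field(default_factory=PoolConfig)
    caller: CallerConfig = Field(default_factory=CallerConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def _params_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the summary.

    With ``out_dir`` set, all intermediate tables (marker map, truth set,
    counts per pool, retained sites, calls, intervals TSV + BED) and a
    ``summary.json`` are written; outputs are deterministic functions of the
    config.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]
    seed_map, seed_cross, seed_trait, seed_sel, seed_pool, _ = seeds
    phash = _params_hash(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str, **info):
        log.info("stage=%s params=%s seed=%s %s", name, phash, cfg.seed,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    # -- marker map -----------------------------------------------------
    mc = cfg.map
    mm = build_marker_map(
        [mc.chrom_length] * mc.n_chromosomes, mc.markers_per_chrom, mc.cM_per_Mb, seed_map,
    )
    stage("marker_map", markers=mm.n_markers, total_cM=round(mm.total_cm, 1))
    if out is not None:
        write_marker_map(mm, out / "marker_map.tsv")

    # -- trait / truth --------------------------------------------------
    arch = TraitArchitecture(
        qtls=tuple(PlantedQtl(q.chrom, q.marker_index, q.effect) for q in cfg.trait.qtls),
        mu0=cfg.trait.mu0,
        sigma_e=cfg.trait.sigma_e,
    )
    truth_qtls = []
    for q in arch.qtls:
        ci = mm.chrom_index(q.chrom)
        truth_qtls.append(TruthQtl(q.chrom, int(mm.positions[ci][q.marker_index]), q.effect))
    truth = TruthSet(tuple(truth_qtls))
    if out is not None:
        with open(out / "truth_qtls.tsv", "w") as fh:
            fh.write("chrom\tpos\teffect\n")
            for tq in truth.qtls:
                fh.write(f"{tq.chrom}\t{tq.pos}\t{tq.effect:.10g}\n")

    # -- intercross -----------------------------------------------------
    f1 = make_f1(mm, cfg.cross.f1_size)
    f13 = advance_intercross(f1, cfg.cross.target_generation, cfg.cross.pop_size, mm, seed_cross)
    stage("intercross", generation=f13.generation_label, n=f13.n)

    # -- selection replicates ------------------------------------------
    sel_ss = np.random.SeedSequence(seed_sel).spawn(cfg.selection.n_replicates)
    selected = []
    for r, sub in enumerate(sel_ss, start=1):
        scfg = SelectionConfig(
            rounds=cfg.selection.rounds,
            generations_per_round=cfg.selection.generations_per_round,
            bottleneck_size=cfg.selection.bottleneck_size,
            seed=int(sub.generate_state(1)[0]),
        )
        selected.append(serial_dilution_selection(f13, arch, scfg))
        stage("selection", replicate=r, rounds=scfg.rounds, lineages=selected[-1].n)

    # -- pooled sequencing ----------------------------------------------
    freqs_initial = allele_frequency_table(f13)
    pool_ss = np.random.SeedSequence(seed_pool).spawn(2 * cfg.selection.n_replicates + 1)
    pc = cfg.pools
    if pc.shared_initial_library:
        shared = simulate_pool_counts(freqs_initial, PoolSpec(
            "initial", pc.initial_mean_depth, pc.error_rate, int(pool_ss[0].generate_state(1)[0])))
        initial_counts = [shared] * cfg.selection.n_replicates
    else:
        initial_counts = [
            simulate_pool_counts(freqs_initial, PoolSpec(
                f"initial_r{r}", pc.initial_mean_depth, pc.error_rate,
                int(pool_ss[r].generate_state(1)[0])))
            for r in range(1, cfg.selection.n_replicates + 1)
        ]
    selected_counts = []
    for r, pop in enumerate(selected, start=1):
        spec = PoolSpec(f"selected_r{r}", pc.selected_mean_depth, pc.error_rate,
                        int(pool_ss[cfg.selection.n_replicates + r].generate_state(1)[0]))
        selected_counts.append(simulate_pool_counts(allele_frequency_table(pop), spec))
    stage("pool_seq", pools=len(initial_counts) + len(selected_counts))
    if out is not None:
        for c in [initial_counts[0]] if pc.shared_initial_library else initial_counts:
            write_counts_table(c, out / f"counts_{c.pool_id}.tsv")
        for c in selected_counts:
            write_counts_table(c, out / f"counts_{c.pool_id}.tsv")

    # -- QTL calling ----------------------------------------------------
    cc = cfg.caller
    fcfg = FilterConfig(cc.min_depth, (cc.af_low, cc.af_high), cc.delta_threshold)
    retained, deltas, calls, intervals = map_qtls(
        initial_counts[0], selected_counts, fcfg,
        chrom_lengths=mm.chrom_length_dict(),
        max_gap=cc.max_gap, min_sites=cc.min_sites,
        subtelomere_window=cc.subtelomere_window,
        condition=cfg.condition,
        initial_counts_per_replicate=None if pc.shared_initial_library else initial_counts,
    )
    stage("map_qtls", retained=len(retained), calls=len(calls), intervals=len(intervals))
    if out is not None:
        retained.reset_index().to_csv(out / "retained_sites.tsv", sep="\t", index=False)
        with open(out / "site_calls.tsv", "w") as fh:
            reps = "\t".join(f"delta_af_r{r}" for r in range(1, len(deltas) + 1))
            fh.write(f"chrom\tpos\t{reps}\tdirection\n")
            for c in calls:
                ds = "\t".join(f"{d:.6g}" for d in c.delta_af)
                fh.write(f"{c.chrom}\t{c.pos}\t{ds}\t{c.direction}\n")
        write_intervals_tsv(intervals, out / "intervals.tsv")
        write_intervals_bed(intervals, out / "intervals.bed")

    # -- evaluation -----------------------------------------------------
    report = match_intervals(intervals, truth, tolerance=cfg.evaluation.match_tolerance)
    stage("evaluate", tp=report.tp, fp=report.fp, fn=report.fn)

    summary = {
        "version": __version__,
        "params_hash": phash,
        "config": cfg.model_dump(),
        "n_markers": mm.n_markers,
        "n_retained_sites": int(len(retained)),
        "n_called_sites": len(calls),
        "intervals": [
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "n_sites": iv.n_sites, "mean_abs_delta": round(iv.mean_abs_delta, 6),
                "direction": iv.direction, "subtelomeric": iv.subtelomeric,
                "condition": iv.condition,
            }
            for iv in intervals
        ],
        "recovery": {
            "tp": report.tp, "fp": report.fp, "fn": report.fn,
            "power": report.power, "fdr": report.fdr,
            "matches": [list(m) for m in report.matches],
        },
    }
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return summary
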