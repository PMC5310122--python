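# coldqtl

Bulk-segregant QTL mapping of growth traits by pooled sequencing, as a
tested, reusable pipeline built around a forward simulation with known
ground truth:

1. **Cross simulation** (`coldqtl.cross`) — two homozygous-divergent diploid
   founders, Haldane-model meiosis, random intercrossing to an advanced
   generation (F13 by default), an additive polygenic growth-rate trait with
   planted QTLs, and batch serial-dilution selection (exponential clonal
   amplification `exp(mu * g * ln2)` per round plus a multinomial
   bottleneck).
2. **Pool-seq simulation** (`coldqtl.poolseq`) — Poisson (or
   negative-binomial) depth, binomial allele sampling with a symmetric
   miscall model `p' = p(1-e) + (1-p)e`, canonical counts TSVs, optional
   VCF (FORMAT/AD) ingestion.
3. **QTL calling** (`coldqtl.mapping`) — per-pool allele frequencies; sites
   retained with depth >= 30 in every pool and initial allele frequency in
   the inclusive 30–70% band; sites called when every replicate's frequency
   change is >= 0.1 in the same direction; same-direction calls merged into
   intervals (gap <= 25 kb, >= 3 sites) and flagged as subtelomeric within
   30 kb of a chromosome end. TSV and BED export.
4. **Phenotype kinetics** (`coldqtl.kinetics`) — blank subtraction and
   `y = ln(OD_t/OD_0)` transform, reparameterised Gompertz fitting
   (`y = D*exp(-exp((mu_max*e/D)(lam-t)+1))`) by damped Gauss–Newton,
   broad-sense heritability `((Var_seg - Var_env)/Var_seg) * 100`, the
   2-sigma transgression rule, generation counting, fermentation T100
   (density crossing 995 g/L, with a STUCK sentinel) and relative T100, and
   two-tailed t-tests with Bonferroni correction.
5. **Evaluation & pipeline** (`coldqtl.evaluate`, `coldqtl.pipeline`) —
   one-to-one matching of called intervals against planted truth (power,
   FDR), delta-AF threshold sweeps, and a fully seeded, schema-validated
   end-to-end runner producing deterministic outputs.

## CLI

```sh
# full pipeline from a YAML config (see coldqtl.pipeline.RunConfig for keys)
coldqtl run-all --config cfg.yaml --seed 1 --out runs/demo

# QTL calling from existing counts tables (one baseline library per replicate)
coldqtl map-qtl --initial init_r1.tsv --initial init_r2.tsv \
    --selected sel_r1.tsv --selected sel_r2.tsv --out mapped/

# growth-curve fitting (wide CSV: time column + one column per well)
coldqtl phenotype growth.csv --blanks blank1,blank2 --out fits.tsv

# fermentation endpoints and strain-vs-control tests
coldqtl ferment density.csv --control hybrid --out ferm.tsv

# score intervals against a planted-truth TSV
coldqtl evaluate --intervals mapped/intervals.tsv --truth truth_qtls.tsv
```

Every stochastic stage requires an explicit seed (config `seed`, or
`--seed`); identical config + seed reproduces byte-identical outputs.

## File formats

- **Marker map TSV**: `chrom  pos  cM` (1-based bp), preceded by
  `#length <chrom> <bp>` header lines.
- **Counts TSV**: `chrom  pos  count_A  count_B`, sorted, unique sites;
  parent-A is the superior founder's allele.
- **Intervals**: TSV is 1-based inclusive; BED is 0-based half-open with
  `score = 1000 * mean |dAF|` (capped).
- **Growth CSV**: first column time (h), one column per well (OD600).
- **Density CSV**: columns `time, density, strain, replicate` (g/L).
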