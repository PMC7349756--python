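# ribotag

Analysis of RiboTag immunoprecipitation (IP) experiments in mixed-species
co-cultures: how cleanly does cell-type-restricted expression of an
epitope-tagged ribosomal protein (RPL22-HA / RPL22-V5) separate one cell
type's translatome from a two-species mixture?

When a human and a mouse cell type are co-cultured and each expresses a
differently tagged RPL22, reads from an IP library can be assigned
unambiguously to their species of origin by aligning to a hybrid
human+mouse reference (plus GFP/mCherry reporter contigs). Off-target
reads — the species whose cells did *not* carry the precipitated tag —
measure cross-contamination directly. This package implements the
downstream statistics for such experiments, and a generative simulator so
every statistic can be validated against analytic expectations.

## The statistic at the core

For each library, let `p_c` be the percent of uniquely mapping reads on
chromosome `c`. For an IP and its matched co-culture input, plot the
change `Δ_c = p_c(IP) − p_c(input)` against the initial percent
`p_c(input)`, per chromosome. If a fraction of every off-target
transcript is carried over indiscriminately, off-target points fall on a
line through the origin, and the **depletion efficiency** is the negative
slope of the ordinary-least-squares regression over off-target
chromosomes:

    D = −slope of  Δ_c ~ p_c(input)   over off-target chromosomes.

`D = 1` is the theoretical maximum: a chromosome holding 5% of the input
that loses every read after IP changes by exactly −5 points, and if that
holds for all off-target chromosomes the slope is −1.

Around this the package provides:

- **io**: featureCounts-dialect count matrices, samtools-idxstats
  chromosome counts, gene-annotation tables, sample sheets with IP/input
  pairing — all validated, all round-tripping through writers;
- **composition**: per-chromosome / per-species percent tables, delta
  tables at chromosome and gene level;
- **depletion**: the regression above (slope, intercept, R², two-sided
  t-test p), per-IP report tables, enrichment/depletion calls;
- **enrichment**: self-contained permutation GSEA (weighted
  Kolmogorov–Smirnov running sum, gene-permutation null,
  Benjamini–Hochberg adjustment) over Ensembl biotype sets and over
  chromosome sets restricted to protein-coding genes;
- **reporter**: absolute GFP/mCherry quantification from digital-PCR
  partition counts via Poisson inversion `λ = −ln(1 − f)`, mCherry/GFP
  ratios and between-IP fold differences;
- **sim**: a generative model of the whole experiment (log-normal
  expression, biotype-dependent on-target capture, zero capture of
  on-target mitochondrial RNA, uniform off-target retention `k`) whose
  truth record carries the exact expectation `D = 1 − k/Z` of the fitted
  efficiency.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data. `python analysis/01_simulate.py` generates a 28% human / 72% mouse
co-culture (~1.9k genes, 10⁶ reads/library, off-target retention
k = 0.2) and prints the analytic expectations:

```
simulated 1882 genes x 3 samples (seed=1, library size 1,000,000)
  HA_IP: on-target human; expected off-target slope -0.4490, expected efficiency 0.4490
  V5_IP: on-target mouse; expected off-target slope -0.6834, expected efficiency 0.6834
```

`python analysis/03_depletion.py` then recovers those efficiencies from
the simulated counts:

```
ip_sample target_class species  n_chromosomes   slope  r_squared  p_value  depletion_efficiency
    HA_IP           on   human             24  1.3105     0.6520   0.0000                   NaN
    HA_IP          off   mouse             22 -0.4570     0.9986   0.0000                0.4570
    V5_IP           on   mouse             21  0.3133     0.2235   0.0304                   NaN
    V5_IP          off   human             25 -0.6769     0.9976   0.0000                0.6769

  HA_IP: fitted efficiency 0.4570 vs analytic expectation 0.4490 (|diff| = 0.0080)
  V5_IP: fitted efficiency 0.6769 vs analytic expectation 0.6834 (|diff| = 0.0065)
```

Off-target depletion is tightly linear (R² ≈ 0.998) while the on-target
fit is noisy with a positive slope — the structure such experiments show.
`02_composition.py` reports the 28/72 split shifting to 60/40 after the
HA IP and 9/91 after the V5 IP; `04_enrichment.py` shows protein-coding
transcripts enriched (ES +0.59, adjusted p = 0.0005) with lncRNA,
pseudogene and mitochondrial sets depleted; `05_reporter.py` recovers
mCherry/GFP ratios by simulated dPCR that match read-count ratios
(e.g. 2.548 vs 2.545 in the input) and a 25.7-fold ratio difference
between the two IPs.

The same pipeline runs from the command line (`ribotag simulate`,
`ribotag depletion`, `ribotag gsea`, `ribotag reporter`, `ribotag
analyze`) on user-supplied featureCounts/idxstats tables.

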