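# Methods

## The quantities computed

**Chromosome proportions.** For a library and a quantification mode
(`all_genes`, `protein_coding_only`, or `chromosome_level` for
samtools-idxstats input), each chromosome's reads are expressed as a
percent of the mode's library total (0–100 scale). Reporter contigs
(GFP/mCherry) are excluded from numerator and denominator by default:
they are cell-type markers rather than chromosomes of either species and
are analysed separately; a flag re-includes them. Percentages sum to 100
to 1e-9 and are invariant under uniform count scaling.

**Delta tables.** For an IP and its matched input, the per-chromosome
(or per-gene) change is `Δ = percent(IP) − percent(input)`. The sign
convention is IP minus input, under which off-target depletion produces a
negative regression slope; output headers state the convention. With a
shared denominator the deltas sum to zero exactly.

**Depletion efficiency.** Ordinary least squares of `Δ` on the initial
percent over the chromosomes of one target class. The fit includes an
intercept: nothing constrains the line through the origin a priori, and
empirical on-target fits (slope ≈ 1.3, R² ≈ 0.6 in the simulated worked
example) are inconsistent with forced-origin geometry; a
`through_origin` flag exists for sensitivity analysis (slope
`Σxy/Σx²`, uncentred R², t-test with n−1 df). The p-value is the
two-sided t-test of zero slope with n−2 df, as returned by
`scipy.stats.linregress`; for a simple regression this is equivalent to
the F-test. Fits require ≥3 chromosomes (two points would give a
vacuous R² = 1) and non-degenerate x. The depletion efficiency is
exactly `−slope`, reported for the off-target class.

Mitochondrial handling: the *on-target* MT chromosome is excluded from
on-target fits by default, because mitochondrial transcripts are
translated by mitoribosomes and are invisible to ribosome-mediated
capture, so MT sits far below the on-target trend. The *off-target* MT
chromosome is included in off-target fits by default: off-target material
arrives by non-specific carry-over, which does not distinguish
mitochondrial from nuclear RNA, so off-target MT behaves like every other
off-target chromosome. Both defaults are overridable.

**Gene-set enrichment.** Genes are ranked by
`log2((CPM_IP + c)/(CPM_input + c))` with pseudocount c = 1 (CPM = counts
per million of the library; the statistic is invariant to uniform count
scaling); ties break lexically on gene id so the order is deterministic.
The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum with weight exponent p = 1: hits advance by their share of
`Σ|stat|^p` over the set, misses retreat by `1/(N − m)`; the ES is the
signed maximal deviation, clamped to [−1, 1] against floating-point
accumulation. If every member statistic is zero the hit increments fall
back to `1/m`. Because the design has one IP/input pair, the null is a
*gene* permutation: random same-size sets drawn from the ranked universe
(nulls are shared between sets of identical size within one call, and
deterministic given the seed). The p-value is one-sided on the sign of
the observed ES and conditional on same-sign null draws,
`p = (1 + #{same-sign null ≥ |ES|}) / (1 + #{same-sign null})` — the
unconditional form with `n_perm + 1` in the denominator is
anti-conservative by roughly a factor of two because only about half the
null draws land on either sign, and fails a type-I calibration check
that this form passes. P-values honour the `1/(n_perm+1)` floor and are
Benjamini–Hochberg adjusted across the tested sets
(`statsmodels.stats.multitest`). Sets with fewer than 5 members in the
universe are skipped and logged. Two collections are built from the
annotation: one set per Ensembl biotype over all genes, and one set per
chromosome over protein-coding genes only (the analysis in which the
mitochondrial chromosome is the expected depletion signal).

**Digital PCR.** With template Poisson-distributed over partitions of
volume v µL, the positive fraction f estimates `1 − e^{−λ}`, so
`λ = −ln(1 − f)` copies/partition and the concentration is `λ/v`
copies/µL. The 95% interval is the Clopper–Pearson binomial interval on
f pushed through the same transform; Clopper–Pearson is conservative,
which the round-trip coverage test (≥90% of 200 replicates) relies on.
Saturated reactions (all partitions positive) raise an error rather than
an infinite estimate, and undetected targets flag the mCherry/GFP ratio
as undefined rather than dividing by zero. Partition volumes are treated
as equal (no per-partition volume correction; per-partition volumes are
not generally published). Fold differences between two ratios are always
reported ≥ 1 with an explicit direction label.

## The generative model

The simulator emulates a two-cell-type co-culture: a human cell type
carrying GFP and RPL22-HA, a mouse cell type carrying mCherry and
RPL22-V5, sequenced against the canonical chromosomes of both genomes
(25 human + 22 mouse, species-prefixed names `hs_*`/`mm_*`, one MT each)
plus the two reporter contigs.

Per cell type, gene abundances are i.i.d. log-normal (μ = 0, σ = 1) with
mass apportioned: `mito_mass_fraction` (default 0.05) on the MT
chromosome, `reporter_mass_fraction` (default 0.01) on the reporter, the
rest on nuclear genes. Nuclear biotypes are drawn per gene
(protein_coding 0.70, lncRNA 0.20, pseudogene 0.10 — the rough shape of
an expressed Ensembl annotation); MT genes are 0.35 protein_coding /
0.55 Mt_tRNA / 0.10 Mt_rRNA, matching the human MT gene census. The
co-culture input mixes the two profiles with mass fraction m = 0.28
human, reproducing the 28/72 human/mouse read split of the reference
experiment.

An IP reweights input proportions by per-gene capture factors and
renormalises:

| transcript class              | weight                      | default |
|-------------------------------|-----------------------------|---------|
| on-target protein coding      | `capture_protein_coding`    | 1.0     |
| on-target lncRNA              | `capture_lncRNA`            | 0.5     |
| on-target pseudogene          | `capture_pseudogene`        | 0.3     |
| on-target mitochondrial       | 0 (fixed)                   | 0       |
| any off-target transcript     | `off_target_retain` k       | 0.2     |
| reporter, on-target cell type | `capture_protein_coding`    | 1.0     |
| reporter, off-target cell type| k                           | 0.2     |

On-target capture is ribosome-mediated, hence biotype-dependent and zero
for mitochondrial RNA; off-target retention is non-specific carry-over,
hence uniform across biotypes *including* the off-target MT. That single
modelling choice is what makes off-target depletion exactly linear:
every expected off-target point lies on `Δ = (k/Z_eff − 1)·p`, where
`Z_eff` is the retained mass fraction computed over non-reporter genes
relative to the non-reporter input mass (the normaliser matching the
reporter-excluded percentage denominators). The truth record stores
`Z_total = Σ w_g p_g` over all genes, `Z_eff`, the expected slope
`k/Z_eff − 1` and the expected efficiency `D = 1 − k/Z_eff`; when
`k > Z_total` the expected efficiency is negative and a warning is
recorded in the truth rather than raising. Counts are multinomial at a
fixed library size (default 10⁶) per sample; one shared input serves
both IPs, mirroring a split lysate. With k in {0.05, 0.2, 0.5, 0.75}
the default configuration yields expected efficiencies from ≈0.92 down
to ≈0.01, spanning the 0.25–0.87 range such experiments report, and the
fitted efficiency recovers the expectation within 0.02 at 10⁶ reads.

The dPCR simulator draws positives as `Binomial(n_total, 1 − e^{−cv})`;
defaults (496 partitions of 0.024 µL) follow plate-based dPCR geometry.

**What the simulator does not model** — and therefore what passing tests
do not establish about real data: read-level effects (alignment
ambiguity between close homologs, multimapping loss, gene length, GC),
overdispersion beyond multinomial sampling, biological replicate
variability, the yield decline of sequential IPs, any dependence of
capture on expression level, and contamination mechanisms that are not
uniformly proportional (e.g. abundance-selective reassociation after
lysis). The linearity of off-target depletion is an assumption the
simulator shares with the statistic; real data can and do depart from it
(low-efficiency IPs show visibly lower off-target R²).

## Problem sizes and numerical choices

Tests and the analysis scripts run the default 1,882-gene, 10⁶-read
configuration; the permutation analyses use n_perm = 10⁴ for the sign
tests and 199 permutations × 200 draws for the calibration check —
sizes at which every Monte-Carlo tolerance in the suite is comfortably
inside its sampling error. Tolerances: exact identities are asserted at
1e-9–1e-12; OLS against the closed-form normal equations at 1e-10;
simulator recovery at 0.02 (≈3 multinomial standard errors at 10⁶
reads); the type-I rate within the binomial 99% band around 0.05 over
200 draws. Tabular floats are written with 6 significant digits;
mitochondrial chromosome names are recognised from a configurable set
({MT, chrM, chrMT}, matched exactly or after a species prefix ending in
`_`).
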