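# Methods

## Scope and model

`pmdclock` implements the analysis machinery for division-coupled DNA
methylation erosion in partially methylated domains (PMDs): sequence-
context annotation of CpGs, methylation-vs-population-doubling (PD)
trajectory analysis, replication-timing scoring, elastic-net clock
training, and a mechanistic simulator that provides ground truth for all
of it. Upstream array processing (idat parsing, detection p-values,
normalization QC) and PMD boundary calling are out of scope: beta
matrices and domain intervals are consumed as published.

## CpG context annotation

A CpG is the plus-strand dinucleotide `CG`, indexed by the 0-based
position of the C; since `CG` is its own reverse complement, one record
per site suffices, and flank classes are reverse-complement symmetric.

* **Flank class** — left flank at `pos−1`, right at `pos+2`: `WCGW` if
  both are A/T, `SCGS` if both are C/G, `intermediate` if mixed,
  `ambiguous` if either is N or off the contig edge (ambiguous sites are
  excluded from WCGW/SCGS sets rather than guessed).
* **Solo/social** — distance to the nearest other CpG on the contig,
  measured start-to-start between C positions; solo iff distance ≥ 35 bp
  (threshold configurable). The boundary is assigned to solo ("at least
  35 bp away"). Whether the original definition measures start-to-start
  distance or gap length is not recorded anywhere we could find; the
  start-to-start convention is this package's documented choice, and the
  synthetic-genome generator plants spacings of 34/35/36 bp so the
  boundary behavior is pinned by tests.
* **Domain** — `commonPMD` if inside the PMD interval set, else `HMD` if
  inside the HMD set, else `neither` (mutually exclusive, PMD wins);
  the CpG-island flag and any extra interval flags (e.g. H3K36me3) are
  independent booleans. Intervals are 0-based half-open, merged on load;
  membership is a `searchsorted` lookup against the merged starts/ends.

## Population doublings and value transforms

Cumulative PDs chain `PD = 3.32·(log10 Y − log10 I) + X` across passages
within a lineage (X = previous cumulative PD; first passage takes the
sheet's `inoculum_pd`, default 0). The constant 3.32 is a rounded
1/log10(2), so a single doubling counts as 0.99942 PD, not exactly 1;
the formula is applied as printed. The transform used for hypothesis
tests is the m-value `m = log2(β/(1−β))` with β clipped to
[ε, 1−ε], ε = 1e-6; base 2 is the array-field convention. Effect sizes
(slopes) are reported on the β scale, tests are run on the m scale.

## Trajectory analysis

* `fit_cpg_slopes`: per-probe OLS of β on PD (≥3 non-missing samples),
  vectorized over probes with full observations; returns slope,
  intercept, n, R², slope SE.
* `categorize_cpgs`: β_first/β_last are replicate means at the earliest/
  latest PD; `variable` iff |Δβ| > 0.10, otherwise stable-methylated if
  β_first ≥ 0.70, stable-unmethylated if ≤ 0.30, intermediate starts
  assigned to the nearer bound. The 0.70/0.30 bounds are exposed
  conventions (only the 10%-change rule is externally fixed). Variable
  probes get quartiles of starting methylation within the variable set.
* `compare_slopes`: OLS on m-values with PD, group, and PD×group terms,
  optionally with subculture as a fixed covariate. This is a documented
  fixed-effects approximation to a mixed model with random subculture
  effects: with the small number of subcultures per condition typical of
  these designs, the fixed-effects interaction test targets the same
  slope-difference estimand without the mixed-model machinery. Two
  groups → t-test on the interaction coefficient; more → joint F-test.
  Type-I error is verified at 5% nominal over 1000 null simulations.
* `test_methylation_change`: per-probe difference of mean m-values
  (post − pre), one-sample t-test over probes, one-sided (`less` =
  methylation lost) by default; identical inputs return p = 0.5.
* `bin_and_compare`: covariate quantile bins (equal counts up to ties)
  with per-bin slope medians and a Kruskal–Wallis omnibus test.

## Replication timing

Six-fraction Repli-seq signal (G1b, S1, S2, S3, S4, G2) is percent-
normalized per bin and weighted as
`WA = 0.917·G1b + 0.750·S1 + 0.583·S2 + 0.417·S3 + 0.250·S4 + 0·G2`,
so WA ∈ [0, 0.917], higher = earlier replication, and the score is
invariant to positive rescaling of the raw signal. CpGs inherit the WA
of their containing bin (NaN if uncovered); overlapping bins are an
error.

## Clock training

Two-stage procedure:

1. **Reference model** — elastic net (mixing α = 0.5) of observed
   cumulative PD on probe betas, trained on the youngest lineage.
2. **PD normalization** — for every other lineage the reference model
   predicts the replicative history of its earliest-PD sample; that
   prediction becomes the lineage's normalized starting PD, and later
   samples add their observed PD increments. The reference lineage keeps
   observed PDs. Estimates are therefore relative to the reference
   lineage's (unknown) true starting history — a shared offset is
   unidentifiable and deliberately not modeled.
3. **Final clock** — samples split at random (seeded) into train/test
   (default test fraction 0.33, matching a 122/60 split at n = 182);
   elastic net of normalized PD on betas restricted to common-PMD CpGs
   of *all* flank contexts (solo-WCGWs saturate early; the wider pool
   extends dynamic range). Stratified splitting by lineage is available
   but off by default.

Numerical choices: penalty chosen by 10-fold cross-validation at the
minimum mean CV error (fold assignment and coordinate descent seeded, so
training is bit-reproducible); features are standardized internally and
coefficients reported back on the β scale with an unregularized
intercept, which makes the fit shift-equivariant in PD (verified by
test). Probes with no observed beta are dropped with a warning; partial
missingness is mean-imputed at training. At application, missing model
probes are a hard error unless `impute=True` substitutes stored training
means (with a per-sample imputation count), preventing silent drift on
reduced arrays. Training is unweighted across samples.

The dual-set estimator scores a gaining and a losing probe set, each
linearly in its mean methylation, and reports the larger score; it
mirrors max-rule gain/loss clocks. `summarize_model` reports probe
counts and mean coefficients per context class (solo-WCGW PMD, other
PMD, non-PMD); reproducing the published clock's composition statistics
additionally requires its deposited coefficient file and the public
solo-WCGW annotation, which are external downloads, so tests validate
the reporting machinery on clocks whose composition is known by
construction.

## Simulator

Per division, population-mean methylation updates as
`β′ = β(1−r) + g(1−β(1−r))` (maintenance failure with probability r,
then de novo gain with probability g). This contraction has fixed point
`β* = g/(1−(1−r)(1−g))` approached geometrically with ratio
(1−r)(1−g) — the self-limiting plateau of long-cultured immortalized
cells.

**Default per-division rates** (chosen once; all overridable):

| class | r | g | β* |
| --- | --- | --- | --- |
| soloWCGW_PMD | 0.030 | 0.003 | ≈ 0.09 |
| social_PMD | 0.012 | 0.003 | ≈ 0.20 |
| solo_nonPMD | 0.002 | 0.0008 | ≈ 0.29 |
| social_nonPMD | 0.0002 | 0.002 | ≈ 0.92 (slight net gain) |

The soloWCGW rate makes a culture starting at β ≈ 0.6–0.7 approach its
plateau within roughly 40 PDs after a ~60-PD replicative lifespan, and
the ordering reproduces the observed context ranking (PMD solo-WCGW
fastest loss; social non-PMD CpGs a slight gain). Because erosion
saturates, fitted secant slopes attenuate in lineages with large
replicative-history offsets — rate comparisons should therefore be made
within young lineages or early windows, as the package's own analyses
do.

**Rate modifiers.** Replication timing multiplies r by
`1 + κ(0.917 − WA)/0.917` (κ = 0.5 default; PMD probes draw WA from
U(0.10, 0.45), non-PMD from U(0.55, 0.90)). Expression is protective:
r is multiplied by `1 − e·expression` (e = 0.5; 30% of probes
gene-linked with expression in U(0.2, 1)). A per-day loss rate
u = 1e-4/day models maintenance failure during unscheduled,
repair-associated DNA synthesis under ambient oxygen: it acts on
elapsed time, not divisions, so arrested cultures still lose methylation
very slowly. Effective rates are clipped to [0, 1).

**Cultures.** A scenario is a set of lineages, each with an in-vivo
starting offset (applied as divisions before culture start) and a
passage schedule of (growth ratio, days) pairs. Scheduled PDs per
passage are `3.32·log10(ratio)`, applied as integer division steps plus
one rate-scaled fractional step so the sample sheet's yield/inoculum
bookkeeping inverts the PD equation exactly. Observed betas are drawn
from a Beta distribution with the true mean and precision ν = 100
(array-like scatter; mean-preserving and bounded, unlike additive
Gaussian noise); ν = None disables noise, and exact betas are always
returned in the truth tables.

**Canonical scenarios.** `standard_scenario`: seven lineages, offsets
5–50 PDs, 26 passages at growth ratio 4 (≈ 2 PDs, 7 days each) — ~52
culture PDs, 189 samples. `immortalized_scenario`: one lineage run ~200
PDs to the plateau. `serum_scenario`: four parallel cultures of one cell
type at 0.50/0.35/0.22/0.15 divisions/day (15/5/1/0.5 % serum) over 140
days — equal elapsed time, unequal divisions; the slowest culture still
cycles (~1 doubling/week; serum-restricted fibroblasts fed several times
weekly do not fully quiesce), so every lineage traverses a PD range
resolvable against the clock's noise floor. `arrest_scenario`: shared
early passages, then a replication-blocked lineage (growth ratio 1,
days advancing) against a proliferating control.

**Planted genomes.** `simulate_genome` builds a contig from A/T filler
(no accidental CpG can form), planting CpGs with controlled flanks and
start-to-start spacings drawn from sets straddling the 35-bp solo
boundary, PMD-class sites under a single PMD interval. The truth table
drives exact-match tests of the annotator.

**What the simulator does not emulate** — and hence what a green test
does not establish: cell-to-cell heterogeneity (bulk means only),
selection in culture (the plateau is modeled as a de novo/loss
equilibrium; stabilization by selection against further loss cannot be
distinguished by this design), probe-level technical artifacts beyond
symmetric Beta noise (no batch effects, detection failures, or
cross-reactive probes), and transcriptional feedback (expression is a
static per-probe protection factor).

## Degenerate inputs and tie-breaks

Empty probe filters, constant PDs, groups under 3 samples, inverted
category thresholds, all-zero Repli-seq profiles, overlapping timing
bins, out-of-range betas, duplicate ids, and malformed BED lines are all
hard errors with the offending entity named. Identical data duplicated
into two groups yields a slope-difference estimate of 0 with p = 1;
identical pre/post groups give p = 0.5 in the one-sided shift test; a
contig's only CpG is solo at infinite distance; equal dual-clock scores
are returned with a tie flag.

## Known limitations

Estimated replicative histories are relative to the reference lineage;
the fixed-effects slope comparison understates between-subculture
variance relative to a mixed model when subcultures are many and noisy;
the clock assumes the application samples share the training platform's
probe set (imputation is opt-in and reported, not silent); and the
simulator's defaults describe fibroblast-like serial culture, not
tissues.
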