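# Methods

This note documents the models, parameter choices and numerical
conventions behind `zwscan`, and what the synthetic-data validation does
and does not demonstrate about real data.

## Biological model

In the avian ZW system males are ZZ and females ZW. Two consequences drive
the scan:

1. **Expression dosage.** Birds lack chromosome-wide dosage compensation,
   so a Z gene outside the pseudoautosomal region (PAR) has two male
   copies against one female copy and is expected at log₂(M:F) ≈ 1;
   inside the PAR both sexes are diploid and log₂(M:F) ≈ 0. Along a
   synteny-ordered Z gene map the per-gene ratio is therefore a noisy
   step function whose changepoint is the PAR boundary.
2. **Heterozygosity.** A female is hemizygous outside the PAR: she carries
   a single Z allele and cannot be heterozygous there, so
   heterozygous-site density collapses to ~0 in females but not males,
   while inside the PAR the sexes match. Requiring *both* signatures
   (male-biased smoothed expression and male-biased smoothed SNP density)
   before flagging a region non-PAR-like guards against ordinary
   sex-biased autosomal expression, which carries no density signal.

Gene order comes from a synteny map of a reference chromosome (in
practice a well-assembled relative; avian synteny is strongly conserved),
supplied as a BED file. The package does not infer orthology itself.

## Pipeline stages and parameters

### Hemoglobin depletion

Whole-blood RNA-seq is dominated by a small number of globin transcripts.
`flag_high_share_transcripts` flags any transcript holding at least
`threshold` (default 0.20, inclusive) of the pooled read pairs. Because
several globins can share the load without any single one reaching the
threshold, the pipeline also accepts an explicit id list (e.g. from a
pilot assembly or homology) and unions it with the share rule; in
synthetic mode the generator's two globin ids play that role. Depletion
conserves reads exactly (input = kept + removed), and `subsample` draws an
exact read budget without replacement via a multivariate hypergeometric
across (transcript, sample) cells — each retained pair is a uniform pick
from the pool, so expected cell counts scale proportionally.

Accounting percentages are rounded to the nearest integer, ties away from
zero, which is how such tables are conventionally reported.

### ORFs and coding effects

All maximal ORFs are scanned in three frames on both strands. An ORF runs
from ATG, or from the contig edge (5′-partial — assembled transcripts
routinely truncate real coding sequence), to the first in-frame stop or
the edge (3′-partial). Maximality is by forward-strand interval
containment within a strand, so an edge-to-stop partial supersedes an ATG
ORF nested inside it. A transcript is retained as coding when its best
ORF is strictly longer than `min_aa` = 100 amino acids, stop codon
excluded; ties prefer complete over partial, then the plus strand, then
the leftmost start. Codons containing N never match start/stop and
translate to X; a substitution in such a codon is classified
`indeterminate` and excluded from amino-acid-change counts. Stop gain and
loss count as nonsynonymous (a stop is treated as an amino-acid state).

### SNP marker rules

Frequencies are per individual: alt reads / total reads at the site,
undefined (missing) at zero depth. Defaults and comparison directions:

| rule | default | direction |
|---|---|---|
| coverage, every bird | 50 reads | inclusive ≥ |
| contig SNP density | 1 / 200 bp | strict < |
| within-species low tail | 5 % | strict < |
| within-species high tail | 35 % | strict > |
| diagnostic carrier species | 80 % | strict >, every bird |
| diagnostic other species | 5 % | strict <, every bird |

The density rule counts all sites on the contig before coverage
filtering and gates only within-species markers; diagnostic calls require
only coverage. A pooled-frequency mode for the diagnostic rule (cutoffs
applied to each species' mean frequency) is available as
`diag_mode="pooled"`; per-bird is the default because "every bird above
80 %" is the stricter and more reproducible reading. Raising `min_depth`
can only shrink the passing set, and lowering `diag_high` can only grow
the diagnostic set; both monotonicities are property-tested.

### Differential expression

Counts are quantile-normalized: each column is mapped onto the row-wise
mean of the sorted columns; tied values within a column receive the mean
of the reference values their ranks span. With ties the transform is
idempotent only up to that tie-averaging, which the tests acknowledge.

Each gene is modelled NB(μ, α) with Var = μ + αμ². Dispersion is
method-of-moments within groups, α̂ = max(0, (s² − m)/m²), pooled across
groups by residual degrees of freedom and shrunk toward the cohort median
with weight n₀/(n₀ + df), n₀ = 10 — a light empirical-Bayes stabilizer
for 8-vs-8 designs. The test is a likelihood ratio of a one-mean versus
two-mean fit with the dispersion held fixed (the NB mean MLE is then the
sample mean, so the statistic is closed-form), referred to χ²₁, with
Benjamini–Hochberg adjustment across genes. Simulation checks show raw
type-I error ≈ 0.05 at nominal 0.05 (2,000 null NB genes) and ≥ 95 %
power for a 4-fold change at depth 1000, n = 8 + 8. Fold changes use
pseudocount 0.5.

Species calls require significance *and* |log₂FC| ≥ log₂(2) (inclusive);
sex calls use significance only, with a parallel annotation of which
calls also pass 2-fold, because imposing the fold cutoff would
presuppose the non-PAR dosage signature being tested. The sex comparison
pools the two species; a species-blocked variant is out of scope.

Against an exhaustive permutation oracle, the χ²₁ p-value of clearly
separated 3-vs-3 toys matches the permutation mid-p within 0.05. The
mid-p convention is required because the LR statistic is invariant under
swapping the two groups, so a 3-vs-3 permutation grid resolves p only in
steps of 0.1; for null genes at n = 6 the chi-square approximation
carries an irreducible per-gene conditioning error (median ≈ 0.05–0.07)
that no implementation removes, checked as a median bound at 4-vs-4.

### Sex-chromosome scan

Per-gene log₂ M:F uses normalized counts with pseudocount 0.5. Per-sex
SNP density counts heterozygous sample-site events — alt frequency inside
[0.2, 0.8] (inclusive) with depth ≥ 20 — divided by (individuals of that
sex × transcript kb). The heterozygosity band, rather than hard genotype
calls, keeps the scan usable straight from allele depths; both band and
depth floor are parameters.

Both tracks are smoothed with a centered 10-gene moving average,
truncated at chromosome ends; for even windows the center is offset left
(offsets −5…+4), a stated convention so results are reproducible. A gene
is non-PAR-flagged when smoothed log₂ M:F > τ_expr = 0.5 (the midpoint
of the two dosage modes at 0 and 1) *and* the smoothed male/female
density ratio exceeds τ_dens = 1.5 (ε = 1e−9 guards empty female
density); runs of ≥ min_run = 5 flagged genes become non-PAR-like
regions, and the region list partitions the ordered genes.

The PAR boundary is the k minimizing the summed squared error of fitting
one mean to genes [0, k) and another to [k, n), by exhaustive search with
ties broken toward the smallest k (a constant profile therefore yields
k = 0, i.e. no PAR).

## The synthetic generator

`simdata` simulates at the count/allele-depth level — alignment and
variant calling are upstream tools whose *output* statistics are modelled,
which keeps a full cohort desk-scale and the whole pipeline testable.

Defaults describe a two-species cohort of 8 birds each with equal sex
ratio: 300 Z-syntenic genes of which the first ⌊2/3 · 300⌋ = 200 are PAR
(large ancestral-style PARs, as in paleognaths), 4000 autosomal genes,
two globins jointly absorbing 20 % of every library, NB counts with mean
depth 500 per gene and per-gene α ~ Gamma(shape 2, mean 0.1), male means
×2 outside the PAR, 10 % of genes carrying a species log₂FC ~ N(0, 1),
diagnostic SNPs at 1/kb (alt fixed in one species, absent in the other)
and within-species SNPs at 0.5/kb with the second species at twice that
rate (unequal diversity between a bottlenecked and a larger remnant
population), segregating at allele frequency U(0.1, 0.5). Site depth
equals the gene's count for that sample (uniform coverage along the
transcript); alt depth is Binomial(depth, dosage) with dosage 0/0.5/1,
and hemizygous females draw a single Bernoulli allele — heterozygosity is
impossible by construction. Transcript lengths are log-normal (median
2 kb); each transcript carries one planted ORF covering ~55 % of its
length so ORF discovery has an unambiguous answer.

The autosome count matters more than it looks: quantile normalization
forces every sample onto one distribution, so if sex-linked genes were a
large share of the library the male non-PAR excess would be partly
normalized away and the upper dosage mode would fall visibly below
log₂ = 1. Real assemblies have hundreds of Z genes among tens of
thousands of transcripts; 4000 autosomes keep the non-PAR share (~2 %)
realistically small while staying fast enough for seeded replicate tests.

What the generator does **not** emulate: per-gene baseline expression
differences (all non-globin genes share one mean), sequencing error in
allele depths, indels, isoforms, mapping bias, batch effects, or
covariance between neighbouring genes. Passing recovery tests therefore
demonstrates the estimators are correct under the stated model, not that
real libraries meet the model; on real data the coverage filter interacts
with expression level, so marker recall is expression-weighted.

## Validation problem sizes

Seeded-replicate checks use: 20 seeds for the two-fold dosage
Monte-Carlo and for diagnostic precision/recall (scaled gene sets where
only per-site statistics matter), 50 seeds for PAR-boundary recovery at
defaults (≥ 90 % within ±3 genes), 2,000 null genes for test
calibration, 100 seeds for power. `scripts/acceptance.py` re-runs the
accounting arithmetic on the published per-species read totals and the
simulation-based recoveries (3 dosage/SNP seeds, 20 boundary seeds),
deriving every stream from `--seed`.

## Known limitations

- The DE test's χ²₁ reference is asymptotic; at n = 3 per group exact
  permutation is preferable and provided as an oracle only.
- The density filter is a per-contig rate, not linkage-aware pruning.
- Non-PAR calling depends on τ_expr/τ_dens/min_run; the defaults are
  documented, not fitted, and regions near the boundary inherit the
  moving average's ±(window/2) resolution.
- The boundary fit assumes a single contiguous PAR; interleaved
  PAR/non-PAR architectures (inversions) are reported via region calls
  instead.
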