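# Methods

## The design being modelled

The pipeline targets a two-stressor factorial experiment on cultured human
fibroblasts: gravity (standing 1G, `ST`, vs continuous 3D-clinostat
rotation simulating microgravity, `RO`) crossed with radiation (none, 1 Gy
X-ray, 1 Gy carbon ion) and harvest time (3 h, 24 h after exposure). The
ten conditions carry 6 replicates for the two non-irradiated conditions and
3 for the eight irradiated ones — 36 RNA-seq samples. The scientific
question is not whether radiation changes expression (it does, strongly)
but whether the *response to radiation is different under microgravity*:
an interaction, not a main effect.

## Count model and the exact test

Counts are modelled negative-binomial: for gene *g* in sample *j* of
condition *c*, `y ~ NB(mean = f_j * mu_gc, var = mu + phi mu^2)` with a
per-sample library factor `f_j` and a common dispersion `phi`. With the
small replicate numbers of this design (N=3 per irradiated condition),
per-gene dispersion estimates are hopeless; a common dispersion shared
across genes is the appropriate level of pooling, and tagwise shrinkage is
deliberately out of scope.

**Library-size equalization.** The exact test conditions on group sums,
which is valid only when samples share a library size. Counts are therefore
mapped to a common size (the geometric mean of the factor-adjusted library
sizes) by a quantile-to-quantile NB transformation: each observation's tail
probability under its input-mean distribution is re-expressed as the
quantile of the output-mean distribution, averaging a normal and a gamma
continuous approximation. Gene-wise expected counts use the overall
relative abundance of the gene across the contrast's samples.

**The conditional test.** For groups of sizes `n_a`, `n_b` with equalized
per-sample mean `mu` and common `phi`, the group sums are NB with sizes
`n_a/phi`, `n_b/phi` and a shared success probability, so conditionally on
the total `s` the observed split follows `BetaBinomial(s, n_a/phi,
n_b/phi)` — independent of `mu`, which is why the test is exact. The
two-sided p-value sums the probabilities of all splits whose probability
does not exceed the observed one (the "small-p" rejection region, standard
for this test and well defined on asymmetric supports; doubling the
one-sided tail is not used). `phi = 0` degenerates to the binomial split of
a Poisson total. For totals above 20,000 the support enumeration is
truncated to the central `1 - 2e-13` probability mass; the truncated
p-value agrees with full enumeration to better than 1e-9 (verified in the
test suite). A tie tolerance of 1e-10 relative guards against equal
probabilities lost to floating point. Zero totals are untestable and return
p = 1 by convention.

**Dispersion (qCML).** The common `phi` maximizes the conditional
log-likelihood of within-group counts given the group totals, summed over
genes and over all ten condition groups, on `phi` in `[0, 10]` by
golden-section search (tolerance 1e-6). Because the equalization itself
depends on `phi`, pseudo-counts are computed at a method-of-moments pilot
value and the estimate is refined once. Genes with total count <= 5 are
excluded from estimation (dominated by discreteness, nearly uninformative).
A method-of-moments fallback covers degenerate likelihoods (estimate at the
upper boundary or non-finite); an estimate at the lower boundary is
reported as exactly 0 (Poisson). On the default fixture (2,000 genes,
truth 0.1) the estimate is accurate to three decimals; the test suite
requires 25% accuracy at phi = 0.2 and 6 vs 6 replicates.

**Significance convention.** Following the screening convention this
pipeline reproduces, contrasts are judged at unadjusted p < 0.05 and
absolute fold change > 2 (fold change computed on normalized group means
with a 0.01 pseudocount on both means, mirroring the heatmap transform's
pseudocount). Benjamini-Hochberg adjustment is available behind a flag for
reuse, but is off by default: the screen's inferences are confined to an
82-gene panel and a handful of contrasts, not the 57k-gene transcriptome.

## Normalization

TMM-style scaling factors: the reference sample is the column whose upper
quartile of relative abundance is closest to the mean upper quartile; for
each sample, gene-wise log2 ratios (M) against the reference are trimmed by
30% on M and 5% on abundance (A), and averaged with inverse approximate
variance weights; the exponentiated factor set is rescaled to geometric
mean 1. Normalized expression is counts per million of the factor-adjusted
library size. Genes that are zero everywhere stay in the output so the gene
universe is aligned across stages.

Two properties deserve a caveat. CPM column sums equal `1e6 / factor`, so
they are equal across samples exactly when factors are 1 — true for pure
depth differences, but under NB replicate noise (and real composition
shifts) factors scatter by a few percent, and column sums with them. And
because the precision weights depend on depth, rescaling one column's
counts reproduces its normalized values only to ~1e-3 relative, not
exactly. Both are properties of weighted TMM itself, not implementation
artifacts.

## The five-step screen

* **Step 1** — intersect the detected genes (>= 1 nonzero count) with the
  cell-cycle panel.
* **Step 2** — keep genes whose *maximum* normalized value across the
  standing-1G samples reaches 1000. "1G sample" is read as *all* standing
  samples (irradiated included), with the non-irradiated-only reading one
  configuration flag away; likewise the maximum is over replicates by
  default, with a condition-mean option. The threshold is a configuration
  field because it lives on the normalization scale: it is calibrated
  against the default fixture's library composition and must be revisited
  for other data.
* **Step 3** — per irradiation arm (X3, X24, C3, C24), exact test of
  ST-irradiated vs RO-irradiated (3 vs 3). A gene passes with p < alpha in
  at least one arm; all per-arm p-values are retained in the output
  records.
* **Step 4** — only for genes failing step 3: exact test of non-irradiated
  ST vs RO (6 vs 6), judging a microgravity-alone effect. Passing genes
  proceed to step 5 and are treated identically to step-3 entrants from
  there on.
* **Step 5** — per gene, `r = mean(ST) / mean(RO)` over non-irradiated
  samples (means of normalized values across the N=6 groups; a single
  per-gene scalar). Each rotating irradiated mean is converted by `r`, and
  the adjusted fold change `r * mean(RO-arm) / mean(ST-arm)` classifies the
  arm: strictly below 1 `enhanced_decrease`, strictly above
  `enhanced_increase`, exactly 1 none (a strict reading of "decrease or
  increase"). A zero non-irradiated RO mean makes the gene unclassifiable
  and unselected. The per-gene summary class is taken from the arm with the
  smallest step-3 p-value — the arm with the strongest interaction
  evidence.

A gene is *selected* when it survives steps 1-2 and passes step 3 or 4.
The funnel is checked for monotonicity (each stage a subset of the
previous) on every run. Adjusted fold changes are emitted for all arms, not
only the significant ones, so both readings of "which arms get a fold
change" are available in the records.

Relative expression summaries divide each condition mean by the per-gene
maximum of condition means (so exactly one condition per gene sits at 1.0),
with standard errors computed from replicate-level relative values and
direction calls (up/down/ns) from the exact test on requested condition
pairs.

## Heatmap transform

Per gene and condition, the displayed value is `log2(mean CPM + 0.01)` —
transform of the replicate mean, not mean of transforms, because the
display shows one cell per condition. Conditions are grouped vs the ST
reference at `|delta| < 1` -> no change, else down/up by sign; `|delta| =
1.0` exactly is assigned to the changed group ("smaller than 1.0" being
exclusive, its complement is inclusive). The exported metadata records the
color-scale bounds (-7, 0, +13).

## Enrichment

Plain hypergeometric upper tail `P(X >= overlap)` on the 2x2 overlap table,
equivalent to one-sided Fisher (asserted to 1e-12 in tests); the universe
defaults to all detected genes. Service-specific modified scores used by
web annotation tools are intentionally not reproduced — their results
depend on database versions and are not reproducible from a count matrix.
Reports list the top three significant sets per list, without padding.

## The synthetic generator

The generator is the package's study stand-in, not a tuning surface. Its
defaults encode the design above: 36 samples in 10 conditions; 2,000 genes
as a desk-scale stand-in for a full transcriptome; an 84-gene cell-cycle
panel of which 82 are detected (two members get zero expression); 13 panel
genes planted in a high-expression tier (log-normal, median 2,000 expected
counts) so that exactly they clear the step-2 threshold; 9 of the 13 carry
a gravity x radiation interaction of +/-2 log2 units applied only under
RO-irradiated conditions (6 enhanced-increase, 3 enhanced-decrease,
mirroring the checkpoint-release direction mix of the motivating biology);
the other 4 high genes are radiation-responsive but gravity-insensitive, so
they exercise the step-3-fail / step-4-fail path. Background genes are
log-normal (median 60 expected counts, sdlog 1.2 — heavy-tailed like real
RNA-seq abundance); 40 get a +2 log2 radiation effect, 40 get -2 (the
generic damage-response programs driving the heatmap); 30 low-expression
panel genes get the -2 radiation effect (the cell-cycle shutdown program);
3 background genes at mean 500 form a microgravity-alone program (+1.5
log2 in all RO conditions) that exercises step 4's power and the
enrichment stage. Non-planted panel gene means are capped at 80 counts so
replicate maxima stay safely below the step-2 threshold. Dispersion
defaults to phi = 0.1 (typical for cell-line bulk RNA-seq); library
factors are uniform on 0.7-1.3 so normalization genuinely matters. Counts
are drawn as a gamma-Poisson mixture from a single seeded generator;
identical seeds give bit-identical fixtures.

What the generator does **not** emulate: gene-length effects, GC/batch
effects beyond library size, correlated genes, time-dependent effect
profiles (effects are constant across the 3 h / 24 h arms), and any real
biological pathway structure — the gene symbols of the panel are a
plausible synthetic stand-in for a commercial cell-cycle array list.
Passing recovery tests therefore demonstrates the *procedure's*
correctness and power under the declared model, not performance on real
libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run at the generator's default scale
(2,000 genes x 36 samples; 10-20 seeds for recovery medians; 2,000 null
genes for calibration), chosen as the smallest sizes at which the screen's
funnel counts are stable and power is near its asymptote. Oracle
equivalence of the exact test is enumerated exhaustively for totals up to
50, group sizes up to 6 and phi in {0, 0.1, 0.5} (group-label symmetry,
verified separately, covers the transposed cases). Golden-section tolerance
1e-6 on phi; truncation mass 1e-13 per tail; tie tolerance 1e-10 relative.

## Known limitations

* Common dispersion only; genes with gene-specific overdispersion will be
  mis-calibrated in proportion to their deviation.
* The step-2 threshold is scale-coupled (see above).
* The exact test is conservative at very low totals (discrete support);
  calibration is validated in the expression range the screen operates in
  (hundreds of counts and up), which the step-2 filter guarantees.
* The screen's step-3 "any arm significant" aggregation controls no
  family-wise error across the four arms; with a 13-gene step-2 set this
  admits roughly one alpha-level false selection per run, visible in the
  recovery tests' false-positive budget.
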