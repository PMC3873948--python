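# Methods

`cistrans` dissects intra-specific regulatory divergence between two
inbred lines from allele-specific RNA-Seq counts. The design point is a
cross without replicate libraries: two parental libraries and one pooled
F1 library whose reads have been assigned to parental alleles at fixed
SNPs. All inference is per gene, on counts.

## Model and tests

For a gene with parental counts (p1, p2) and F1 allele counts (h1, h2),
three likelihood-ratio (G) tests on 1 df are run:

- **TDE** (total differential expression): p1 : p2 against the ratio of
  effective parental library sizes. A goodness-of-fit G-test — the null
  ratio sits on whole-library sums (millions of read pairs) and is
  treated as a known constant rather than an estimated margin.
- **cis**: h1 : h2 against the global allelic ratio (effective
  allele-column sizes) multiplied by the gene's mapping-bias factor.
  Both alleles share one cellular environment in the F1, so a residual
  allelic imbalance is cis-regulatory. Same goodness-of-fit form.
- **trans**: the 2×2 independence G-test of (p1, p2) against (h1, h2)
  after bias correction and rescaling to common effective depth
  (rounded half-to-even to keep integer counts, which makes the
  statistic deterministic and symmetric). Both ratios are gene-level
  measurements here, hence the independence form with estimated
  margins. A change in allelic ratio between parental and hybrid
  backgrounds indicates trans-acting divergence.

G = 2·Σ O·ln(O/E) over cells, with 0·ln 0 = 0; p-values from χ²(1); no
Williams or Yates correction. Tables with a zero margin are degenerate:
they are reported as G = 0, p = 1 with a flag rather than dropped, so
every output table covers the same gene set. Each test family is
Benjamini–Hochberg adjusted separately across genes, significance at
q ≤ 0.05 by default.

The goodness-of-fit choice for TDE/cis versus full independence is
exposed as a sensitivity switch (`gtest_form: independence` re-estimates
the library ratio from a 2×2 table whose second row is the rest of the
library); with genes tiny relative to the library the two are nearly
identical. Whether the bias factor also enters the trans test is a
consistency choice (`trans_apply_bias`, default on): the correction is a
property of the hybrid read assignment, so every use of (h1, h2) should
see it.

## Mapping-bias correction

Allele assignment can retain a residual preference for one parental
allele even after mapping to both parental genomes. The per-gene
correction factor — derived upstream from simulated reads, consumed
here as an input column — multiplies the cis null ratio and divides h1
in the trans test. With factor c the null becomes h1/h2 = c·(global
allelic ratio): a gene whose imbalance is pure mapping artifact scores
G = 0. Simulations with c = 2 confirm the corrected test keeps its 5%
type-I error while the uncorrected one rejects nearly always.

## Normalization

TMM (trimmed mean of M-values) is computed jointly over the four count
columns, treating the two hybrid allele columns as pseudo-libraries;
the trans test contrasts parental against hybrid-allele columns, so all
four must share a scale. Defaults follow the method's convention: 30%
two-sided trim on M, 5% on A, inverse-asymptotic-variance weights,
reference column chosen as the one whose 75th-percentile count fraction
is closest to the mean. Genes with a zero in either column of a pair
are excluded pairwise (no pseudo-counts in normalization); fewer than
10 usable genes in a pair falls back to factor 1.0 with a warning.
Factors are rescaled to geometric mean 1 and multiply the raw
*full-library* totals (summed before the coverage filter) into
effective sizes. The implementation reproduces edgeR's
`calcNormFactors(method="TMM")` to ten decimals on a random matrix;
the test suite pins frozen oracle factors.

Computing TMM on parent-pair and allele-pair separately would also be
defensible; the joint computation is the default because a common scale
is what the trans test assumes.

## Filtering

Genes enter testing when p1 + p2 ≥ 20 (boundary included). Library
totals for null ratios are never recomputed after filtering.

## Classification

With T/C/R the three significance flags:

| T | C | R | category |
|---|---|---|----------|
| − | − | − | conserved |
| + | + | − | cis |
| + | − | + | trans |
| − | + | + | compensatory |
| + | + | + | cis+trans or cis-by-trans by direction |
| other | | | ambiguous |

In the all-significant branch, the sign of log2(h1′/h2′) (cis
direction) is compared with the sign of log2(p1′/p2′) − log2(h1′/h2′)
(trans direction): equal signs reinforce (cis+trans), opposite signs
oppose (cis-by-trans). An exactly zero direction is uninterpretable and
goes to ambiguous rather than being given an arbitrary sign.

Effect sizes: cis-magnitude = |log2(h1′/h2′)|, trans-magnitude =
|log2(p1′/p2′) − log2(h1′/h2′)| on normalized, bias-corrected values.
A pseudo-count of 0.5 (configurable) is added to all four normalized
values when any raw count is zero — magnitudes need finite values for
ranking; the tests never see pseudo-counts because that would distort
their sampling distribution.

Inheritance modes compare F1 total expression (h1 + h2, effective size
the sum of the allele columns) with each parent via the same
goodness-of-fit G machinery, BH per comparison family: over-/
under-dominant when F1 differs significantly from both parents and
lies above/below the parental range; additive when the parents differ,
F1 differs from both and lies strictly between; dominant toward the
parent F1 is indistinguishable from when parents differ. All residual
patterns fold into conserved expression so the five modes partition
every tested gene. The additive-vs-other contrast of cis-magnitudes
(one-tailed rank-sum, additive stochastically greater; normal
approximation with tie and continuity correction) excludes
conserved-expression genes.

## Power simulation

Counts are Poisson. At expression level n and imbalance γ ≥ 1 the rate
pair is λ₁ = 2n/(γ+1), λ₂ = 2nγ/(γ+1) (λ₁+λ₂ = 2n, λ₂/λ₁ = γ); hybrid
allele rates are halved. Pure cis: parents at (λ₁, λ₂), hybrid at
(λ₁/2, λ₂/2). Pure trans: parents imbalanced, hybrid balanced at n/2.
Combined: separate γ_P and γ_H, hybrid halved. The imbalance grid runs
1 to 10 in steps of 0.2 (46 points); per point 10 000 genes are
simulated with expression levels resampled from an observed set or,
dataset-free, from a log-normal stand-in (median 100, log-sd 1). The
rejection rule defaults to nominal α = 0.05 per gene — the cleanest
power definition — with BH across the simulated genes available to
mimic the full pipeline.

Combined effects are reported against the index |γ_P − γ_H| + 1. The
pair realizing an index value g is a same-direction construction chosen
once: γ_H = (g+1)/2 and γ_P = γ_H + (g−1). Both components are active
for g > 1 and the trans test's effective contrast γ_P/γ_H grows much
slower than g, which reproduces the characteristic power deficit of
combined architectures relative to the pure curves. Detection uses the
cis test for cis genes and the trans test for trans and combined genes,
with library ratios known and balanced (the simulation generates no
library-level variation).

## Synthetic data generator

The generator emulates the analysis input — not reads, not sequence.
Each gene draws an architecture from a configurable mixture (defaults
loosely mirror intra-specific ASE studies: 55% conserved, 16% trans,
9% cis, 8% compensatory, 6% each combined class), an expression level
(log-normal, median 100, log-sd 1, creating the realistic power
gradient), and |log2 γ| effect sizes from an exponential (mean 1.0)
drawn separately for the cis and trans components, with symmetric ±
direction signs. Latent log2 imbalances (m_P, m_H) per architecture:
conserved (0, 0); cis (m, m); trans (m, 0); compensatory (0, m);
cis+trans m_P = m_H + e_t with matching signs; cis-by-trans
m_P = m_H − e_t with opposing ones. Rates follow the Poisson power
construction, scaled by library-depth multipliers (defaults 1.0, 1.2,
0.9 to exercise normalization) with the bias factor multiplied onto the
h1 rate. SNP counts per gene are 1 + Poisson(3.4), echoing the ~4.4
fixed SNPs per gene typical of such crosses.

What the generator does not emulate: biological overdispersion beyond
Poisson (no replicates existed to estimate it), gene-length effects,
correlated expression between genes, or alignment-level artifacts (bias
factors are drawn, not derived). Passing recovery tests therefore show
the inference machinery is correct under its own model, not that real
data meet that model.

The strong-effect benchmark preset (γ ≥ 4 via a +2 floor on |log2 γ|,
n ≥ 500, 5 000 genes, no bias, equal depths; cis 10% / trans 10% /
conserved 80%) is the regime where pure-category recovery should be
nearly perfect: measured sensitivities are ≥ 0.95 and conserved genes
pick up a spurious label in ~2% of cases — the rate BH adaptivity
admits with three families rejecting ~20% of genes each, comfortably
below the 5% design bound. In mixtures that include combined
architectures the cis-by-trans class recovers at only ~0.7–0.8
sensitivity even at strong effects: its total-expression signal is the
difference of two opposing components and is often small. That is a
property of the classification scheme, not an implementation artifact.

## Numerical choices and degenerate inputs

- Rounding of rescaled counts is half-to-even (trans test only).
- Zero-margin tables: G = 0, p = 1, flagged, never dropped.
- BH is statsmodels' step-up (`fdr_bh`), verified against the literal
  definition; q-values restore input order and preserve ties.
- Reported problem sizes: calibration and power use 10 000 simulated
  genes per condition (Monte-Carlo SE ≤ 0.005 on a rate near 0.05);
  the recovery benchmark uses 5 000 genes; the study-scale preset uses
  7 631 genes, the size of the motivating fly dataset.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical tables.

## Known limitations

- Poisson sampling only; with biological replication a dispersion
  model (negative binomial) would be preferable and is out of scope.
- The deposited gene-summary reader accepts openpyxl-readable
  workbooks; legacy binary spreadsheets must be converted first.
- The reproduction harness compares recomputed calls against the
  labels a summary table carries; agreement depends on the upstream
  table having used the same decision rules.
- Pooled reciprocal crosses: one hybrid library, no imprinting or
  parent-of-origin fields.
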