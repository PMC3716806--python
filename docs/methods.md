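# Methods

This note records the statistical model the package implements, the choices
made where the method description left the design open, and what the
synthetic data do and do not establish about behavior on real cohorts.

## Data model and quality control

Genotypes are held as a samples × SNPs dosage matrix counting copies of the
**minor** allele (0/1/2, NaN for missing).  Orientation is fixed once at
load time from the input cohort's allele frequencies (ties at 0.5 break to
the alphabetically first allele), which makes the MAF filter and the
distance metric orientation-free as long as one matrix is used throughout.
Missing genotypes are retained at load and handled pairwise-complete
downstream; no call-rate filter is imposed by default.

SNP filters: the Hardy-Weinberg test is the 1-df chi-square goodness of fit
against HWE proportions at the observed allele frequency — at a removal
threshold of 1e-8 the decision lives deep in the tail where the chi-square
is the standard GWAS choice; monomorphic SNPs return p = 1 (no departure is
testable).  Removal bounds are strict (`p < 1e-8`, `MAF < 0.02`), so
boundary values are retained.  A SNP failing both filters is reported under
HWE.

Sample screening takes the top 10 principal components of the standardized
matrix (center 2f, scale sqrt(2f(1−f)), missing → 0) and flags samples
beyond 6 robust SDs on any component.  The spread estimate is the median /
1.4826 × MAD of the still-unflagged samples, refined for up to 5 rounds.  A
plain mean/SD rule is structurally unable to catch clustered outliers: a
cluster holding fraction *f* of the cohort can never exceed
sqrt((1−f)/f) naive SDs (≈ 4.4 at f = 0.05) on the component it creates,
because it inflates that SD itself.  The robust scale references the bulk
noise instead; on homogeneous cohorts the two rules agree and nothing is
flagged.  Stratification per phenotype is a two-sample t-test of case vs
control scores on each retained component.

## Phenotype coding

The seven binary traits follow the NASH CRN scoring conventions:
steatohepatitis definite vs absent (borderline excluded), NAS ≥ 5 vs < 5,
steatosis grade ≥ 2, lobular inflammation grade ≥ 2, ballooning grade 2 vs
grade 0 (grade 1 excluded), fibrosis stage ≥ `fibrosis_cut` (default 2) vs
below, cirrhosis yes vs no.  Unknown values are excluded everywhere and
excluded samples never enter any downstream computation for that trait.
The fibrosis cut is configurable because "significant fibrosis" (≥ 2) and
"advanced fibrosis" (≥ 3) are both defensible contrasts; the default is the
former.  NAS is validated against the sum of its three components at parse
time to prevent silent miscoding.

## Universe and SNP selection

A SNP is eligible when it survives QC and maps (via the supplied SNP→gene
file; the mapping provenance is the caller's responsibility) to a gene
appearing in at least one pathway; pathways retaining fewer than 5 eligible
genes are dropped.  Per phenotype, each gene is represented by the SNP with
the greatest |Cochran-Armitage trend statistic| (scores 0/1/2, missing
dropped per SNP), computed on the trait's case/control samples.  Ties break
by smaller p, then lexicographic SNP id, so selection is deterministic.  A
SNP mapping to several genes may represent each of them; within one pathway
shared SNPs are deduplicated, which is why a pathway's SNP count never
exceeds its gene count.

## Distance, distinction, and the resampling null

The pairwise distance is the mean absolute dosage difference over
pairwise-complete SNPs — the simplest metric consistent with 0/1/2 data, and
one a brute-force oracle can recompute in a few lines.  The distance score
is computed as a *difference of logarithms*,
S = log2(D̄_ctrl + ε) − log2(D̄_case + ε), not a log of a ratio: IEEE
subtraction is exactly antisymmetric, so swapping case/control labels
negates every S bitwise.  The guard ε = 1/(2·|SNPs|·N) bounds S when a
leave-one-out mean distance is exactly zero and shrinks as the problem
grows.  DS is the difference of class means of S — the minimal statistic
with exact antisymmetry under label swap at fixed scores; any scale effect
is absorbed by the resampling null.  Note that recomputing S *and* DS after
a label swap leaves DS invariant (both flips cancel); antisymmetry is a
per-operation property.

Dummy pathways match the real pathway on **gene count**, and per-gene
best-SNP selection is re-applied to each dummy set so the winner's-curse
bias of the real statistic is reproduced in the null (a raw SNP-count match
is available via `dummy_match="snps"`).  Dummy gene sets are drawn
uniformly without replacement from all eligible genes and may overlap the
real pathway.  p(DS) is the raw fraction of dummy DS ≥ observed DS — ties
count, and 0.000 is a legitimate value; an add-one corrected version
(1+count)/(1+B) is reported alongside for downstream ranking.  Each pathway
draws from its own seeded stream (seed ⊕ pathway ⊕ trait folded through
CRC32 into a SeedSequence), so results are reproducible per pathway
regardless of execution order or parallelism.

The production path avoids the O(N²·K) pairwise matrix: with dosages in
{0,1,2}, the per-sample sum of distances to a class decomposes over the
three dosage values into three (N×K)·(K) products against per-class
genotype-count vectors.  Columns containing missing genotypes fall back to
the exact pairwise-complete computation (one-hot BLAS products).  The two
paths agree to machine precision and are cross-checked in the tests against
an explicit double-loop oracle.

## Odds ratios and multiplicity

Case status is regressed on S (intercept + slope, ML logistic fit); OR =
exp(slope) per unit S with a two-sided Wald p.  Under perfect or
quasi-perfect separation the MLE diverges: the fit is flagged
non-converged, the OR is displayed capped (">10" by default — capping also
triggers on converged estimates above the cap), and the p-value falls back
to the score test, which is well defined at β = 0, so every pathway carries
a p-value into the FDR family.  BH adjustment runs across **all** pathways
analyzed for the trait; restricting the family to the displayed subset
would be incoherent.  The significance table filters to p(DS) < 0.05
(strict) for display only.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular cohort: HWE genotypes at MAFs uniform on (0.05, 0.5); optional
two-subpopulation Balding-Nichols structure (off by default — the target
setting is a deliberately homogeneous cohort); a round-robin SNP→gene
partition; random gene-set pathways of 5–100 genes; and a logistic liability
with additive per-SNP effects confined to one causal pathway, the simplest
model under which a joint multi-SNP signal exists while individual SNPs can
stay sub-significant.  The steatohepatitis diagnosis tracks the Bernoulli
case draw (with a 5% borderline fraction); the six remaining histologic
columns derive from the same liability through independent N(0,1) noise and
fixed bin cuts, with the fibrosis cuts placed so that roughly 15% of a null
cohort reaches stage 4, matching the cirrhosis prevalence of biopsy-proven
NAFLD series; NAS is the exact sum of its three components.  Everything is
a deterministic function of one seed.

What the generator does **not** contain: linkage disequilibrium, haplotype
structure, chip ascertainment, relatedness, covariates, or realistic
pathway overlap topology.  Passing calibration and recovery tests therefore
demonstrates correctness of the machinery under the stated model, not power
or error control on real genotype data, where LD between a pathway's SNPs
and its neighbors is the main unmodeled force.

## Study sizes used in the checks

The calibration study uses 300 samples × 5,000 SNPs × 100 pathways with
B = 200 dummy draws; the recovery study uses 20 cohorts of 600 samples with
ten causal SNPs at β = 0.4 and the same B — sizes chosen so the full suite
runs in minutes on a single CPU while leaving the binomial acceptance bands
meaningful.  The enumeration check uses a 6-gene universe (20 possible
3-gene dummies) against B = 2,000 Monte-Carlo draws.

## Known limitations

- The distance metric and DS are declared, documented replacements for the
  original method's unpublished internals, not recoveries of them; results
  are comparable in spirit, not numerically.
- The score-test fallback p under separation is conservative relative to a
  penalized-likelihood (Firth) fit, which is not implemented.
- p(DS) resolution is 1/B; ranking among pathways tied at 0 relies on the
  add-one corrected value and DS magnitude.
- The PCA screen assumes outliers are a minority (< ~40%) of samples; the
  robust scale breaks down beyond that.
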