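# Methods

## The model

`decstat` treats a genomic region as two association *patterns*: the
vector of per-SNP evidence log₁₀(1/p) for a disease trait and the same for
the expression of a nearby gene. If one variant (or a tight LD cluster)
drives both traits, the two patterns are positively correlated, and the
sign relation between the per-allele effects says whether the
expression-raising allele raises or lowers disease risk. The DEC statistic
captures both facts at once:

* σ(x, y): Spearman rank correlation of the unsigned patterns over
  informative SNPs — pattern similarity;
* Pen = 1/(1 + e^(−k1·(σ−k2))): a logistic gate on that similarity,
  default steepness k1 = 30 and midpoint k2 = 0.3, so Pen = ½ at σ = 0.3,
  ≈ 0.95 at σ = 0.4 and ≈ 0.05 at σ = 0.2;
* SC(x, y): Spearman correlation of the signed points
  (sign(β_dis)·x, sign(β_eqtl)·y), every SNP entered twice — once per
  choice of reference allele, the second point being the joint negation of
  the first. The duplicated set is symmetric under (u, v) → (−u, −v), which
  makes SC, and hence DEC, exactly invariant to per-SNP reference-allele
  choices (a property the test suite checks to 1 × 10⁻¹²);
* DEC = Pen × SC ∈ (−1, 1).

Informative SNPs are those with log₁₀(1/p) ≥ 1.2 (p ≲ 0.063) in at least
one scan. The cutoff is inclusive here; since p-values are continuous,
boundary ties have probability zero and the choice is cosmetic — it is
configurable (`DECConfig.informative_threshold`). At least 3 informative
SNPs are required (`min_informative`); a rank correlation on fewer points
carries no information. σ is computed on the informative subset by
default; `sigma_scope="all"` uses every harmonized SNP instead, for users
who prefer the whole-region reading of pattern similarity.

Zero effect estimates (possible with discrete genotype data — a slope of
exactly 0 occurs with positive probability) are assigned positive sign
with a logged warning rather than crashing the pipeline.

## Significance: the in-silico eQTL null

A large DEC could reflect nothing more than the region's LD: any eQTL
anywhere in the region produces a smooth association pattern that may
resemble the disease pattern by chance. The null therefore holds the
genotypes — and the disease pattern — fixed and asks how often a *random*
eQTL of the same strength, placed anywhere in the region, would score as
high. For each SNP j: an expression trait yⱼ = βⱼ·gⱼ + ε is synthesized
with βⱼ = √(r²/((1−r²)·var(gⱼ))), so gⱼ explains r² of var(yⱼ) in
expectation; yⱼ is rescanned against **all** SNPs on the real genotypes,
so the simulated pattern inherits the LD; the same DEC configuration
scores it against the unchanged disease scan.

"The same variance as the true eQTL" is operationalized as the sample R²
between expression and dosage at the observed scan's top SNP — the only
single-number strength summary a scan provides. A fixed r² can be supplied
instead (`NullConfig(variance_explained_mode="fixed", r2=...)`), and the
choice is reported in the output metadata (`r2_used`).

The empirical p-value is the exceedance fraction n(simulated DEC ≥
observed DEC)/N, which can legitimately be 0 at resolution 1/N; the
permutation-valid estimator (n+1)/(N+1) is available as
`estimator="add-one"`. Simulations whose informative set falls below
`min_informative` score −∞ (non-exceeding): dropping them would bias p
downward. One simulated eQTL per SNP is the default; `n_replicates_per_snp`
sharpens the null's resolution beyond 1/n_snps.

A subtlety worth knowing: when the eQTL signal dwarfs the disease signal
(easy to arrange in simulation: h² = 0.2 at n = 2000 gives p ≈ 10⁻⁹⁰),
the informative set is dominated by SNPs significant in only one scan, and
σ over that set is small or negative — the penalty then pushes every DEC,
observed and simulated alike, toward zero. The exceedance test is
unaffected, because observed and null live on the same compressed scale;
only the *absolute* magnitude of DEC loses interpretability in that
regime.

## The synthetic cohort

No individual-level data ship with the package; the generator emulates the
statistical shape of a single-region eQTL + case/control study and is
itself part of the tested surface.

* **Genotypes.** Two latent haplotypes per individual from a within-block
  AR(1) Gaussian copula: corr(zᵢ, zⱼ) = ρ^|i−j| inside a block, 0 across
  blocks; a haplotype carries allele 1 at SNP s iff zₛ < Φ⁻¹(mafₛ).
  Sites are in Hardy–Weinberg proportions in expectation and dosage r²
  decays monotonically with distance — the one LD feature the null's
  validity rests on. No recombination-map realism, no coalescent history,
  no population structure.
* **Expression.** y = β·g_c + ε with ε ~ N(0, 1) and β chosen so the
  causal dosage explains exactly h² of the variance in expectation;
  mean-centered. Generated "already normalized": the microarray-style
  preprocessing a real panel needs (variance stabilization, batch/covariate
  correction) is out of scope, so passing tests say nothing about those
  steps.
* **Disease.** Case probability expit(α + log-OR·g_c) with α solved by
  Brent's method on the realized dosages so the mean case probability
  equals the target prevalence exactly (numerical, not analytic, by
  design). A population Bernoulli draw — no case/control ascertainment —
  keeps the logistic scan correctly specified.

Defaults are the package's standing study conditions: 320 individuals,
200 SNPs over 600 kb, MAF ∈ (0.05, 0.5) uniform, ρ = 0.8 in blocks of 20
(realistic-looking block LD with adjacent-dosage r ≈ 0.5), prevalence 0.5
(balanced case/control sampling shape). Three independent seed substreams
(genotypes / expression / disease) hang off one master seed: identical
config + seed is byte-reproducible, and regenerating one phenotype leaves
the rest untouched.

## Association scans

Both scans are computed in-repo, vectorized across SNPs:

* eQTL: simple OLS of expression on dosage with intercept; two-sided t
  test on the slope, n − 2 df. Agreement with the explicit
  normal-equation oracle is tested to 1 × 10⁻⁸.
* disease: per-SNP logistic regression by Newton scoring (IRLS) to score
  sup-norm ≤ 1 × 10⁻⁸ or 100 iterations; two-sided Wald test (the usual
  GWAS output; the difference from a likelihood-ratio test is immaterial
  at these scales). Agreement with `statsmodels.Logit` is tested to
  1 × 10⁻⁶. Separation — which can satisfy the gradient criterion at a
  divergent estimate — is flagged when |log-odds| > 12; estimates are
  reported at the cap with a warning rather than as NaN.

Monomorphic SNPs are dropped from either scan with a logged warning (the
same policy in both, so harmonization stays well defined). Dosage coding
is additive 0/1/2 throughout. Harmonization intersects on SNP id, flips
the eQTL record where its allele pair is swapped relative to the disease
record, and drops (and reports) irreconcilable pairs; strand is not
tracked — A/T and C/G SNPs are treated like any other pair, which is safe
for generator-produced data and a documented caveat for external summary
statistics.

## Numerical choices

* Spearman is Pearson on midranks (`scipy.stats.rankdata`); the duplicated
  point set always contains ties (every |value| twice), so the midrank
  convention is load-bearing, not cosmetic. Constant vectors raise.
* p-values are floored at the smallest subnormal (≈ 5 × 10⁻³²⁴) so
  log₁₀(1/p) stays finite; t/normal tail probabilities underflow long
  after any rank-based quantity stops caring.
* Exact p ties in the top-eQTL search break toward the lowest SNP index,
  logged.
* Summary-statistics TSVs are written with full float repr and re-read
  through Python's exact `float()`, so write → read is bit-identical.

## Test and acceptance problem sizes

The statistical acceptance checks run at the sizes their claims are stated
for: scan calibration pools 50 null regions of 200 SNPs × 500 individuals;
pipeline type-I error uses 200 replicates (n = 500, 100 SNPs, independent
causal variants in different LD blocks, one simulation per SNP); power and
sign use 100 replicates (n = 2000, 200 SNPs, shared causal variant,
h² = 0.2, log-OR = 0.4). The whole suite runs in ≈ 2 minutes on one CPU.
`scripts/acceptance.py` re-derives the headline quantities at the same
conditions with 50/100 replicates for the rate estimates.

## Known limitations

* The null simulates single-SNP eQTL architectures only; a true eQTL
  driven by multiple independent signals is represented by its top SNP's
  R² alone.
* The penalty constants (30, 0.3) are taken as given and exposed as
  configuration; no tuning machinery is provided or wanted.
* The generator's LD is block-stationary AR(1) — adequate for exercising
  LD-awareness, not a model of any real region's haplotype structure.
* Covariates (ancestry, batch, age, …) are supported nowhere; both scans
  are marginal models.
* With the paper-literal exceedance estimator, p = 0 simply means "beyond
  the null's resolution"; use `add-one` when a proper p-value is needed
  downstream.
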