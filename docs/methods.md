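# Methods

## Model

At a diallelic X-linked locus with alleles D (focal/mutant, frequency p)
and d, unrelated females carry genotypes dd, Dd, DD with frequencies

    g0 = q² + ρpq,    g1 = 2(1 − ρ)pq,    g2 = p² + ρpq,

where ρ is the inbreeding coefficient (ρ = 0 is Hardy–Weinberg
equilibrium).  Conditional on genotype, a quantitative trait Y is normal:

    Y | dd ~ N(β0 + bᵀz, σ0²)
    Y | Dd ~ N(β0 + β1 + bᵀz, σ1²)
    Y | DD ~ N(β0 + β1 + β2 + bᵀz, σ2²)

with optional covariates z.  X-chromosome inactivation (XCI) motivates two
departures from an ordinary additive model.  First, the heterozygote mean
need not sit midway between the homozygote means: if a fraction θ of a
heterozygote's cells keep D active, her expected trait sits at the
θ-weighted point between the homozygote means.  Second, cell-to-cell
mosaicism inflates the heterozygote variance relative to homozygotes.

The estimand is the skewness measure

    γ = 2β1 / (β1 + β2) ∈ [0, 2],     θ = γ/2,

defined whenever association is present (β = (β1 + β2)/2 ≠ 0).  γ = 1 is
random inactivation; γ > 1 is skewing towards D (up to γ = 2, all cells
expressing D); γ < 1 is skewing against D.  γ is a ratio of regression
coefficients, hence invariant to affine changes of the trait, and the
allele-relabeling g → 2 − g maps γ → 2 − γ.

## Variance structures

Two parameterizations of the group variances are provided.

* `variance_structure="shared"` (default): σ0² = σ2² estimated pooled over
  the two homozygote groups; σ1² free.  This is the XCI-motivated
  structure — only heterozygotes are mosaic, so only their variance is
  inflated — and it keeps inference calibrated when the rarer homozygote
  group is small.  At p = 0.1 and n = 1000 the DD group holds about ten
  females; estimating a separate σ2² from ten observations makes all
  Wald- and likelihood-based tests of γ noticeably anti-conservative
  (empirical size near 7% for the likelihood-ratio test at the 5% level,
  verified against an independent optimizer and a from-scratch R
  implementation), whereas the pooled structure holds the nominal level
  across the whole evaluation grid.
* `variance_structure="free"`: all three variances free.  This is the
  fully heteroscedastic likelihood written out below; it is retained for
  sensitivity analysis and is the form checked against generic numerical
  optimizers in the test suite.

All likelihood formulas below hold for either structure, with the
convention that the shared structure ties σ0 = σ2 during maximization.

## Estimation

The unconstrained log-likelihood of a sample with n_i females per
genotype (n = n0 + n1 + n2) is

    l1 = −Σᵢ nᵢ log σᵢ − Σⱼ (y0j − β0 − bᵀz0j)²/2σ0²
                      − Σⱼ (y1j − β0 − β1 − bᵀz1j)²/2σ1²
                      − Σⱼ (y2j − β0 − β1 − β2 − bᵀz2j)²/2σ2² − n log√(2π).

Without covariates the MLE is closed form: group means for the mean
parameters and MLE (divisor nᵢ) group variances, pooled across the
homozygote groups under the shared structure.  The MLE divisor is
deliberate — the likelihood-ratio machinery needs exact maximized
likelihoods, not unbiased variance estimates.  With covariates the
likelihood is maximized by block coordinate ascent: weighted least squares
for the mean parameters at the current variances (weights 1/σᵢ²),
closed-form variance updates at the current means.  Both steps are exact
blockwise maximizations, so the objective ascends monotonically;
iteration stops when the relative log-likelihood change falls below 1e-10
or after 500 iterations (flagged, never silent).

The point estimate is γ̂_raw = 2β̂1/(β̂1 + β̂2), reported after truncation
to [0, 2] as γ̂.  Both values are preserved; downstream Wald tests use the
truncated estimate by default (a switch restores the raw ratio).  If any
genotype group has fewer than two females (c + 2 with c covariates) or
zero within-group variance, the fit refuses with a typed error: the
likelihood is unbounded and γ undefined, and silently regularizing would
bias the Monte-Carlo studies.

The covariance of (β̂1, β̂2) defaults to the inverse information of the
fitted model — without covariates Var(β̂1) = σ̂0²/n0 + σ̂1²/n1,
Var(β̂2) = σ̂1²/n1 + σ̂2²/n2, Cov = −σ̂1²/n1 — and `cov="ols"` substitutes
the homoscedastic ordinary-least-squares covariance (dispersion
RSS/(n − p)) for comparison with analyses that ignored the variance
heterogeneity.

## Confidence regions and tests

Three constructions of a level-(1 − α) region for γ, all intersected with
[0, 2]; endpoint conventions follow the truncation (clipped endpoints
closed, analytic roots open).

**Likelihood ratio.**  The constrained fit under H0: γ = γ0 restricts the
genotype means to β0 + (0, γ0, 2)β and is maximized by the same
coordinate ascent.  λ(γ0) = 2(l1 − l0) is asymptotically χ²₁, and the
region is {γ0 : λ(γ0) < χ²₁,₁₋α}, obtained by evaluating
f(γ0) = λ(γ0) − χ²₁,₁₋α on a 401-point scan grid over [0, 2] (density
configurable), bisecting every sign change to an interval below 1e-6
(well under the 4-decimal reporting precision), and assembling the
sub-level set from the refined roots: no root and f < 0 gives [0, 2]
("full"); no root and f > 0 an empty region; one root a one-sided region
[0, γ^LR) or (γ^LR, 2] according to the boundary signs; two roots either
the inner interval or the discontinuous union [0, γL) ∪ (γU, 2].  A
tangency of f at zero (the measure-zero point-region case) is not
detectable by sign changes and is classified by the zero-width rule
below.  More than two sign changes would contradict the shape of λ and
raises with diagnostics.  For Monte-Carlo work the scan and all bisection
steps are vectorized across replicates on per-genotype sufficient
statistics (counts, means, within-group sums of squares), which is what
makes 10,000-replicate coverage studies of an inverted LR test tractable
on one CPU.

**Fieller.**  Under H0, β̂1 − γ0β̂ is asymptotically normal with variance
Var(β̂1) + γ0²Var(β̂) − 2γ0Cov(β̂1, β̂), where Var(β̂) and Cov(β̂1, β̂) derive
from the covariance of (β̂1, β̂2).  Setting the squared pivot equal to
z²_{α/2} yields the quadratic Aγ0² + Bγ0 + C = 0 with

    A = β̂² − z²Var(β̂),   B = 2z²Cov(β̂1, β̂) − 2β̂1β̂,   C = β̂1² − z²Var(β̂1).

With Δ = B² − 4AC: Δ > 0, A > 0 gives the root interval (A > 0 is
exactly "association significant at level α", logged as a diagnostic);
Δ > 0, A < 0 the complement of the root interval (possibly one-sided,
full, or discontinuous after truncation); Δ < 0, A < 0 all of [0, 2].
Degenerate cases: A = 0 reduces to a linear equation and a half-line;
Δ = 0 to a point.  Δ < 0 with A > 0 contradicts Fieller's theorem and can
only arise from rounding; it falls back to [0, 2] with a warning.  A
region that is empty after truncation is reported as such and counted in
the EP index.

**Delta.**  First-order error propagation of the ratio gives

    Var(γ̂) = Var(β̂1)/β̂² + β̂1²Var(β̂)/β̂⁴ − 2β̂1Cov(β̂1, β̂)/β̂³,

and the region is (γ̂ ± z_{α/2}√Var(γ̂)) ∩ [0, 2] — always one bounded
continuous interval.  The companion Wald test is known to be badly
calibrated: truncation skews the distribution of γ̂, making the test
conservative when γ0 sits at a boundary the estimate piles up against
(empirical size far below α at γ0 = 0) and anti-conservative in the
interior (near twice α at γ0 = 1 in the harder settings).  It is kept as
a comparator, not recommended for use.

Regions are represented as up to two disjoint segments with openness
flags and a status in {continuous, discontinuous, empty, point, full}; a
segment narrower than 1e-9 counts as a point, since numerically refined
roots never collide exactly.

**Prescreen statistics.**  The scan pipeline uses Levene's one-way test on
absolute deviations from the group mean (the classical form, robust for
non-normal but symmetric traits; `center="median"` gives the
Brown–Forsythe variant), the exact Hardy–Weinberg test (conditioning on
allele counts, enumerating same-parity heterozygote counts, summing
probabilities not exceeding the observed one — plain p, no mid-p), and
the minor-allele frequency over nonmissing females.

## Synthetic data

The generator draws each female's genotype from (g0, g1, g2) and her
trait from the group-conditional normals with means
(β0, β0 + γβ, β0 + 2β) and variances (σ0², σ1², σ2²), where

    σ1² = θ(1 − θ)a² + 1.1,    θ = γ/2,

a is the additive effect and 1.1 the heterozygote residual variance.
Defaults are the evaluation study's conditions: β0 = 0.1, β = 0.3,
σ0² = σ2² = 1, base variance 1.1, K = 10,000 replicates at the 5% level;
the factorial grid crosses p ∈ {0.1, 0.3}, ρ ∈ {0, 0.05},
γ ∈ {0, 0.5, 1, 1.5, 2}, a ∈ {0.1, 0.3}, n ∈ {1000, 2000} (80 cells).
At γ = 1, σ1² is 1.1025 (a = 0.1) or 1.1225 (a = 0.3); at γ ∈ {0, 2} the
inflation vanishes regardless of a.

Each replicate draws from an independent child stream spawned from the
cell seed, so results are reproducible and independent of chunking or
parallel order.  A replicate in which any genotype group ends up with
fewer than two members — possible only for the rare homozygote at
p = 0.1, with probability of order 1e-4 per replicate — is redrawn from
the same stream and the occurrences counted; the fit is undefined on such
samples and the alternative (dropping them) would silently change K.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, genotyping error and informative missingness, non-normal or
heavy-tailed traits, relatedness, and male genotypes (X-inactivation is a
female phenomenon and the methods use females only).  Passing
Monte-Carlo checks on these data therefore validate the statistical
machinery under the model's own assumptions, not robustness to real-data
violations of them — the known fragility being trait non-normality,
which in applications is mitigated by the Levene prescreen but not by
the normal-likelihood machinery itself.

## Evaluation harness

For interval studies the harness reports, per (scenario, method) cell:
CP, the proportion of regions containing the true γ, counted whatever the
region's shape (full regions count as covering); ML and MR, the
proportions of replicates whose *continuous* region misses the truth on
the left/right while containing the point estimate — both divided by the
total K, exactly as the counting formulas are defined, not by the number
of continuous regions; their balance ratio ML/(ML + MR); DP, the
proportion of discontinuous regions; and EP, the proportion empty or
reduced to a point.  Discontinuous regions are excluded from ML/MR
because left and right are not well defined for a two-piece set.
Size/power studies report the rejection rate of the chosen test's
p-value at level α; within a cell all methods share the same simulated
replicates.  Reports are emitted as TSV tables, one row per cell.

Problem sizes: size/power and median studies run at the design's
K = 10,000; interval-index studies (coverage, EP), whose cost is
dominated by LR root-finding, run at K = 2,000 in the test suite and
K = 4,000 in the acceptance script.  These were fixed in advance as a
precision/runtime tradeoff; at K = 2,000 the binomial standard error of a
5%-scale proportion is about 0.5 percentage points, and tolerance bands
in the tests are widened accordingly.

## Scan pipeline

Quality control applies, in order: individual genotype missingness
(> 10% excluded), SNP missingness (> 10%), then minor-allele frequency
(< 5%) and exact Hardy–Weinberg test (p < 1e-4) on the remaining
subjects; removals are counted per rule and the filter is idempotent.
Sex and unrelatedness are taken from the caller's metadata — pedigree
bookkeeping is upstream of this tool.  Each SNP × trait pair gets a
Levene prescreen p-value on complete cases for that SNP (subjects with a
missing genotype are dropped SNP-wise, standard practice the upstream
study leaves unspecified).  γ and all three regions are estimated for
pairs passing the single-trait Bonferroni threshold (0.05 divided by the
number of SNPs actually tested — the post-QC count by default, with the
divisor overridable for fidelity to analyses that used the pre-QC count)
or belonging to a SNP associated with two or more traits at 1e-3.
Estimation is deliberately a second stage after association screening:
without association γ is ill-defined and the LR/Fieller regions tend to
be discontinuous or uninformative.  Trait normality is not asserted; a
per-SNP failure (degenerate group, no association) is recorded in the
row's status and the scan continues.

## Known limitations

* The normal within-group likelihood is load-bearing; heavy-tailed traits
  distort both the estimate and the regions (the prescreen is robust, the
  estimation stage is not).
* Estimates at the truncation boundaries (γ̂ ∈ {0, 2}) are point masses,
  so symmetric-normal approximations around γ̂ (the delta method) fail
  there by construction.
* Only unrelated females are supported; no pedigree correlation, no male
  hemizygotes, no Bayesian treatment of the [0, 2] constraint.
* The free-variance structure is exact maximum likelihood but its χ²/
  normal asymptotics need all three groups reasonably large; prefer the
  shared structure unless there is evidence the homozygote variances
  differ.
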