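# Methods

## Model

At each biallelic site, the data for individual *i* are the counts of
A, C, G, T among aligned read bases, summarized through a genotype
likelihood. With a 4×4 error matrix ε, where ε(b→b′) is the probability
that a read reports b′ when the true allele is b (diagonal entries are
1 minus the row's off-diagonal sum), a read from genotype {a₁, a₂} is an
equal mixture of the two allele copies, so

    log P(Dᵢ | {a₁,a₂}) = Σ_b n_b log[(ε(a₁→b) + ε(a₂→b)) / 2].

The multinomial coefficient is omitted: it is constant across genotypes
and cancels in every ratio and in the frequency likelihood. Likelihoods
are therefore ≤ 1, and an individual with zero reads carries a flat
likelihood (it contributes a constant factor and is retained rather
than dropped). Natural logs are used throughout; log₁₀ appears only at
the calling-filter boundary, where the threshold *f* is conventionally
quoted in log₁₀ units.

Given major/minor alleles, the MAF likelihood assumes Hardy–Weinberg
equilibrium and independence across individuals:

    ℓ(p) = Σᵢ log[(1−p)² Lᵢ(0) + 2p(1−p) Lᵢ(1) + p² Lᵢ(2)],

computed per individual by log-sum-exp. When the minor allele is
uncertain, the likelihood is averaged over the three non-major
nucleotides with equal prior weight, evaluated as
l₍₁₎ + log(1 + e^{l₍₂₎−l₍₁₎} + e^{l₍₃₎−l₍₁₎}) − log 3 with l₍₁₎ the
largest candidate log-likelihood.

Assumptions: biallelic sites, HWE within each group, independent
individuals, site-independent reads, error rates known and shared
across individuals. None of the estimators uses linkage information.

## Estimation

- **EM.** The posterior dosage E[g | Dᵢ, p] is averaged over individuals
  and halved; iteration stops when the log-likelihood gain falls below
  `tol` (default 10⁻³) or after `max_iter` = 1000 iterations
  (non-convergence is flagged, not raised). Initialization p₀ = 0.1;
  tests confirm insensitivity over p₀ ∈ {0.01, 0.1, 0.4}. Known-minor
  EM runs on [0, 1] and folds estimates above 0.5 back with an allele
  relabel; the unknown-minor parameter space is [0, 0.5] and the update
  is clipped (the clipped update still maximizes the constrained
  surrogate, so ascent is preserved). Under the unknown-minor model the
  candidate minor allele enters EM as a site-level latent variable:
  candidates are re-weighted by their conditional likelihood each
  E-step, and the M-step averages posterior dosages across candidates.
  The reported minor allele is the candidate with the highest posterior
  weight at p̂, or "unknown" when the top weight is within a factor of 2
  of the runner-up.
- **Direct.** Bounded 1-D maximization (Brent) on [0, 0.5], with both
  endpoints checked so boundary optima are exact. Concavity is not
  assumed; the optimizer is validated against a grid search
  (step 5·10⁻⁴) in the tests, and EM and direct optimization agree to
  |Δp̂| < 10⁻⁴ at tight tolerance.
- All batch pipelines normalize each individual's likelihood vector by
  its maximum and carry the log-offset separately; offsets cancel
  exactly in likelihood-ratio statistics.

## Association tests

The LRT compares group-specific frequencies (p₁, p₂) against a shared
p₀ on the pooled sample, each maximized as above, with 2Δℓ referred to
χ²(1). Under the unknown-minor model the null marginalizes the pooled
likelihood; the alternative maximizes the joint marginal
(1/3) Σ_m L_cases(p₁ | m) · L_controls(p₂ | m) over (p₁, p₂) — the
candidate minor allele is *shared* between groups, so the null is
nested and the statistic is non-negative by construction. (An
independent-marginalization variant is available behind
`shared_minor=False` for comparison; it is not nested.) With perfect
genotype likelihoods the known-minor LRT reduces algebraically to the
allelic G-test, which the tests verify numerically.

LRT statistics are computed with a tighter EM tolerance (10⁻⁶) than the
estimation default: the statistic is a difference of separately
maximized log-likelihoods, and at tolerance 10⁻³ residual
under-maximization of the (slower-converging) pooled null fit inflates
the null distribution noticeably (genomic-control inflation ≈ 1.13 at
5× in our measurements, vs ≈ 1.01–1.04 at 10⁻⁶). Negative values from
optimizer noise are clamped at zero.

The G-test excludes uncalled individuals; a 2×2 table with any zero
margin (monomorphic or empty group) returns statistic 0 and p-value 1,
since such sites carry no association signal. The Cochran–Armitage
trend test uses scores (0, 1, 2) on the 2×3 genotype table, with
degenerate tables likewise returning 0.

Calling policy details: the best genotype is called iff its log₁₀
likelihood ratio to the runner-up is ≥ *f* (non-strict comparison);
with *f* = 0 exact ties resolve to the lower dosage code (deterministic,
and the more common genotype at low MAF), while under *f* > 0 ties are
missing; zero-read individuals are always missing, since a flat
likelihood carries no information.

## Simulator

The generator emulates the study conditions the estimators are designed
for: per site, genotypes are Binomial(2, p) under HWE; each of the two
allele copies yields Poisson(depth/2) reads, making haplotype coverage
independent; each read's reported base is drawn from the error-matrix
row of its true allele; output is the per-individual 4-nucleotide count
vector. Population frequencies can be fixed, or drawn from the
Wright–Fisher stationary law (mass ∝ 1/i on the derived-allele grid
i/(2Nₑ), i = 1 … 2Nₑ−1, full grid without truncation, folded to
min(x, 1−x)), with Nₑ = 10,000 by default. Case/control frequencies
come from a multiplicative penetrance model f₀γᵍ with prevalence
K = 10%: f₀ = K/(q+pγ)², case MAF = pγ/(q+pγ), control MAF =
p(1 − f₀γ(q+pγ))/(1−K); infeasible penetrances raise an explicit error.
The simulation truth fixes A as major and C as minor allele; all
estimators re-derive alleles from the data (most common and second most
common pooled nucleotide, ties broken A<C<G<T) and must not exploit the
convention — an equivariance test relabels nucleotides consistently and
checks the estimates are unchanged.

**Error matrix.** The 12 type-specific rates are a config input. The
default is uniform with 1% total per-base error (each off-diagonal
1/300), a level representative of raw short-read base calls. The choice
matters: the biases of calling-based estimators (upward-biased Call F
medians, inflated low-frequency spectrum bins, null miscalibration of
the allelic G-test) all grow with the error level, while the likelihood
estimators — which model the matrix exactly — are nearly unaffected
between 0.1% and 1%. Real platforms concentrate errors in specific
substitutions rather than spreading them uniformly; a concentrated
matrix of the same total would hurt calling more (errors pile onto one
candidate minor) and the likelihood methods less. Simulations here
therefore bound, rather than exactly reproduce, real-platform behavior;
likelihood-ratio power in particular is mildly conservative relative to
a concentrated matrix of equal total error. The generator also omits
mapping error, per-read quality variation, indels, multi-allelic sites
and linkage between sites, so passing tests demonstrate correctness of
the inference under the stated generative model, not robustness to
those artifacts.

## Evaluation conventions

- Spectrum: estimates < 2% are discarded (the boundary value 2% is
  retained); bins of width 0.02 cover [0.02, 0.5], proportions are over
  retained sites.
- Empirical-null power: the critical value at false-positive rate r is
  the linear-interpolation ("type 7") 1−r quantile of the null
  statistics — documented because power at small r is sensitive to the
  quantile convention; power is the fraction of alternative statistics
  strictly exceeding it.
- Inflation factor: median statistic / median of χ²(1) (≈ 0.4549), the
  median-based genomic-control estimator.
- Undefined estimates (no called individuals) are excluded from MSE and
  medians with the exclusion count reported.

## Simulation sizes

`scripts/acceptance.py` uses 1,000 sites per depth for the bias sweep
(n = 200, depths 2–12×), 2,000 sites for the true-genotype MSE
(n = 50, 20×), 20,000 sites for the spectrum (n = 200, 4×), 5,000 null
sites for G-test calibration (500+500, 2×) and 20,000 + 20,000
null/alternative sites for power (500+500, 5×). The test suite runs the
same pipelines at reduced sizes (10,000 spectrum sites; 2,500 sites for
LRT inflation; 3,000 + 3,000 for power) chosen so Monte-Carlo noise is
small against each tolerance.

## Known limitations

- Very rare variants (MAF < 1%) at low coverage are intrinsically hard
  to distinguish from sequencing error; the 2% spectrum cutoff reflects
  this.
- Error rates are treated as known and global; estimating them is out
  of scope.
- p-values rely on the asymptotic χ²(1) tail; for small samples or
  extreme tails use the empirical-null machinery instead.
- HWE is assumed within groups; the framework extends to other
  genotype-frequency models but none is implemented.
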