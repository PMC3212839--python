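# glikfreq

Minor allele frequency (MAF) estimation and case/control association
testing from genotype likelihoods, for low- and medium-coverage
short-read sequencing data.

## The problem

In sequencing studies that spread a fixed budget over many individuals,
each site in each individual is covered by only a few reads (2–15×).
Calling a genotype per individual and then counting alleles — the
workflow inherited from SNP arrays and Sanger data — breaks down in this
regime: heterozygotes are miscalled or dropped, allele frequency
estimates become biased (badly so when low-confidence calls are
filtered out), the low-frequency tail of the site frequency spectrum is
inflated by sequencing errors, and allelic association tests reject far
too often under the null.

`glikfreq` implements the alternative: keep the per-genotype likelihoods
and integrate over genotype uncertainty. At a biallelic site with minor
allele frequency *p*, assuming Hardy–Weinberg equilibrium and
independent individuals, the likelihood is

    L(p) = ∏ᵢ Σ_{g=0,1,2} P(g | p) · P(Dᵢ | g)
    P(g | p) = (1−p)²,  2p(1−p),  p²   for g = 0, 1, 2

where *g* is individual *i*'s minor-allele dosage and P(Dᵢ | g) its
genotype likelihood, computed from base counts (n_A, n_C, n_G, n_T) and
a 4×4 type-specific error matrix ε as

    log P(Dᵢ | {a₁,a₂}) = Σ_b n_b · log[ (ε(a₁→b) + ε(a₂→b)) / 2 ].

The MLE p̂ is found by EM (iterating the mean posterior dosage) or by
bounded 1-D optimization. When the minor allele itself is ambiguous
(rare variants), the likelihood is marginalized over the three
non-major nucleotides with equal weight, evaluated stably in log space.
The same machinery yields a case/control likelihood-ratio test of
H₀: p_cases = p_controls against group-specific frequencies, referred to
χ²(1). Genotype-calling baselines (ML calls, optional log₁₀
likelihood-ratio filter *f*, allele counting), the allelic G-test and
the Cochran–Armitage trend test are included for comparison, along with
a read-count simulator (HWE genotypes, Poisson(depth/2) reads per allele
copy, type-specific errors, Wright–Fisher 1/x stationary frequencies,
multiplicative disease model) and evaluation tools (MSE, folded spectrum
with a 2% cutoff, type-I error, genomic-control inflation, empirical-null
ROC power).

## Worked example

Estimate MAFs at 500 simulated sites (200 individuals, 2× mean depth,
true MAF 5%, 1% total per-base error):

```python
import numpy as np
from glikfreq import SimulationConfig, DiseaseModel, disease_model_freqs, simulate_sites
from glikfreq import pipeline
from glikfreq.likelihood_core import ErrorMatrix

err = ErrorMatrix.uniform()          # 1% total per-base error
cfg = SimulationConfig(n_individuals=200, depth=2.0, error=err)
rng = np.random.default_rng(0)
genotypes, counts = simulate_sites(0.05, cfg, rng, n_sites=500)

ml      = pipeline.ml_maf_estimates(counts, err)["maf"]
call_nf = pipeline.calling_maf_estimates(counts, err, f=0.0)
call_f  = pipeline.calling_maf_estimates(counts, err, f=1.0)
truth   = pipeline.true_genotype_maf_estimates(genotypes)

print(f"median true-genotype estimate: {np.median(truth):.4f}")
print(f"median ML estimate:            {np.median(ml):.4f}")
print(f"median Call NF estimate:       {np.nanmedian(call_nf):.4f}")
print(f"median Call F estimate:        {np.nanmedian(call_f):.4f}")
```

prints

```
median true-genotype estimate: 0.0500
median ML estimate:            0.0480
median Call NF estimate:       0.0516
median Call F estimate:        0.1288
```

At 2× the likelihood estimator tracks the truth, unfiltered calling is
mildly biased upward, and filtered calling (*f* = 1) more than doubles
the true frequency — filtering discards well-covered reference
homozygotes as "low confidence" while sequencing errors keep promoting
spurious heterozygotes. The multiplicative disease model gives the
group frequencies used in power simulations:

```python
case, control = disease_model_freqs(DiseaseModel(0.01, 2.0, 0.1))
# case MAF: 0.0198  control MAF: 0.0089
```

A command-line interface mirrors the library
(`glikfreq simulate|call|estimate|assoc|evaluate`, see `glikfreq --help`);
all I/O is tab-separated text (read counts, 10-genotype natural-log
likelihood tables, calls, YAML configs).

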