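"""Read-count simulator for low-coverage sequencing experiments.

Sites are simulated independently.  Per individual, the genotype is drawn
under Hardy-Weinberg equilibrium at the site's MAF; each of the two allele
copies then produces a Poisson(depth/2) number of reads, so the coverage
of the two haplotypes is independent; finally each read's reported base is
drawn from the error-matrix row of its true allele.  The output is the
per-individual count of A, C, G and T reads — reads themselves are never
materialized.

Population frequencies can be drawn from the Wright-Fisher stationary
distribution (density proportional to 1/x in the derived-allele frequency
x, on the grid i/2Ne), and case/control frequencies from a multiplicative
disease model with fixed prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood_core import ErrorMatrix

#: nucleotide indices used for the simulated truth; estimators must not
#: rely on them and re-derive alleles from the data
MAJOR_INDEX = 0  # A
MINOR_INDEX = 1  # C


class DiseaseModelError(ValueError):
    """Raised when a disease model implies penetrances outside [0, 1]."""


@dataclass(frozen=True)
class SimulationConfig:
    """Read-count simulation settings.

    ``depth`` is the mean number of reads per individual at a site (the
    two allele copies each contribute Poisson(depth/2) reads).
    """

    n_individuals: int
    depth: float
    error: ErrorMatrix = field(default_factory=ErrorMatrix.uniform)
    n_sites: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.depth > 0:
            raise ValueError("depth must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class DiseaseModel:
    """Multiplicative disease model.

    Genotype penetrance is ``f0 * gamma**g`` for ``g`` copies of the risk
    (minor) allele; together with the population MAF and the disease
    prevalence this fixes the case- and control-group allele frequencies.
    """

    combined_maf: float
    relative_risk: float
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.combined_maf <= 0.5:
            raise ValueError("combined_maf must lie in (0, 0.5]")
        if self.relative_risk < 0:
            raise ValueError("relative_risk must be non-negative")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


def disease_model_freqs(model: DiseaseModel) -> tuple[float, float]:
    """Case and control minor allele frequencies implied by the model.

    With population MAF ``p``, ``q = 1-p``, relative risk ``gamma`` and
    prevalence ``K``, the baseline penetrance is ``f0 = K/(q + p*gamma)^2``
    and

        case_maf    = p*gamma / (q + p*gamma)
        control_maf = p * (1 - f0*gamma*(q + p*gamma)) / (1 - K)

    The mixture constraint ``K*case + (1-K)*control = p`` holds by
    construction.
    """
    p, gamma, k = model.combined_maf, model.relative_risk, model.prevalence
    q = 1.0 - p
    denom = q + p * gamma
    f0 = k / denom**2
    if f0 > 1.0 or f0 * gamma**2 > 1.0:
        raise DiseaseModelError(
            "disease model implies a penetrance above 1 "
            f"(f0={f0:.4g}, f0*gamma^2={f0 * gamma**2:.4g})"
        )
    case = p * gamma / denom
    control = p * (1.0 - f0 * gamma * denom) / (1.0 - k)
    return float(case), float(control)


def sample_stationary_mafs(
    n_sites: int, rng: np.random.Generator, pop_size: int = 10000
) -> np.ndarray:
    """Draw folded MAFs from the Wright-Fisher stationary distribution.

    Derived-allele frequencies ``x = i/(2*Ne)`` are sampled on the full
    grid ``i = 1..2*Ne - 1`` with probability proportional to ``1/i`` and
    folded to ``min(x, 1-x)``.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    i_grid, weights = stationary_grid(pop_size)
    probs = weights / weights.sum()
    draws = rng.choice(i_grid, size=n_sites, p=probs)
    x = draws / (2.0 * pop_size)
    return np.minimum(x, 1.0 - x)


def stationary_grid(pop_size: int = 10000) -> tuple[np.ndarray, np.ndarray]:
    """Derived-allele count grid ``1..2Ne-1`` and its 1/i weights."""
    i_grid = np.arange(1, 2 * pop_size)
    return i_grid, 1.0 / i_grid


def expected_folded_spectrum(
    pop_size: int = 10000, cutoff: float = 0.02, bin_width: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Exact folded-spectrum bin proportions above a MAF cutoff.

    Sums the 1/i weights over the grid, folds, drops mass below
    ``cutoff`` and returns (bin_edges, proportions) for bins of width
    ``bin_width`` covering [cutoff, 0.5].
    """
    i_grid, weights = stationary_grid(pop_size)
    maf = np.minimum(i_grid, 2 * pop_size - i_grid) / (2.0 * pop_size)
    keep = maf >= cutoff
    edges = np.arange(cutoff, 0.5 + bin_width / 2, bin_width)
    hist, _ = np.histogram(maf[keep], bins=edges, weights=weights[keep])
    return edges, hist / hist.sum()


def simulate_sites(
    mafs: np.ndarray | float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n_sites: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate genotypes and read counts for one or more sites.

    Parameters
    ----------
    mafs
        Scalar or (S,) per-site true minor allele frequencies.
    cfg
        Number of individuals, mean depth and error model.
    rng
        Source of all randomness.
    n_sites
        Number of sites when ``mafs`` is scalar (defaults to
        ``cfg.n_sites``).

    Returns
    -------
    genotypes : (S, N) int8 array of minor-allele dosages
    counts : (S, N, 4) int64 array of A/C/G/T read counts; the truth uses
        A as major and C as minor allele.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim == 0:
        s = cfg.n_sites if n_sites is None else n_sites
        mafs = np.full(s, float(mafs))
    if np.any((mafs < 0) | (mafs > 1)):
        raise ValueError("MAFs must lie in [0, 1]")
    n = cfg.n_individuals
    genotypes = rng.binomial(2, mafs[:, np.newaxis], size=(mafs.size, n)).astype(np.int8)
    half_depth = cfg.depth / 2.0
    n_minor = rng.poisson(genotypes * half_depth)
    n_major = rng.poisson((2 - genotypes) * half_depth)
    counts = rng.multinomial(n_major, cfg.error.rates[MAJOR_INDEX])
    counts += rng.multinomial(n_minor, cfg.error.rates[MINOR_INDEX])
    return genotypes, counts.astype(np.int64)


def simulate_site(
    maf: float, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-site convenience wrapper; returns ((N,) genotypes, (N, 4) counts)."""
    g, c = simulate_sites(float(maf), cfg, rng, n_sites=1)
    return g[0], c[0]


@dataclass
class CaseControlData:
    """Simulated case/control read counts with the generating truth."""

    case_genotypes: np.ndarray  # (S, n_cases)
    case_counts: np.ndarray  # (S, n_cases, 4)
    control_genotypes: np.ndarray
    control_counts: np.ndarray
    case_maf: float
    control_maf: float
    under_null: bool


def simulate_case_control(
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    under_null: bool = False,
    n_sites: int | None = None,
) -> CaseControlData:
    """Simulate read counts for a case/control study.

    Under the null both groups share ``model.combined_maf``; otherwise
    the group MAFs come from :func:`disease_model_freqs`.
    """
    if under_null:
        case_maf = control_maf = model.combined_maf
    else:
        case_maf, control_maf = disease_model_freqs(model)
    s = cfg.n_sites if n_sites is None else n_sites
    cfg_cases = SimulationConfig(n_cases, cfg.depth, cfg.error)
    cfg_controls = SimulationConfig(n_controls, cfg.depth, cfg.error)
    g1, c1 = simulate_sites(case_maf, cfg_cases, rng, n_sites=s)
    g2, c2 = simulate_sites(control_maf, cfg_controls, rng, n_sites=s)
    return CaseControlData(g1, c1, g2, c2, case_maf, control_maf, under_null)
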