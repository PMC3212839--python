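"""Sequencing error model and genotype likelihoods from nucleotide read counts.

At a biallelic site the data for one individual are the counts of A, C, G
and T among the aligned read bases.  Given a 4x4 matrix of type-specific
substitution probabilities ``eps[b, b'] = P(read base b' | true allele b)``,
the log-likelihood of an (unordered) diploid genotype ``{a1, a2}`` is

    log L({a1, a2}) = sum_b n_b * log[(eps[a1, b] + eps[a2, b]) / 2]

i.e. each read is drawn from an equal mixture of the two allele copies.
The multinomial coefficient is constant across genotypes and omitted, so
likelihoods are at most 1 and an individual with zero reads has a flat
(all-ones) likelihood over the ten genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")
NUC_INDEX: dict[str, int] = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: the ten unordered genotypes, in the column order of the GL table
GENOTYPE_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 1), (1, 2), (1, 3),
    (2, 2), (2, 3),
    (3, 3),
)
GENOTYPE_LABELS: tuple[str, ...] = tuple(
    NUCLEOTIDES[a] + NUCLEOTIDES[b] for a, b in GENOTYPE_PAIRS
)

# (4, 4) lookup: unordered pair of nucleotide indices -> position in the
# 10-genotype vector
PAIR_INDEX = np.empty((4, 4), dtype=np.intp)
for _k, (_a, _b) in enumerate(GENOTYPE_PAIRS):
    PAIR_INDEX[_a, _b] = _k
    PAIR_INDEX[_b, _a] = _k


#: default total per-base substitution error rate of the uniform model
DEFAULT_TOTAL_ERROR: float = 0.01


class ErrorModelError(ValueError):
    """Raised for invalid error-matrix specifications."""


@dataclass(frozen=True)
class ErrorMatrix:
    """Type-specific sequencing error probabilities.

    ``rates[b, b']`` is the probability that a read reports base ``b'``
    when the true allele is ``b``.  Only the twelve off-diagonal entries
    are free; each diagonal entry is ``1 - (row off-diagonal sum)``.
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (4, 4):
            raise ErrorModelError(f"error matrix must be 4x4, got {r.shape}")
        off = r.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0) or np.any(off >= 1):
            raise ErrorModelError("off-diagonal error rates must lie in [0, 1)")
        row_err = off.sum(axis=1)
        if np.any(row_err >= 1):
            raise ErrorModelError("each row's total error rate must be < 1")
        if not np.allclose(np.diagonal(r), 1.0 - row_err, atol=1e-12):
            raise ErrorModelError(
                "diagonal entries must equal 1 - row off-diagonal sum"
            )
        object.__setattr__(self, "rates", r)

    @classmethod
    def from_off_diagonal(cls, off: np.ndarray) -> "ErrorMatrix":
        """Build from a 4x4 array whose diagonal is ignored."""
        off = np.asarray(off, dtype=float)
        r = off.copy()
        np.fill_diagonal(r, 0.0)
        np.fill_diagonal(r, 1.0 - r.sum(axis=1))
        return cls(r)

    @classmethod
    def uniform(cls, total_error: float = DEFAULT_TOTAL_ERROR) -> "ErrorMatrix":
        """Uniform matrix with the given total per-base error rate.

        The default (1%, i.e. each off-diagonal entry 1/300) is the
        matrix used throughout the simulation study; it is representative
        of raw base-call error on medium-coverage short-read data.
        """
        off = np.full((4, 4), total_error / 3.0)
        return cls.from_off_diagonal(off)

    @classmethod
    def from_dict(cls, entries: dict[str, float]) -> "ErrorMatrix":
        """Build from config entries keyed ``"eps.A.C"`` etc.

        Missing entries default to 0.
        """
        off = np.zeros((4, 4))
        for key, value in entries.items():
            parts = key.split(".")
            if len(parts) != 3 or parts[0] != "eps":
                raise ErrorModelError(f"bad error-rate key {key!r}")
            b, bp = parts[1], parts[2]
            if b not in NUC_INDEX or bp not in NUC_INDEX or b == bp:
                raise ErrorModelError(f"bad error-rate key {key!r}")
            off[NUC_INDEX[b], NUC_INDEX[bp]] = float(value)
        return cls.from_off_diagonal(off)

    def to_dict(self) -> dict[str, float]:
        out = {}
        for b in range(4):
            for bp in range(4):
                if b != bp:
                    out[f"eps.{NUCLEOTIDES[b]}.{NUCLEOTIDES[bp]}"] = float(
                        self.rates[b, bp]
                    )
        return out

    def genotype_base_probs(self) -> np.ndarray:
        """(10, 4) matrix of per-read base probabilities for each genotype."""
        r = self.rates
        pairs = np.array(GENOTYPE_PAIRS)
        return (r[pairs[:, 0]] + r[pairs[:, 1]]) / 2.0


@dataclass(frozen=True)
class SiteAlleles:
    """Major/minor allele designation at a site; minor may be unknown."""

    major: str
    minor: str | None = None

    def __post_init__(self) -> None:
        if self.major not in NUC_INDEX:
            raise ValueError(f"invalid major allele {self.major!r}")
        if self.minor is not None:
            if self.minor not in NUC_INDEX:
                raise ValueError(f"invalid minor allele {self.minor!r}")
            if self.minor == self.major:
                raise ValueError("major and minor allele must differ")


@dataclass
class SiteReadData:
    """Per-individual A/C/G/T read counts at one site.

    ``counts`` has shape (n_individuals, 4); all-zero rows are legal and
    represent individuals without coverage.
    """

    site_id: str
    counts: np.ndarray
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("counts must have shape (n_individuals, 4)")
        if np.any(c < 0):
            raise ValueError("read counts must be non-negative")
        self.counts = c.astype(np.int64)
        if not self.individuals:
            self.individuals = [str(i) for i in range(c.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> np.ndarray:
        """Summed base counts over individuals, shape (4,)."""
        return self.counts.sum(axis=0)


def gl10_from_counts(counts: np.ndarray, err: ErrorMatrix) -> np.ndarray:
    """Ten-genotype natural-log likelihoods from base counts.

    Parameters
    ----------
    counts
        Integer array whose last axis has length 4 (counts of A, C, G, T);
        any leading axes (individuals, sites) are preserved.
    err
        The substitution-error model.

    Returns
    -------
    Array of shape ``counts.shape[:-1] + (10,)`` with the log-likelihood
    of each unordered genotype.  A base with per-read probability 0 under
    a genotype yields ``-inf`` for that genotype whenever its count is
    positive.
    """
    counts = np.asarray(counts)
    if counts.shape[-1] != 4:
        raise ValueError("last axis of counts must have length 4")
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    probs = err.genotype_base_probs()  # (10, 4)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    impossible = np.isneginf(logp)
    safe_logp = np.where(impossible, 0.0, logp)
    gl = np.asarray(counts, dtype=float) @ safe_logp.T
    if impossible.any():
        hits = np.asarray(counts, dtype=float) @ impossible.T.astype(float)
        gl[hits > 0] = -np.inf
    return gl


def genotype_log_likelihoods(counts: np.ndarray, err: ErrorMatrix) -> np.ndarray:
    """Log-likelihoods of the ten genotypes for a single individual.

    ``counts`` is the length-4 vector (nA, nC, nG, nT).
    """
    counts = np.asarray(counts)
    if counts.shape != (4,):
        raise ValueError("counts must be a length-4 vector")
    if not np.all(counts == np.floor(counts)):
        raise ValueError("counts must be integers")
    return gl10_from_counts(counts, err)


def triplet_for_alleles(gl10: np.ndarray, alleles: SiteAlleles) -> np.ndarray:
    """Re-index 10-genotype likelihoods to the (major, minor) triplet.

    Returns log-likelihoods ordered by minor-allele dosage g = 0, 1, 2,
    i.e. (major/major, major/minor, minor/minor).  Pure re-indexing.
    """
    if alleles.minor is None:
        raise ValueError("minor allele must be known to form a triplet")
    gl10 = np.asarray(gl10)
    if gl10.shape[-1] != 10:
        raise ValueError("last axis must have length 10")
    return triplets_from_gl10(
        gl10, NUC_INDEX[alleles.major], NUC_INDEX[alleles.minor]
    )


def triplets_from_gl10(
    gl10: np.ndarray, major: np.ndarray | int, minor: np.ndarray | int
) -> np.ndarray:
    """Vectorized triplet extraction.

    ``major``/``minor`` are nucleotide indices, scalar or per-site arrays
    broadcastable against the leading axes of ``gl10``.
    """
    gl10 = np.asarray(gl10)
    major = np.asarray(major)
    minor = np.asarray(minor)
    if np.any(major == minor):
        raise ValueError("major and minor allele must differ")
    idx = np.stack(
        [
            PAIR_INDEX[major, major],
            PAIR_INDEX[major, minor],
            PAIR_INDEX[minor, minor],
        ],
        axis=-1,
    )
    if idx.ndim > 1:
        # per-site alleles: insert axes so idx broadcasts over individuals
        extra = gl10.ndim - 2  # axes between site axis and the 10-axis
        idx = idx.reshape(idx.shape[:1] + (1,) * extra + (3,))
    idx = np.broadcast_to(idx, gl10.shape[:-1] + (3,))
    return np.take_along_axis(gl10, idx, axis=-1)


def determine_alleles(site: SiteReadData) -> SiteAlleles:
    """Designate major and minor alleles from pooled base counts.

    The most common nucleotide over all individuals is the major allele
    and the second most common the minor; ties break in the fixed order
    A < C < G < T.
    """
    totals = site.totals()
    if totals.sum() == 0:
        raise ValueError(f"no data at site {site.site_id!r}")
    major, minor = determine_alleles_from_totals(totals[np.newaxis, :])
    return SiteAlleles(NUCLEOTIDES[major[0]], NUCLEOTIDES[minor[0]])


def determine_alleles_from_totals(
    totals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Major/minor nucleotide indices for each row of a (S, 4) totals array."""
    totals = np.asarray(totals)
    major = np.argmax(totals, axis=-1)  # argmax takes the first on ties
    masked = totals.astype(float).copy()
    np.put_along_axis(masked, major[..., None], -np.inf, axis=-1)
    minor = np.argmax(masked, axis=-1)
    return major, minor
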