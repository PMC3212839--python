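"""End-to-end per-site workflows on read-count arrays.

These functions chain the building blocks — allele designation from
pooled counts, genotype likelihoods, calling, ML estimation, association
statistics — over whole (S, N, 4) count arrays, chunking internally to
bound memory.  They are the engines behind the CLI and the simulation
study.
"""

from __future__ import annotations

import numpy as np

from . import association, genotype_calling, likelihood_core, ml_maf
from .genotype_calling import CallPolicy
from .likelihood_core import ErrorMatrix

_CHUNK_ELEMENTS = 12_000_000  # ~ individuals x sites per processing chunk


def _chunks(n_sites: int, n_individuals: int) -> list[slice]:
    per = max(1, _CHUNK_ELEMENTS // max(1, n_individuals))
    return [slice(i, min(i + per, n_sites)) for i in range(0, n_sites, per)]


def site_alleles(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (major, minor) nucleotide indices from pooled counts.

    The most common nucleotide is the major allele, the second most
    common the minor; ties break in A<C<G<T order.  Sites with no reads
    fall back to that same fixed order.
    """
    totals = np.asarray(counts).sum(axis=1)
    return likelihood_core.determine_alleles_from_totals(totals)


def call_genotypes_from_counts(
    counts: np.ndarray, err: ErrorMatrix, policy: CallPolicy
) -> np.ndarray:
    """(S, N) called genotype codes (missing = -1) from count arrays."""
    counts = np.asarray(counts)
    major, minor = site_alleles(counts)
    out = np.empty(counts.shape[:2], dtype=np.int8)
    for sl in _chunks(counts.shape[0], counts.shape[1]):
        gl10 = likelihood_core.gl10_from_counts(counts[sl], err)
        triplets = likelihood_core.triplets_from_gl10(gl10, major[sl], minor[sl])
        out[sl] = genotype_calling.call_genotypes(triplets, policy)
    return out


def calling_maf_estimates(
    counts: np.ndarray, err: ErrorMatrix, f: float = 0.0
) -> np.ndarray:
    """Per-site allele-counting MAF estimates from called genotypes.

    ``f = 0`` is the unfiltered ("Call NF") and ``f = 1`` the common
    filtered ("Call F") baseline.  Sites with no called individuals give
    NaN.
    """
    calls = call_genotypes_from_counts(counts, err, CallPolicy(f))
    return genotype_calling.maf_from_calls_batch(calls)


def ml_maf_estimates(
    counts: np.ndarray,
    err: ErrorMatrix,
    tol: float = ml_maf.DEFAULT_TOL,
    max_iter: int = ml_maf.DEFAULT_MAX_ITER,
) -> dict[str, np.ndarray]:
    """Unknown-minor ML MAF estimates for every site of a count array.

    The major allele is the most common nucleotide at each site; the
    minor allele is marginalized out.  Returns the batch-fit dict (see
    :func:`glikfreq.ml_maf.estimate_maf_unknown_minor_batch`) plus the
    ``major`` indices.
    """
    counts = np.asarray(counts)
    major, _ = site_alleles(counts)
    pieces = []
    for sl in _chunks(counts.shape[0], 4 * counts.shape[1]):
        gl10 = likelihood_core.gl10_from_counts(counts[sl], err)
        pieces.append(
            ml_maf.estimate_maf_unknown_minor_batch(
                gl10, major[sl], tol=tol, max_iter=max_iter
            )
        )
    out = {k: np.concatenate([p[k] for p in pieces]) for k in pieces[0]}
    out["major"] = major
    return out


def true_genotype_maf_estimates(genotypes: np.ndarray) -> np.ndarray:
    """Sample minor-allele frequency of the true genotypes, folded at 0.5."""
    freq = np.asarray(genotypes).mean(axis=1) / 2.0
    return np.minimum(freq, 1.0 - freq)


def _group_alleles(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    totals = np.asarray(case_counts).sum(axis=1) + np.asarray(control_counts).sum(axis=1)
    return likelihood_core.determine_alleles_from_totals(totals)


def g_test_stats(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    err: ErrorMatrix,
    f: float = 0.0,
) -> np.ndarray:
    """Per-site allelic G statistics from called genotypes.

    Alleles are designated from the pooled case+control counts so both
    groups share the same (major, minor) labels.
    """
    case_counts = np.asarray(case_counts)
    control_counts = np.asarray(control_counts)
    major, minor = _group_alleles(case_counts, control_counts)
    policy = CallPolicy(f)
    stats = np.empty(case_counts.shape[0])
    for sl in _chunks(case_counts.shape[0], case_counts.shape[1] + control_counts.shape[1]):
        tables = []
        for grp in (case_counts[sl], control_counts[sl]):
            gl10 = likelihood_core.gl10_from_counts(grp, err)
            trip = likelihood_core.triplets_from_gl10(gl10, major[sl], minor[sl])
            calls = genotype_calling.call_genotypes(trip, policy)
            ok = calls != genotype_calling.MISSING
            minor_n = np.where(ok, calls, 0).sum(axis=1)
            tables.append((minor_n, 2 * ok.sum(axis=1) - minor_n))
        stats[sl] = association.g_test_statistic_batch(
            tables[0][0], tables[0][1], tables[1][0], tables[1][1]
        )
    return stats


def true_genotype_g_stats(
    case_genotypes: np.ndarray, control_genotypes: np.ndarray
) -> np.ndarray:
    """Allelic G statistics computed directly from true genotypes."""
    case_genotypes = np.asarray(case_genotypes)
    control_genotypes = np.asarray(control_genotypes)
    mc = case_genotypes.sum(axis=1)
    mk = control_genotypes.sum(axis=1)
    return association.g_test_statistic_batch(
        mc,
        2 * case_genotypes.shape[1] - mc,
        mk,
        2 * control_genotypes.shape[1] - mk,
    )


def lrt_stats(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    err: ErrorMatrix,
    tol: float = association.LRT_TOL,
    max_iter: int = ml_maf.DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Per-site unknown-minor LRT statistics for case/control data.

    The major allele is designated from the pooled counts; the candidate
    minor allele is shared between groups in the alternative model.
    """
    case_counts = np.asarray(case_counts)
    control_counts = np.asarray(control_counts)
    major, _ = _group_alleles(case_counts, control_counts)
    stats = np.empty(case_counts.shape[0])
    n_eff = 12 * (case_counts.shape[1] + control_counts.shape[1])
    for sl in _chunks(case_counts.shape[0], n_eff):
        gl_case = likelihood_core.gl10_from_counts(case_counts[sl], err)
        gl_control = likelihood_core.gl10_from_counts(control_counts[sl], err)
        stats[sl] = association.lrt_unknown_minor_batch(
            gl_case, gl_control, major[sl], tol=tol, max_iter=max_iter
        )
    return stats
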