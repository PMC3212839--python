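"""Maximum-likelihood minor allele frequency estimation.

Instead of calling genotypes, the likelihood of the MAF ``p`` at a site
integrates over genotype uncertainty under Hardy-Weinberg equilibrium:

    L(p) = prod_i [ (1-p)^2 L_i(0) + 2p(1-p) L_i(1) + p^2 L_i(2) ]

where ``L_i(g)`` is individual *i*'s likelihood of carrying ``g`` copies
of the minor allele.  The MLE is found either with an EM algorithm (the
mean posterior minor-allele dosage is iterated) or by direct bounded 1-D
optimization; both use the stopping/convergence conventions documented on
the individual functions.

When the minor allele itself is uncertain (rare variants), the likelihood
is marginalized over the three non-major nucleotides with equal prior
weight:

    L(p) = (1/3) sum_m L(p | minor = m)

evaluated in log space.  The batch functions operate on whole arrays of
sites at once and are the engines behind the simulation pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .likelihood_core import NUC_INDEX, NUCLEOTIDES, SiteAlleles, triplets_from_gl10

_LN3 = np.log(3.0)

#: for each major-allele index, the other three nucleotides in A<C<G<T order
CANDIDATE_MINORS = np.array(
    [[b for b in range(4) if b != a] for a in range(4)], dtype=np.intp
)

DEFAULT_TOL = 1e-3  # natural-log-likelihood increase below which EM stops
DEFAULT_MAX_ITER = 1000
DEFAULT_P0 = 0.1


@dataclass
class FrequencyFit:
    """Result of a single-site MAF fit."""

    maf: float
    loglik: float
    method: str
    iterations: int
    converged: bool
    alleles: SiteAlleles | None = None
    minor_swapped: bool = False  # estimate folded, allele labels exchanged
    minor_weights: np.ndarray | None = None  # unknown-minor posterior weights

    @property
    def at_upper_bound(self) -> bool:
        return self.maf == 0.5


def hwe_weights(p: np.ndarray | float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2)."""
    p = np.asarray(p, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def loglik_known_minor(triplets: np.ndarray, p: float) -> float:
    """Log-likelihood of MAF ``p`` given per-individual (N, 3) log triplets."""
    triplets = np.asarray(triplets, dtype=float)
    if triplets.ndim != 2 or triplets.shape[-1] != 3:
        raise ValueError("triplets must have shape (n_individuals, 3)")
    if triplets.shape[0] == 0:
        raise ValueError("at least one individual is required")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(loglik_known_minor_batch(triplets[np.newaxis], np.array([p]))[0])


def loglik_known_minor_batch(triplets: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-site log-likelihoods for (S, N, 3) triplets and (S,) frequencies."""
    triplets = np.asarray(triplets, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        log_hwe = np.log(hwe_weights(p))  # (S, 3)
    terms = triplets + log_hwe[:, np.newaxis, :]
    return logsumexp(terms, axis=-1).sum(axis=-1)


def _normalize(logl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear-space likelihoods scaled so each individual's max is 1.

    Returns the scaled array and the per-site log-offset that restores
    absolute log-likelihoods.  The offset is additive and cancels in
    likelihood-ratio statistics.
    """
    off = np.max(logl, axis=-1)
    off = np.where(np.isneginf(off), 0.0, off)
    lin = np.exp(logl - off[..., np.newaxis])
    # sum offsets over every axis except the site axis (0) and none beyond
    return lin, off.reshape(off.shape[0], -1).sum(axis=-1)


def _em_known(
    lin: np.ndarray,
    tol: float,
    max_iter: int,
    p0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM for the known-minor likelihood on normalized (S, N, 3) arrays.

    Iterates p <- mean posterior dosage / 2 over [0, 1]; the caller folds.
    Returns (p, loglik, iterations, converged, identifiable).
    """
    n_sites, n_ind, _ = lin.shape
    identifiable = (np.ptp(lin, axis=-1) > 0).any(axis=-1)
    p = np.full(n_sites, float(p0))
    ll = _ll_lin(lin, p)
    iters = np.zeros(n_sites, dtype=np.int64)
    converged = np.zeros(n_sites, dtype=bool)
    idx = np.flatnonzero(identifiable)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        sub = lin[idx]
        w = hwe_weights(p[idx])[:, np.newaxis, :] * sub  # (A, N, 3)
        denom = w.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            post = (w[..., 1] + 2.0 * w[..., 2]) / denom
        post = np.where(denom > 0, post, 0.0)
        p_new = post.sum(axis=-1) / (2.0 * n_ind)
        ll_new = _ll_lin(sub, p_new)
        gain = ll_new - ll[idx]
        p[idx] = p_new
        ll[idx] = ll_new
        iters[idx] += 1
        done = gain < tol
        converged[idx[done]] = True
        idx = idx[~done]
    p[~identifiable] = np.nan
    return p, ll, iters, converged, identifiable


def _ll_lin(lin: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Log-likelihood (up to the normalization offset) from linear arrays."""
    mix = (hwe_weights(p)[:, np.newaxis, :] * lin).sum(axis=-1)
    with np.errstate(divide="ignore"):
        return np.log(mix).sum(axis=-1)


def estimate_maf_em_batch(
    triplets: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    p0: float = DEFAULT_P0,
    fold: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized EM over (S, N, 3) log-likelihood triplets.

    Returns arrays keyed ``maf``, ``loglik``, ``iterations``,
    ``converged``, ``defined`` and ``swapped`` (estimate above 0.5 folded
    to 1-p with the allele labels logically exchanged).
    """
    triplets = np.asarray(triplets, dtype=float)
    if triplets.ndim != 3 or triplets.shape[-1] != 3:
        raise ValueError("triplets must have shape (n_sites, n_individuals, 3)")
    if triplets.shape[1] == 0:
        raise ValueError("at least one individual is required")
    lin, offs = _normalize(triplets)
    p, ll, iters, converged, defined = _em_known(lin, tol, max_iter, p0)
    swapped = np.zeros(p.shape, dtype=bool)
    if fold:
        with np.errstate(invalid="ignore"):
            swapped = p > 0.5
        p = np.where(swapped, 1.0 - p, p)
    return {
        "maf": p,
        "loglik": ll + offs,
        "iterations": iters,
        "converged": converged & defined,
        "defined": defined,
        "swapped": swapped,
    }


def estimate_maf_em(
    triplets: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    p0: float = DEFAULT_P0,
    alleles: SiteAlleles | None = None,
) -> FrequencyFit:
    """EM fit of the known-minor MAF likelihood for one site."""
    res = estimate_maf_em_batch(
        np.asarray(triplets, dtype=float)[np.newaxis], tol, max_iter, p0
    )
    swapped = bool(res["swapped"][0])
    if swapped and alleles is not None and alleles.minor is not None:
        alleles = SiteAlleles(alleles.minor, alleles.major)
    return FrequencyFit(
        maf=float(res["maf"][0]),
        loglik=float(res["loglik"][0]),
        method="em",
        iterations=int(res["iterations"][0]),
        converged=bool(res["converged"][0]),
        alleles=alleles,
        minor_swapped=swapped,
    )


def estimate_maf_direct(
    triplets: np.ndarray,
    bounds: tuple[float, float] = (0.0, 0.5),
    xatol: float = 1e-9,
    alleles: SiteAlleles | None = None,
) -> FrequencyFit:
    """Direct bounded 1-D maximization of the known-minor likelihood.

    The optimum is compared against both interval endpoints so true
    boundary solutions (monomorphic sites) are reported exactly.
    """
    triplets = np.asarray(triplets, dtype=float)
    if triplets.ndim != 2 or triplets.shape[-1] != 3:
        raise ValueError("triplets must have shape (n_individuals, 3)")
    if triplets.shape[0] == 0:
        raise ValueError("at least one individual is required")
    if np.all(np.ptp(triplets, axis=-1) == 0):
        return FrequencyFit(np.nan, 0.0, "direct", 0, False, alleles)
    lin, offs = _normalize(triplets[np.newaxis])

    def neg(p: float) -> float:
        return -float(_ll_lin(lin, np.array([p]))[0])

    res = minimize_scalar(neg, bounds=bounds, method="bounded", options={"xatol": xatol})
    candidates = np.array([bounds[0], bounds[1], float(res.x)])
    values = np.array([-neg(c) for c in candidates])
    best = int(np.argmax(values + np.array([1e-12, 1e-12, 0.0])))
    return FrequencyFit(
        maf=float(candidates[best]),
        loglik=float(values[best] + offs[0]),
        method="direct",
        iterations=int(res.nfev),
        converged=bool(res.success),
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# unknown minor allele
# ---------------------------------------------------------------------------


def candidate_triplet_array(gl10: np.ndarray, major: np.ndarray | int) -> np.ndarray:
    """(S, 3, N, 3) log triplets for each candidate minor allele.

    ``gl10`` has shape (S, N, 10); ``major`` is a nucleotide index,
    scalar or per-site.  Candidate order follows A<C<G<T among non-major
    nucleotides.
    """
    gl10 = np.asarray(gl10, dtype=float)
    major = np.broadcast_to(np.asarray(major, dtype=np.intp), gl10.shape[:1])
    cands = CANDIDATE_MINORS[major]  # (S, 3)
    stacked = [
        triplets_from_gl10(gl10, major, cands[:, c]) for c in range(3)
    ]
    return np.stack(stacked, axis=1)


def loglik_unknown_minor(gl10s: np.ndarray, major: str, p: float) -> float:
    """Minor-allele-marginalized log-likelihood for one site.

    Computed via the ordered log-scale form
    ``l(1) + ln(1 + e^(l(2)-l(1)) + e^(l(3)-l(1))) - ln 3`` with ``l(1)``
    the largest candidate log-likelihood.
    """
    gl10s = np.asarray(gl10s, dtype=float)
    if gl10s.ndim != 2 or gl10s.shape[-1] != 10:
        raise ValueError("gl10s must have shape (n_individuals, 10)")
    if gl10s.shape[0] == 0:
        raise ValueError("at least one individual is required")
    if major not in NUC_INDEX:
        raise ValueError(f"invalid major allele {major!r}")
    if not 0.0 <= p <= 0.5:
        raise ValueError("p must lie in [0, 0.5]")
    lcand = candidate_triplet_array(gl10s[np.newaxis], NUC_INDEX[major])
    ls = np.array(
        [
            loglik_known_minor_batch(lcand[:, c], np.array([p]))[0]
            for c in range(3)
        ]
    )
    order = np.sort(ls)[::-1]
    return float(
        order[0] + np.log1p(np.exp(order[1] - order[0]) + np.exp(order[2] - order[0])) - _LN3
    )


def _ll_unknown_lin(lin: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Marginal log-likelihood and candidate log-weights.

    ``lin`` has shape (S, 3, N, 3) normalized per (site, individual)
    jointly over candidates.  Returns (loglik (S,), per-candidate
    conditional log-likelihoods (S, 3)), both up to the offset.
    """
    mix = (hwe_weights(p)[:, np.newaxis, np.newaxis, :] * lin).sum(axis=-1)
    with np.errstate(divide="ignore"):
        a = np.log(mix).sum(axis=-1)  # (S, 3)
    return logsumexp(a, axis=-1) - _LN3, a


def _em_unknown(
    lin: np.ndarray,
    tol: float,
    max_iter: int,
    p0: float,
    p_max: float = 0.5,
) -> tuple[np.ndarray, ...]:
    """EM for the unknown-minor marginal on (S, 3, N, 3) arrays.

    The candidate minor allele is a site-level latent variable: the
    E-step weights candidates by their conditional likelihood, the
    M-step updates p from the weighted mean posterior dosage, clipped to
    [0, p_max] (the clipped update still maximizes the constrained Q, so
    ascent is preserved).
    Returns (p, loglik, candidate posterior weights, iters, converged,
    identifiable).
    """
    n_sites, _, n_ind, _ = lin.shape
    identifiable = (np.ptp(lin, axis=-1) > 0).any(axis=(-1, -2))
    p = np.full(n_sites, min(float(p0), p_max))
    ll, a = _ll_unknown_lin(lin, p)
    weights = _softmax(a)
    iters = np.zeros(n_sites, dtype=np.int64)
    converged = np.zeros(n_sites, dtype=bool)
    idx = np.flatnonzero(identifiable)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        sub = lin[idx]
        hw = hwe_weights(p[idx])[:, np.newaxis, np.newaxis, :]
        w = hw * sub  # (A, 3, N, 3)
        denom = w.sum(axis=-1)  # (A, 3, N)
        with np.errstate(invalid="ignore", divide="ignore"):
            post = (w[..., 1] + 2.0 * w[..., 2]) / denom
            log_denom = np.where(denom > 0, np.log(denom), -np.inf)
        post = np.where(denom > 0, post, 0.0)
        a_sub = log_denom.sum(axis=-1)  # (A, 3)
        w_cand = _softmax(a_sub)
        dosage = (w_cand * post.sum(axis=-1)).sum(axis=-1)
        p_new = np.clip(dosage / (2.0 * n_ind), 0.0, p_max)
        ll_new, a_new = _ll_unknown_lin(sub, p_new)
        gain = ll_new - ll[idx]
        p[idx] = p_new
        ll[idx] = ll_new
        weights[idx] = _softmax(a_new)
        iters[idx] += 1
        done = gain < tol
        converged[idx[done]] = True
        idx = idx[~done]
    p[~identifiable] = np.nan
    return p, ll, weights, iters, converged, identifiable


def _softmax(a: np.ndarray) -> np.ndarray:
    amax = np.max(a, axis=-1, keepdims=True)
    amax = np.where(np.isneginf(amax), 0.0, amax)
    e = np.exp(a - amax)
    total = e.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = e / total
    return np.where(total > 0, out, 1.0 / a.shape[-1])


def estimate_maf_unknown_minor_batch(
    gl10: np.ndarray,
    major: np.ndarray | int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    p0: float = DEFAULT_P0,
) -> dict[str, np.ndarray]:
    """Vectorized unknown-minor EM over (S, N, 10) genotype likelihoods.

    In addition to the fields of :func:`estimate_maf_em_batch`, returns
    ``minor`` (nucleotide index of the highest-weight candidate, or -1
    when no candidate dominates by at least a factor of 2) and
    ``minor_weights`` (S, 3).
    """
    gl10 = np.asarray(gl10, dtype=float)
    if gl10.ndim != 3 or gl10.shape[-1] != 10:
        raise ValueError("gl10 must have shape (n_sites, n_individuals, 10)")
    if gl10.shape[1] == 0:
        raise ValueError("at least one individual is required")
    major = np.broadcast_to(np.asarray(major, dtype=np.intp), gl10.shape[:1])
    lcand = candidate_triplet_array(gl10, major)
    # joint normalization across candidates keeps their relative weights
    off = np.max(lcand, axis=(1, 3))  # (S, N)
    off = np.where(np.isneginf(off), 0.0, off)
    lin = np.exp(lcand - off[:, np.newaxis, :, np.newaxis])
    offs = off.sum(axis=-1)
    p, ll, weights, iters, converged, defined = _em_unknown(lin, tol, max_iter, p0)
    minor = _designate_minor(weights, major)
    return {
        "maf": p,
        "loglik": ll + offs,
        "iterations": iters,
        "converged": converged & defined,
        "defined": defined,
        "minor": minor,
        "minor_weights": weights,
    }


def _designate_minor(weights: np.ndarray, major: np.ndarray) -> np.ndarray:
    """Candidate with highest posterior weight, -1 if within factor 2 of
    the runner-up."""
    order = np.argsort(weights, axis=-1)
    best, second = order[..., -1], order[..., -2]
    w_best = np.take_along_axis(weights, best[..., None], axis=-1)[..., 0]
    w_second = np.take_along_axis(weights, second[..., None], axis=-1)[..., 0]
    nuc = CANDIDATE_MINORS[major, best]
    return np.where(w_best >= 2.0 * w_second, nuc, -1).astype(np.intp)


def estimate_maf_unknown_minor(
    gl10s: np.ndarray,
    major: str,
    bounds: tuple[float, float] = (0.0, 0.5),
    xatol: float = 1e-9,
) -> FrequencyFit:
    """Unknown-minor MAF estimate for one site by bounded 1-D maximization.

    The reported minor allele is the candidate with the highest posterior
    weight at the optimum, or ``None`` ("unknown") when the top weight is
    within a factor of 2 of the runner-up.
    """
    gl10s = np.asarray(gl10s, dtype=float)
    if gl10s.ndim != 2 or gl10s.shape[-1] != 10:
        raise ValueError("gl10s must have shape (n_individuals, 10)")
    if gl10s.shape[0] == 0:
        raise ValueError("at least one individual is required")
    if major not in NUC_INDEX:
        raise ValueError(f"invalid major allele {major!r}")
    major_idx = NUC_INDEX[major]
    lcand = candidate_triplet_array(gl10s[np.newaxis], major_idx)
    off = np.max(lcand, axis=(1, 3))
    off = np.where(np.isneginf(off), 0.0, off)
    lin = np.exp(lcand - off[:, np.newaxis, :, np.newaxis])
    offs = float(off.sum())
    if not (np.ptp(lin, axis=-1) > 0).any():
        return FrequencyFit(np.nan, 0.0, "direct", 0, False, SiteAlleles(major))

    def neg(p: float) -> float:
        return -float(_ll_unknown_lin(lin, np.array([p]))[0][0])

    res = minimize_scalar(neg, bounds=bounds, method="bounded", options={"xatol": xatol})
    candidates = np.array([bounds[0], bounds[1], float(res.x)])
    values = np.array([-neg(c) for c in candidates])
    best = int(np.argmax(values + np.array([1e-12, 1e-12, 0.0])))
    p_hat = float(candidates[best])
    _, a = _ll_unknown_lin(lin, np.array([p_hat]))
    weights = _softmax(a)[0]
    minor_idx = _designate_minor(weights[np.newaxis], np.array([major_idx]))[0]
    alleles = SiteAlleles(
        major, None if minor_idx < 0 else NUCLEOTIDES[minor_idx]
    )
    return FrequencyFit(
        maf=p_hat,
        loglik=float(values[best] + offs),
        method="direct",
        iterations=int(res.nfev),
        converged=bool(res.success),
        alleles=alleles,
        minor_weights=weights,
    )
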