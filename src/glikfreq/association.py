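"""Case/control association tests at a single site.

Two families of tests are provided.  The first operates on called
genotypes: the allelic G-test (likelihood-ratio test of independence on
the 2x2 case/control x minor/major allele table) and the Cochran-Armitage
trend test on the 2x3 genotype table.  The second integrates over
genotype uncertainty: a likelihood-ratio test comparing a shared MAF
against group-specific MAFs, using the same marginal likelihoods as the
MAF estimators, in both known-minor and unknown-minor form.  All
statistics are referred to the chi-square(1) upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from . import ml_maf
from .genotype_calling import MISSING
from .ml_maf import FrequencyFit

_TREND_SCORES = np.array([0.0, 1.0, 2.0])

#: EM stopping tolerance for likelihood-ratio statistics.  Tighter than the
#: estimation default: the statistic is a difference of maximized
#: log-likelihoods, so residual under-maximization of the null fit would
#: otherwise inflate the test.
LRT_TOL: float = 1e-6


@dataclass
class AssocResult:
    """Association test outcome: statistic, df=1 and chi-square p-value."""

    statistic: float
    p_value: float
    df: int = 1
    fits: dict[str, FrequencyFit] | None = None
    converged: bool = True


def _chi2_result(stat: float, **kw) -> AssocResult:
    stat = max(float(stat), 0.0)
    return AssocResult(stat, float(chi2.sf(stat, 1)), **kw)


def allele_counts_from_calls(calls: np.ndarray) -> tuple[int, int]:
    """(minor, major) allele counts over called individuals."""
    calls = np.asarray(calls)
    ok = calls != MISSING
    minor = int(np.where(ok, calls, 0).sum())
    return minor, int(2 * ok.sum() - minor)


def g_test_statistic(table: np.ndarray) -> float:
    """G = 2 sum O ln(O/E) on a 2x2 table; degenerate margins give 0.

    Rows are (case, control), columns (minor, major) allele counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    return float(
        g_test_statistic_batch(
            np.array([t[0, 0]]),
            np.array([t[0, 1]]),
            np.array([t[1, 0]]),
            np.array([t[1, 1]]),
        )[0]
    )


def g_test_statistic_batch(
    minor_case: np.ndarray,
    major_case: np.ndarray,
    minor_control: np.ndarray,
    major_control: np.ndarray,
) -> np.ndarray:
    """Vectorized allelic G statistic from per-site allele counts."""
    obs = np.stack(
        [
            np.stack([minor_case, major_case], axis=-1),
            np.stack([minor_control, major_control], axis=-1),
        ],
        axis=-2,
    ).astype(float)  # (S, 2, 2)
    row = obs.sum(axis=-1, keepdims=True)
    col = obs.sum(axis=-2, keepdims=True)
    total = obs.sum(axis=(-1, -2), keepdims=True)
    degenerate = ((row == 0).any(axis=(-1, -2)) | (col == 0).any(axis=(-1, -2)))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / total
        terms = obs * np.log(obs / expected)
    terms = np.where(obs > 0, terms, 0.0)
    g = 2.0 * np.nan_to_num(terms, nan=0.0).sum(axis=(-1, -2))
    return np.where(degenerate, 0.0, np.maximum(g, 0.0))


def g_test(cases: np.ndarray, controls: np.ndarray) -> AssocResult:
    """Allelic G-test from called genotypes; missing individuals excluded.

    Monomorphic or empty tables (a zero margin) return statistic 0 and
    p-value 1: such sites carry no association signal.
    """
    mc, jc = allele_counts_from_calls(cases)
    mk, jk = allele_counts_from_calls(controls)
    stat = g_test_statistic_batch(
        np.array([mc]), np.array([jc]), np.array([mk]), np.array([jk])
    )[0]
    return _chi2_result(stat)


def armitage_trend(cases: np.ndarray, controls: np.ndarray) -> AssocResult:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    Robust to Hardy-Weinberg departures because it compares genotype
    counts directly.  Degenerate tables (zero score variance or an empty
    group) return statistic 0.
    """
    cases = np.asarray(cases)
    controls = np.asarray(controls)
    r = np.array([(cases == g).sum() for g in range(3)], dtype=float)
    s = np.array([(controls == g).sum() for g in range(3)], dtype=float)
    n_col = r + s
    big_r, big_n = r.sum(), r.sum() + s.sum()
    if big_n == 0 or big_r == 0 or big_r == big_n:
        return _chi2_result(0.0)
    num = big_n * (_TREND_SCORES * r).sum() - big_r * (_TREND_SCORES * n_col).sum()
    var = (
        big_r
        * (big_n - big_r)
        * (big_n * (_TREND_SCORES**2 * n_col).sum() - (_TREND_SCORES * n_col).sum() ** 2)
    )
    if var <= 0:
        return _chi2_result(0.0)
    return _chi2_result(big_n * num**2 / var)


# ---------------------------------------------------------------------------
# likelihood-ratio tests on genotype likelihoods
# ---------------------------------------------------------------------------


def lrt_known_minor(
    case_triplets: np.ndarray,
    control_triplets: np.ndarray,
    tol: float = LRT_TOL,
    max_iter: int = ml_maf.DEFAULT_MAX_ITER,
) -> AssocResult:
    """LRT for equal MAF in cases and controls, minor allele known.

    ``2 [l(p1; cases) + l(p2; controls) - l(p0; combined)]`` with each
    term maximized by EM; clamped at zero against optimizer noise.
    """
    case_triplets = np.asarray(case_triplets, dtype=float)
    control_triplets = np.asarray(control_triplets, dtype=float)
    fit_case = ml_maf.estimate_maf_em(case_triplets, tol, max_iter)
    fit_control = ml_maf.estimate_maf_em(control_triplets, tol, max_iter)
    combined = np.concatenate([case_triplets, control_triplets], axis=0)
    fit_null = ml_maf.estimate_maf_em(combined, tol, max_iter)
    fits = {"cases": fit_case, "controls": fit_control, "null": fit_null}
    stat = 2.0 * (fit_case.loglik + fit_control.loglik - fit_null.loglik)
    res = _chi2_result(stat, fits=fits)
    res.converged = (
        fit_case.converged and fit_control.converged and fit_null.converged
    )
    return res


def lrt_known_minor_batch(
    case_triplets: np.ndarray,
    control_triplets: np.ndarray,
    tol: float = LRT_TOL,
    max_iter: int = ml_maf.DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Vectorized known-minor LRT statistics over (S, N, 3) arrays."""
    fold = dict(fold=False)
    a = ml_maf.estimate_maf_em_batch(case_triplets, tol, max_iter, **fold)
    b = ml_maf.estimate_maf_em_batch(control_triplets, tol, max_iter, **fold)
    combined = np.concatenate([case_triplets, control_triplets], axis=1)
    n = ml_maf.estimate_maf_em_batch(combined, tol, max_iter, **fold)
    stat = 2.0 * (a["loglik"] + b["loglik"] - n["loglik"])
    return np.maximum(np.nan_to_num(stat, nan=0.0), 0.0)


def lrt_unknown_minor(
    case_gl10s: np.ndarray,
    control_gl10s: np.ndarray,
    major: str,
    tol: float = LRT_TOL,
    max_iter: int = ml_maf.DEFAULT_MAX_ITER,
    shared_minor: bool = True,
) -> AssocResult:
    """LRT with the minor allele marginalized out.

    The null maximizes the minor-marginalized likelihood of the combined
    sample over one frequency.  With ``shared_minor`` (default) the
    alternative maximizes over (p1, p2) the joint marginal
    ``(1/3) sum_m L_cases(p1 | m) * L_controls(p2 | m)`` — the candidate
    minor allele is shared across groups, so the null is nested and the
    statistic is non-negative.  ``shared_minor=False`` marginalizes each
    group independently (not nested; for comparison only).
    """
    case_gl10s = np.asarray(case_gl10s, dtype=float)
    control_gl10s = np.asarray(control_gl10s, dtype=float)
    stat = lrt_unknown_minor_batch(
        case_gl10s[np.newaxis],
        control_gl10s[np.newaxis],
        major,
        tol=tol,
        max_iter=max_iter,
        shared_minor=shared_minor,
    )[0]
    return _chi2_result(stat)


def lrt_unknown_minor_batch(
    case_gl10: np.ndarray,
    control_gl10: np.ndarray,
    major: np.ndarray | int | str,
    tol: float = LRT_TOL,
    max_iter: int = ml_maf.DEFAULT_MAX_ITER,
    shared_minor: bool = True,
) -> np.ndarray:
    """Vectorized unknown-minor LRT statistics over (S, N, 10) arrays."""
    from .likelihood_core import NUC_INDEX

    if isinstance(major, str):
        major = NUC_INDEX[major]
    case_gl10 = np.asarray(case_gl10, dtype=float)
    control_gl10 = np.asarray(control_gl10, dtype=float)
    major = np.broadcast_to(np.asarray(major, dtype=np.intp), case_gl10.shape[:1])
    combined = np.concatenate([case_gl10, control_gl10], axis=1)
    null = ml_maf.estimate_maf_unknown_minor_batch(combined, major, tol, max_iter)
    if shared_minor:
        ll_alt = _alt_shared_minor_loglik(
            case_gl10, control_gl10, major, tol, max_iter
        )
    else:
        a = ml_maf.estimate_maf_unknown_minor_batch(case_gl10, major, tol, max_iter)
        b = ml_maf.estimate_maf_unknown_minor_batch(control_gl10, major, tol, max_iter)
        ll_alt = a["loglik"] + b["loglik"]
    stat = 2.0 * (ll_alt - null["loglik"])
    return np.maximum(np.nan_to_num(stat, nan=0.0), 0.0)


def _alt_shared_minor_loglik(
    case_gl10: np.ndarray,
    control_gl10: np.ndarray,
    major: np.ndarray,
    tol: float,
    max_iter: int,
    p0: float = ml_maf.DEFAULT_P0,
) -> np.ndarray:
    """Maximized joint marginal log-likelihood over (p1, p2).

    EM with the shared candidate minor allele as a site-level latent
    variable: candidate weights combine both groups' conditional
    likelihoods, and each group's frequency is updated from its own
    weighted posterior dosages (clipped to [0, 0.5]).
    """
    lin_a, offs_a = _normalized_candidates(case_gl10, major)
    lin_b, offs_b = _normalized_candidates(control_gl10, major)
    n_sites = lin_a.shape[0]
    n_a, n_b = lin_a.shape[2], lin_b.shape[2]
    p1 = np.full(n_sites, ml_maf.DEFAULT_P0)
    p2 = np.full(n_sites, ml_maf.DEFAULT_P0)
    ll = _joint_ll(lin_a, lin_b, p1, p2)
    idx = np.arange(n_sites)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        sa, sb = lin_a[idx], lin_b[idx]
        a_a, post_a = _cand_stats(sa, p1[idx])
        a_b, post_b = _cand_stats(sb, p2[idx])
        w_cand = ml_maf._softmax(a_a + a_b)
        p1_new = np.clip((w_cand * post_a).sum(axis=-1) / (2.0 * n_a), 0.0, 0.5)
        p2_new = np.clip((w_cand * post_b).sum(axis=-1) / (2.0 * n_b), 0.0, 0.5)
        ll_new = _joint_ll(sa, sb, p1_new, p2_new)
        gain = ll_new - ll[idx]
        p1[idx], p2[idx], ll[idx] = p1_new, p2_new, ll_new
        idx = idx[gain >= tol]
    return ll + offs_a + offs_b


def _normalized_candidates(
    gl10: np.ndarray, major: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    lcand = ml_maf.candidate_triplet_array(gl10, major)
    off = np.max(lcand, axis=(1, 3))
    off = np.where(np.isneginf(off), 0.0, off)
    lin = np.exp(lcand - off[:, np.newaxis, :, np.newaxis])
    return lin, off.sum(axis=-1)


def _cand_stats(lin: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-candidate conditional log-likelihood and summed posterior dosage."""
    w = ml_maf.hwe_weights(p)[:, np.newaxis, np.newaxis, :] * lin
    denom = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = (w[..., 1] + 2.0 * w[..., 2]) / denom
        log_denom = np.where(denom > 0, np.log(denom), -np.inf)
    post = np.where(denom > 0, post, 0.0)
    return log_denom.sum(axis=-1), post.sum(axis=-1)


def _joint_ll(
    lin_a: np.ndarray, lin_b: np.ndarray, p1: np.ndarray, p2: np.ndarray
) -> np.ndarray:
    a_a, _ = _cand_stats(lin_a, p1)
    a_b, _ = _cand_stats(lin_b, p2)
    return logsumexp(a_a + a_b, axis=-1) - np.log(3.0)
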