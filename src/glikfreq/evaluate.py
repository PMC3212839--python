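"""Evaluation machinery for the simulation study.

Accuracy metrics (MSE, median bias), the folded MAF spectrum with a
low-frequency cutoff, null-calibration summaries (type-I error rate,
genomic-control inflation factor, QQ data) and empirical-null ROC power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

#: median of the chi-square(1) distribution (genomic-control denominator)
CHI2_1_MEDIAN: float = float(chi2.ppf(0.5, 1))


@dataclass
class SpectrumResult:
    """Folded MAF spectrum above a cutoff.

    ``proportions[k]`` is the fraction of retained sites with estimate in
    ``[edges[k], edges[k+1])`` (last bin closed at 0.5).
    """

    edges: np.ndarray
    proportions: np.ndarray
    n_retained: int
    n_total: int

    @property
    def empty(self) -> bool:
        return self.n_retained == 0


def _paired(estimates: np.ndarray, truths: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape or estimates.ndim != 1:
        raise ValueError("estimates and truths must be equal-length 1-D arrays")
    if estimates.size == 0:
        raise ValueError("empty input")
    ok = ~np.isnan(estimates)
    return estimates[ok], truths[ok], int((~ok).sum())


def mse(estimates: np.ndarray, truths: np.ndarray) -> tuple[float, int]:
    """Mean squared error, excluding undefined (NaN) estimates pairwise.

    Returns ``(mse, n_excluded)``; raises if every estimate is undefined.
    """
    est, tru, n_excluded = _paired(estimates, truths)
    if est.size == 0:
        raise ValueError("all estimates are undefined")
    return float(np.mean((est - tru) ** 2)), n_excluded


def median_estimate(estimates: np.ndarray) -> float:
    """Median over defined estimates (NaN excluded)."""
    estimates = np.asarray(estimates, dtype=float)
    ok = ~np.isnan(estimates)
    if not ok.any():
        raise ValueError("all estimates are undefined")
    return float(np.median(estimates[ok]))


def spectrum(
    estimates: np.ndarray, cutoff: float = 0.02, bin_width: float = 0.02
) -> SpectrumResult:
    """Histogram of estimates on [cutoff, 0.5], dropping those below cutoff.

    Estimates exactly at the cutoff are retained (only strictly smaller
    ones are discarded).  NaN estimates are dropped.
    """
    estimates = np.asarray(estimates, dtype=float)
    n_total = estimates.size
    kept = estimates[~np.isnan(estimates) & (estimates >= cutoff)]
    edges = np.arange(cutoff, 0.5 + bin_width / 2, bin_width)
    hist, _ = np.histogram(kept, bins=edges)
    if kept.size:
        proportions = hist / kept.size
    else:
        proportions = np.zeros(len(edges) - 1)
    return SpectrumResult(edges, proportions, int(kept.size), int(n_total))


def type_i_error(null_stats: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of chi-square(1) p-values below ``alpha`` under the null."""
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("empty input")
    pvals = chi2.sf(null_stats, 1)
    return float(np.mean(pvals < alpha))


def empirical_power(
    null_stats: np.ndarray,
    alt_stats: np.ndarray,
    fpr_grid: np.ndarray | float,
) -> np.ndarray | float:
    """Power at empirical-null critical values.

    The critical value at false-positive rate ``r`` is the empirical
    ``1-r`` quantile of the null statistics (linear-interpolation,
    "type 7", quantile); power is the fraction of alternative statistics
    strictly exceeding it.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    alt_stats = np.asarray(alt_stats, dtype=float)
    if null_stats.size == 0 or alt_stats.size == 0:
        raise ValueError("empty input")
    fpr = np.atleast_1d(np.asarray(fpr_grid, dtype=float))
    crit = np.quantile(null_stats, 1.0 - fpr)
    power = (alt_stats[np.newaxis, :] > crit[:, np.newaxis]).mean(axis=1)
    return float(power[0]) if np.ndim(fpr_grid) == 0 else power


def inflation_factor(stats: np.ndarray) -> float:
    """Genomic-control inflation factor: median statistic / chi2(1) median."""
    stats = np.asarray(stats, dtype=float)
    if stats.size == 0:
        raise ValueError("empty input")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def qq_points(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical chi2(1) quantiles, sorted statistics) for QQ plots.

    The i-th order statistic is paired with the chi-square(1) quantile at
    probability ``(i - 0.5)/n``.
    """
    stats = np.asarray(stats, dtype=float)
    if stats.size == 0:
        raise ValueError("empty input")
    n = stats.size
    theoretical = chi2.ppf((np.arange(1, n + 1) - 0.5) / n, 1)
    return theoretical, np.sort(stats)
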