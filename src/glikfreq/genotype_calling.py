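"""Maximum-likelihood genotype calling and count-based MAF estimation.

These are the "Call NF" (no filter) and "Call F" (filtered) baselines: the
most likely of the three genotypes is assigned to each individual, a call
optionally being withheld unless it beats the runner-up by a factor of
``10**f`` in likelihood.  The minor allele frequency is then estimated by
counting alleles among called individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: sentinel genotype code for a missing (uncalled) individual
MISSING: int = -1

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class CallPolicy:
    """Calling-confidence filter.

    ``f`` is the log10 likelihood-ratio threshold between the best and
    second-best genotype; ``f = 0`` disables filtering and ``f = 1``
    (a common choice) requires the best genotype to be at least 10 times
    more likely than the runner-up.
    """

    f: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f >= 0):
            raise ValueError("filter threshold f must be non-negative")


def call_genotypes(triplets: np.ndarray, policy: CallPolicy) -> np.ndarray:
    """Call genotypes from (..., 3) log-likelihood triplets.

    Returns an integer array over the leading axes with values in
    {0, 1, 2} or :data:`MISSING`.  Rules:

    - an individual with no reads (flat all-zero triplet) is never called;
    - with ``f = 0`` the maximum-likelihood genotype is returned, exact
      ties resolving to the lower genotype code;
    - with ``f > 0`` the call requires
      ``log10 L(best) - log10 L(second) >= f``, so exact first-place ties
      are missing.
    """
    triplets = np.asarray(triplets, dtype=float)
    if triplets.shape[-1] != 3:
        raise ValueError("last axis of triplets must have length 3")
    best = np.argmax(triplets, axis=-1)  # lowest code on exact ties
    srt = np.sort(triplets, axis=-1)
    top, second = srt[..., 2], srt[..., 1]
    # zero reads <=> all three likelihoods are exactly 1 (log 0)
    no_data = np.all(triplets == 0.0, axis=-1)
    if policy.f == 0:
        called = ~no_data
    else:
        with np.errstate(invalid="ignore"):
            ratio = (top - second) / _LN10
        # -inf - -inf gives nan; such triplets carry no ranking information
        passed = np.where(np.isnan(ratio), False, ratio >= policy.f)
        called = passed & ~no_data
    return np.where(called, best, MISSING).astype(np.int8)


def call_genotype(triplet: np.ndarray, policy: CallPolicy) -> int | None:
    """Single-individual form of :func:`call_genotypes`; None when missing."""
    code = int(call_genotypes(np.asarray(triplet)[np.newaxis, :], policy)[0])
    return None if code == MISSING else code


def maf_from_calls(calls: np.ndarray) -> float:
    """Allele-counting MAF estimate from called genotypes.

    ``calls`` holds genotype codes (minor-allele dosage) with
    :data:`MISSING` for uncalled individuals, which are excluded.  With
    zero called individuals the estimate is undefined and NaN is
    returned.
    """
    return float(maf_from_calls_batch(np.asarray(calls)[np.newaxis, :])[0])


def maf_from_calls_batch(calls: np.ndarray) -> np.ndarray:
    """Per-site allele-counting MAF estimates for a (S, N) calls array."""
    calls = np.asarray(calls)
    ok = calls != MISSING
    n_called = ok.sum(axis=-1)
    dosage = np.where(ok, calls, 0).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = dosage / (2.0 * n_called)
    return np.where(n_called > 0, est, np.nan)
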