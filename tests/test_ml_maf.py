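"""Maximum-likelihood MAF estimation (known and unknown minor allele)."""

import numpy as np
import pytest

from glikfreq import SimulationConfig, simulate_sites
from glikfreq.likelihood_core import (
    NUCLEOTIDES,
    ErrorMatrix,
    gl10_from_counts,
    triplets_from_gl10,
)
from glikfreq import ml_maf
from glikfreq.ml_maf import (
    estimate_maf_direct,
    estimate_maf_em,
    estimate_maf_em_batch,
    estimate_maf_unknown_minor,
    estimate_maf_unknown_minor_batch,
    hwe_weights,
    loglik_known_minor,
    loglik_unknown_minor,
)

TIGHT = dict(tol=1e-10, max_iter=100_000)


def perfect_triplets(genotypes):
    """Log-likelihood triplets that identify each genotype exactly."""
    trip = np.full((len(genotypes), 3), -np.inf)
    trip[np.arange(len(genotypes)), genotypes] = 0.0
    return trip


def grid_argmax(triplets, step=5e-4):
    grid = np.arange(0.0, 0.5 + step / 2, step)
    lls = [loglik_known_minor(triplets, p) for p in grid]
    return grid[int(np.argmax(lls))]


def simulated_triplets(rng, n_sites, n=60, depth=4.0, maf=0.15):
    err = ErrorMatrix.uniform()
    cfg = SimulationConfig(n, depth, err)
    _, counts = simulate_sites(maf, cfg, rng, n_sites=n_sites)
    gl10 = gl10_from_counts(counts, err)
    return triplets_from_gl10(gl10, 0, 1)


class TestLoglikKnownMinor:
    def test_point_mass_closed_form(self):
        trip = perfect_triplets([0])
        assert loglik_known_minor(trip, 0.0) == 0.0
        assert loglik_known_minor(trip, 0.5) == pytest.approx(np.log(0.25))

    def test_flat_data_constant_in_p(self):
        trip = np.zeros((5, 3))
        for p in (0.0, 0.17, 0.5, 1.0):
            assert loglik_known_minor(trip, p) == pytest.approx(0.0)

    def test_two_individual_hand_value(self):
        trip = perfect_triplets([0, 1])
        expected = np.log(0.75**2) + np.log(2 * 0.25 * 0.75)
        assert loglik_known_minor(trip, 0.25) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            loglik_known_minor(np.zeros((0, 3)), 0.1)


class TestKnownMinorEstimators:
    def test_perfect_genotypes_exact(self):
        trip = perfect_triplets([0] * 90 + [1] * 10)
        fit = estimate_maf_em(trip)
        assert fit.maf == pytest.approx(0.05, abs=1e-12)
        assert fit.converged
        fit_d = estimate_maf_direct(trip)
        assert fit_d.maf == pytest.approx(0.05, abs=1e-6)

    def test_all_major_boundary(self):
        trip = perfect_triplets([0] * 30)
        fit = estimate_maf_direct(trip)
        assert fit.maf == 0.0
        assert fit.converged

    def test_flat_data_flagged(self):
        res = estimate_maf_em(np.zeros((8, 3)))
        assert not res.converged and np.isnan(res.maf)
        res_d = estimate_maf_direct(np.zeros((8, 3)))
        assert not res_d.converged and np.isnan(res_d.maf)

    def test_em_loglik_monotone(self, rng):
        trip = simulated_triplets(rng, 1, n=80, depth=2.0)[0]
        lin, _ = ml_maf._normalize(trip[np.newaxis])
        p = 0.4
        last = ml_maf._ll_lin(lin, np.array([p]))[0]
        for _ in range(60):
            w = hwe_weights(np.array([p]))[:, np.newaxis, :] * lin
            denom = w.sum(axis=-1)
            post = np.where(denom > 0, (w[..., 1] + 2 * w[..., 2]) / denom, 0.0)
            p = float(post.sum() / (2 * trip.shape[0]))
            ll = ml_maf._ll_lin(lin, np.array([p]))[0]
            assert ll >= last - 1e-10
            last = ll

    def test_em_direct_agreement(self, rng):
        trips = simulated_triplets(rng, 100)
        for trip in trips:
            em = estimate_maf_em(trip, **TIGHT)
            direct = estimate_maf_direct(trip)
            assert em.maf == pytest.approx(direct.maf, abs=1e-4)

    def test_direct_matches_grid_oracle(self, rng):
        trips = simulated_triplets(rng, 15, n=40)
        for trip in trips:
            fit = estimate_maf_direct(trip)
            assert abs(fit.maf - grid_argmax(trip)) <= 5e-4

    def test_initialization_insensitive(self, rng):
        trip = simulated_triplets(rng, 1, n=100, depth=6.0, maf=0.1)[0]
        fits = [estimate_maf_em(trip, p0=p0, **TIGHT).maf for p0 in (0.01, 0.1, 0.4)]
        assert np.ptp(fits) < 1e-4

    def test_simulated_recovery(self, rng):
        err = ErrorMatrix.uniform(0.015)  # 0.005 per direction
        cfg = SimulationConfig(200, 2.0, err)
        _, counts = simulate_sites(0.05, cfg, rng, n_sites=1)
        trip = triplets_from_gl10(gl10_from_counts(counts, err), 0, 1)[0]
        fit = estimate_maf_em(trip)
        assert fit.maf == pytest.approx(0.05, abs=0.03)

    def test_fold_above_half(self):
        # minor-labelled allele is actually the common one
        trip = perfect_triplets([2] * 90 + [1] * 10)
        fit = estimate_maf_em(trip)
        assert fit.minor_swapped
        assert fit.maf == pytest.approx(0.05, abs=1e-9)

    def test_batch_matches_scalar(self, rng):
        trips = simulated_triplets(rng, 30)
        res = estimate_maf_em_batch(trips, tol=1e-10, max_iter=100_000)
        for j in range(30):
            fit = estimate_maf_em(trips[j], **TIGHT)
            assert res["maf"][j] == pytest.approx(fit.maf, abs=1e-12)
            assert res["loglik"][j] == pytest.approx(fit.loglik, abs=1e-9)


class TestUnknownMinor:
    def brute_marginal(self, gl10s, major, p):
        """Linear-space summation oracle for the minor-marginalized likelihood."""
        total = 0.0
        hwe = hwe_weights(p)
        for m in ml_maf.CANDIDATE_MINORS[major]:
            prod = 1.0
            for row in gl10s:
                trip = np.exp(
                    triplets_from_gl10(row[np.newaxis], major, m)[0]
                )
                prod *= float((hwe * trip).sum())
            total += prod / 3.0
        return np.log(total)

    def test_matches_linear_space_oracle(self, rng):
        err = ErrorMatrix.uniform()
        cfg = SimulationConfig(8, 3.0, err)
        for maf in (0.1, 0.4):
            _, counts = simulate_sites(maf, cfg, rng, n_sites=5)
            for c in counts:
                gl10 = gl10_from_counts(c, err)
                for p in (0.0, 0.07, 0.5):
                    got = loglik_unknown_minor(gl10, "A", p)
                    want = self.brute_marginal(gl10, 0, p)
                    assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_p_zero_equals_all_major_likelihood(self, rng):
        err = ErrorMatrix.uniform()
        _, counts = simulate_sites(0.2, SimulationConfig(10, 4.0, err), rng, n_sites=1)
        gl10 = gl10_from_counts(counts[0], err)
        got = loglik_unknown_minor(gl10, "A", 0.0)
        want = float(triplets_from_gl10(gl10, 0, 1)[:, 0].sum())
        assert got == pytest.approx(want, abs=1e-12)

    def test_dominant_candidate_limit(self):
        # only the AC heterozygote explains the data: candidates G and T
        # are ~45 nats behind, so the marginal collapses to l(C) - ln 3
        gl10 = np.full((1, 10), -45.0)
        gl10[0, 1] = 0.0  # AC
        ll = loglik_unknown_minor(gl10, "A", 0.3)
        l_c = loglik_known_minor(triplets_from_gl10(gl10, 0, 1), 0.3)
        assert ll == pytest.approx(l_c - np.log(3.0), abs=1e-12)

    def test_unambiguous_site_matches_known_minor(self, rng):
        err = ErrorMatrix.uniform()
        cfg = SimulationConfig(100, 20.0, err)
        _, counts = simulate_sites(0.25, cfg, rng, n_sites=1)
        gl10 = gl10_from_counts(counts[0], err)
        unknown = estimate_maf_unknown_minor(gl10, "A")
        known = estimate_maf_direct(triplets_from_gl10(gl10, 0, 1))
        assert unknown.maf == pytest.approx(known.maf, abs=1e-3)
        assert unknown.alleles.minor == "C"

    def test_no_minor_reads_boundary(self, err_zero):
        counts = np.tile([6, 0, 0, 0], (20, 1))
        gl10 = gl10_from_counts(counts, err_zero)
        fit = estimate_maf_unknown_minor(gl10, "A")
        assert fit.maf == 0.0

    def test_batch_em_matches_direct(self, rng):
        err = ErrorMatrix.uniform()
        cfg = SimulationConfig(80, 4.0, err)
        _, counts = simulate_sites(0.12, cfg, rng, n_sites=25)
        gl10 = gl10_from_counts(counts, err)
        res = estimate_maf_unknown_minor_batch(gl10, 0, tol=1e-10, max_iter=100_000)
        for j in range(25):
            direct = estimate_maf_unknown_minor(gl10[j], "A")
            assert res["maf"][j] == pytest.approx(direct.maf, abs=2e-4)

    def test_equivariance_under_relabeling(self, rng):
        # permute nucleotide labels consistently in counts and error matrix
        err = ErrorMatrix.from_off_diagonal(
            np.random.default_rng(5).uniform(0.001, 0.01, size=(4, 4))
        )
        cfg = SimulationConfig(60, 4.0, err)
        _, counts = simulate_sites(0.2, cfg, rng, n_sites=1)
        perm = np.array([2, 0, 3, 1])  # new index of old nucleotide
        counts_p = np.zeros_like(counts)
        counts_p[..., perm] = counts
        off_p = np.zeros((4, 4))
        off_p[np.ix_(perm, perm)] = err.rates
        err_p = ErrorMatrix.from_off_diagonal(off_p)
        fit = estimate_maf_unknown_minor(gl10_from_counts(counts[0], err), "A")
        fit_p = estimate_maf_unknown_minor(
            gl10_from_counts(counts_p[0], err_p), NUCLEOTIDES[perm[0]]
        )
        assert fit.maf == pytest.approx(fit_p.maf, abs=1e-9)
        assert fit_p.alleles.minor == NUCLEOTIDES[perm[1]]

    def test_rare_snp_unknown_not_worse_than_known(self, rng):
        """For very rare variants the marginalized estimator should match or
        beat the fixed counts-designated-minor estimator in RMSE."""
        err = ErrorMatrix.uniform()
        cfg = SimulationConfig(1000, 8.0, err)
        p_true = 0.005
        _, counts = simulate_sites(p_true, cfg, rng, n_sites=300)
        gl10_chunks, known, unknown = [], [], []
        from glikfreq.likelihood_core import determine_alleles_from_totals

        major, minor = determine_alleles_from_totals(counts.sum(axis=1))
        for j0 in range(0, 300, 100):
            gl10 = gl10_from_counts(counts[j0 : j0 + 100], err)
            trip = triplets_from_gl10(gl10, major[j0 : j0 + 100], minor[j0 : j0 + 100])
            known.append(estimate_maf_em_batch(trip)["maf"])
            unknown.append(
                estimate_maf_unknown_minor_batch(gl10, major[j0 : j0 + 100])["maf"]
            )
        rmse_known = np.sqrt(np.mean((np.concatenate(known) - p_true) ** 2))
        rmse_unknown = np.sqrt(np.mean((np.concatenate(unknown) - p_true) ** 2))
        assert rmse_unknown <= rmse_known * 1.02
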