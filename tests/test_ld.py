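"""EM haplotype-frequency estimation and the D / D' / r2 statistics."""

import numpy as np
import pytest

from snpld import (
    MISSING,
    HaplotypeFrequencies,
    InsufficientDataError,
    MonomorphicPairError,
    SnpldError,
    compute_D,
    compute_Dmax,
    compute_Dprime,
    compute_r2,
    correct_r2,
    em_haplotype_freqs,
    ld_pair,
    make_panel,
    two_locus_counts,
)
from snpld.ld import (
    _em_iterate,
    _em_starts,
    _gamete_sufficient_stats,
    _loglik_batch,
    em_haplotype_freqs_batch,
    polymorphic_mask,
)

HAND = HaplotypeFrequencies(0.35, 0.25, 0.15, 0.25)  # pA=0.6, pB=0.5, D=0.05


def random_tables(seed, n_tables, n_ind=20):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_tables:
        t = rng.multinomial(n_ind, rng.dirichlet([1.0] * 9)).reshape(3, 3)
        if polymorphic_mask(t.reshape(1, 9))[0]:
            out.append(t)
    return out


def grid_search_pAB(table, resolution=1e-4):
    """Independent likelihood oracle: scan p_AB on a fixed-marginal grid."""
    n9 = np.asarray(table, dtype=float).reshape(1, 9)
    c, ndh, ngam = _gamete_sufficient_stats(n9)
    pA = float((c[0, 0] + c[0, 1] + ndh[0]) / ngam[0])
    pB = float((c[0, 0] + c[0, 2] + ndh[0]) / ngam[0])
    grid = np.arange(max(0.0, pA + pB - 1.0), min(pA, pB) + resolution / 10, resolution)
    ps = np.stack([grid, pA - grid, pB - grid, 1.0 - pA - pB + grid], axis=1)
    lls = _loglik_batch(np.clip(ps, 0, 1), np.repeat(n9, len(grid), axis=0))
    k = int(np.nanargmax(lls))
    return float(grid[k]), float(lls[k])


class TestEmHaplotypeFreqs:
    def test_fully_determined_phase(self):
        counts = np.zeros((3, 3), int)
        counts[2, 2] = 10  # every individual AB/AB
        res = em_haplotype_freqs(counts)
        assert res.freqs.p_AB == pytest.approx(1.0)
        assert res.converged

    def test_no_double_heterozygotes_equals_gamete_counting(self, rng):
        for _ in range(20):
            t = rng.multinomial(25, rng.dirichlet([1.0] * 9)).reshape(3, 3)
            t[1, 1] = 0
            n9 = t.reshape(1, 9).astype(float)
            if not polymorphic_mask(n9)[0]:
                continue
            c, ndh, ngam = _gamete_sufficient_stats(n9)
            res = em_haplotype_freqs(t)
            expected = c[0] / ngam[0]
            np.testing.assert_allclose(
                [res.freqs.p_AB, res.freqs.p_Ab, res.freqs.p_aB, res.freqs.p_ab],
                expected, atol=1e-9,
            )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_attains_grid_search_likelihood(self, seed):
        for t in random_tables(seed, 15):
            res = em_haplotype_freqs(t)
            p_grid, ll_grid = grid_search_pAB(t)
            assert res.loglik >= ll_grid - 1e-6
            assert res.freqs.p_AB == pytest.approx(p_grid, abs=1e-3)

    def test_marginals_equal_observed_frequencies(self):
        for t in random_tables(3, 25):
            n9 = t.reshape(1, 9).astype(float)
            c, ndh, ngam = _gamete_sufficient_stats(n9)
            hf = em_haplotype_freqs(t).freqs
            assert hf.pA == pytest.approx((c[0, 0] + c[0, 1] + ndh[0]) / ngam[0], abs=1e-12)
            assert hf.pB == pytest.approx((c[0, 0] + c[0, 2] + ndh[0]) / ngam[0], abs=1e-12)

    def test_loglik_monotone_across_iterations(self):
        for t in random_tables(4, 10):
            n9 = t.reshape(1, 9).astype(float)
            c, ndh, ngam = _gamete_sufficient_stats(n9)
            for start in _em_starts(c, ndh, ngam):
                p = start
                ll_prev = _loglik_batch(p, n9)[0]
                for _ in range(60):
                    p, _, _ = _em_iterate(p, c, ndh, ngam, tol=0.0, max_iter=1)
                    ll = _loglik_batch(p, n9)[0]
                    assert ll >= ll_prev - 1e-9
                    ll_prev = ll

    def test_batch_equals_scalar(self):
        tables = random_tables(5, 30)
        n9 = np.stack([t.reshape(9) for t in tables]).astype(float)
        pb, convb, llb, _ = em_haplotype_freqs_batch(n9)
        for k, t in enumerate(tables):
            res = em_haplotype_freqs(t)
            np.testing.assert_allclose(
                pb[k], [res.freqs.p_AB, res.freqs.p_Ab, res.freqs.p_aB, res.freqs.p_ab],
                atol=1e-12,
            )
            assert llb[k] == pytest.approx(res.loglik, abs=1e-9)

    def test_empty_table_raises(self):
        with pytest.raises(InsufficientDataError):
            em_haplotype_freqs(np.zeros((3, 3), int))


class TestStatistics:
    def test_D_independence_and_coupling(self):
        assert compute_D(HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)) == 0.0
        assert compute_D(HaplotypeFrequencies(0.5, 0.0, 0.0, 0.5)) == pytest.approx(0.25)

    def test_D_hand_value(self):
        assert compute_D(HAND) == pytest.approx(0.05)

    def test_Dprime_hand_value(self):
        assert compute_Dmax(HAND) == pytest.approx(0.2)
        assert compute_Dprime(HAND) == pytest.approx(0.25)

    def test_Dprime_complete_coupling(self):
        assert compute_Dprime(HaplotypeFrequencies(0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)

    def test_Dprime_zero_convention(self):
        assert compute_Dprime(HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)) == 0.0

    def test_r2_values(self):
        assert compute_r2(HaplotypeFrequencies(0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)
        assert compute_r2(HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)) == 0.0
        assert compute_r2(HAND) == pytest.approx(0.05**2 / (0.6 * 0.4 * 0.5 * 0.5))

    def test_monomorphic_marginal_raises(self):
        with pytest.raises(MonomorphicPairError):
            compute_Dprime(HaplotypeFrequencies(0.5, 0.5, 0.0, 0.0))

    def test_r2_bounded_by_absolute_Dprime(self):
        for t in random_tables(6, 40):
            hf = em_haplotype_freqs(t).freqs
            try:
                r2, dp = compute_r2(hf), compute_Dprime(hf)
            except MonomorphicPairError:
                continue
            assert r2 <= abs(dp) + 1e-9


class TestCorrectR2:
    def test_fixed_point_at_one(self):
        for n in (2, 24, 100):
            assert correct_r2(1.0, n) == pytest.approx(1.0)

    def test_null_expectation_removed(self):
        assert correct_r2(1 / 24, 24) == 0.0

    def test_hand_value(self):
        assert correct_r2(0.5, 24) == pytest.approx((0.5 - 1 / 24) / (1 - 1 / 24))

    def test_floor_and_exact_mode(self):
        assert correct_r2(0.0, 24) == 0.0
        assert correct_r2(0.0, 24, floor=False) == pytest.approx(-1 / 23)

    def test_invalid_n(self):
        with pytest.raises(SnpldError):
            correct_r2(0.5, 1)


class TestLdPair:
    def test_duplicated_locus_gives_r2_one(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        panel = make_panel(np.stack([col, col], axis=1))
        est = ld_pair(panel, 0, 1)
        assert est.r2 == pytest.approx(1.0)
        assert abs(est.Dprime) == pytest.approx(1.0)
        assert est.distance_bp == 10_000
        assert est.n_alleles == 12

    def test_pairing_is_by_sample_not_by_value_order(self):
        # same multiset of genotypes, different arrangement: r2 must differ
        a = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        b = a[::-1].copy()
        aligned = ld_pair(make_panel(np.stack([a, a], axis=1)), 0, 1)
        reversed_ = ld_pair(make_panel(np.stack([a, b], axis=1)), 0, 1)
        assert aligned.r2 == pytest.approx(1.0)
        assert reversed_.D == pytest.approx(-aligned.D)

    def test_missing_reduces_n_alleles(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        b = a.copy()
        b[0] = MISSING
        est = ld_pair(make_panel(np.stack([a, b], axis=1)), 0, 1)
        assert est.n_alleles == 10

    def test_monomorphic_in_complete_subset(self):
        # second locus is monomorphic once the missing row is dropped
        a = np.array([1, 2, 1, 2], dtype=np.int8)
        b = np.array([MISSING, 0, 0, 0], dtype=np.int8)
        with pytest.raises(MonomorphicPairError):
            ld_pair(make_panel(np.stack([a, b], axis=1)), 0, 1)

    def test_insufficient_data(self):
        a = np.array([1, MISSING], dtype=np.int8)
        b = np.array([MISSING, 1], dtype=np.int8)
        with pytest.raises(InsufficientDataError):
            ld_pair(make_panel(np.stack([a, b], axis=1)), 0, 1)

    def test_non_syntenic_pair_rejected(self):
        panel = make_panel(np.ones((4, 2), dtype=np.int8), chrom=["1", "2"])
        with pytest.raises(SnpldError, match="syntenic"):
            ld_pair(panel, 0, 1)


class TestSamplingBehaviour:
    def test_parameter_recovery_moderate_sample(self):
        """Genotypes built by random union of gametes from known haplotype
        frequencies are recovered by EM within sampling error."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.dirichlet([2.0] * 4)
            pA, pB = p[0] + p[1], p[0] + p[2]
            if min(pA, 1 - pA, pB, 1 - pB) < 0.1:
                continue
            n = 1000
            gametes = rng.multinomial(1, p, size=2 * n).argmax(axis=1)
            g1 = (gametes < 2).astype(int).reshape(n, 2).sum(axis=1)
            g2 = ((gametes == 0) | (gametes == 2)).astype(int).reshape(n, 2).sum(axis=1)
            hf = em_haplotype_freqs(two_locus_counts(g1, g2)).freqs
            se = np.sqrt(p[0] * (1 - p[0]) / (2 * n))
            assert abs(hf.p_AB - p[0]) < 5 * se

    def test_linkage_equilibrium_null_level(self):
        """Independent loci: mean r2 is at the ~1/n_individuals chance level
        and corrected r2 is near zero."""
        rng = np.random.default_rng(13)
        n, reps = 2000, 40
        r2s, r2cs = [], []
        for _ in range(reps):
            g1 = rng.binomial(2, 0.3, size=n).astype(np.int8)
            g2 = rng.binomial(2, 0.4, size=n).astype(np.int8)
            est = ld_pair(make_panel(np.stack([g1, g2], axis=1)), 0, 1)
            r2s.append(est.r2)
            r2cs.append(est.r2_corrected)
        assert np.mean(r2s) < 3.0 / n
        assert np.mean(r2cs) < 3.0 / n
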