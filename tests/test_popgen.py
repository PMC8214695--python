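"""Diversity, F_ST, fixed differences, HWE, PCoA and Mantel tests."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from islandrad import (GenotypeMatrix, ValidationError, fixed_differences,
                       heterozygosity_and_fis, hwe_exact, mantel,
                       pairwise_fst, partial_mantel, pcoa,
                       simulate_genotypes)
from islandrad.popgen import PCoA, allele_sharing_distance, hwe_scan


def gm_from(rows, pops, loci=None):
    rows = np.asarray(rows, dtype=np.int8)
    loci = loci or [f"l{j}" for j in range(rows.shape[1])]
    return GenotypeMatrix([f"i{k}" for k in range(rows.shape[0])],
                          pops, loci, rows)


class TestDiversity:
    def test_all_heterozygous_negative_fis(self):
        gm = gm_from([[1], [1], [1], [1]], ["P"] * 4)
        res = heterozygosity_and_fis(gm, "P")
        assert res["H_o"] == pytest.approx(1.0)
        assert res["F_IS"] < 0

    def test_all_homozygous_fis_one(self):
        gm = gm_from([[0], [2], [0], [2]], ["P"] * 4)
        res = heterozygosity_and_fis(gm, "P")
        assert res["H_o"] == 0.0
        assert res["F_IS"] == pytest.approx(1.0)

    def test_hwe_population_fis_near_zero(self):
        gm = simulate_genotypes(n_pops=1, n_per_pop=50, n_loci=200,
                                target_F=0.01, ancestral_freq=(0.3, 0.3),
                                seed=5)
        res = heterozygosity_and_fis(gm, "pop1")
        assert abs(res["F_IS"]) < 0.05

    def test_monomorphic_population_fis_undefined(self):
        gm = gm_from([[0], [0], [0]], ["P"] * 3)
        res = heterozygosity_and_fis(gm, "P")
        assert res["H_e"] == 0.0
        assert math.isnan(res["F_IS"])


def wc_theta_oracle(n1, n2, p1, p2, h1, h2):
    """Literal Weir & Cockerham (1984) theta for two populations, one locus.

    Transcribed independently from the published component formulas.
    """
    r = 2
    nbar = (n1 + n2) / 2
    C2 = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / ((r - 1) * nbar ** 2)
    nc = nbar * (1 - C2 / r)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestFst:
    def test_identical_pops_hudson_zero(self):
        block = [[0], [1], [2], [1]]
        gm = gm_from(block + block, ["P1"] * 4 + ["P2"] * 4)
        _, fst, raw = pairwise_fst(gm, "hudson")
        assert raw[0, 1] <= 0  # unbiased estimator: at or below zero
        assert fst[0, 1] == 0.0

    @pytest.mark.parametrize("estimator", ["weir_cockerham", "hudson"])
    def test_fixed_pops_fst_one(self, estimator):
        gm = gm_from([[0, 0], [0, 0], [2, 2], [2, 2]],
                     ["P1", "P1", "P2", "P2"])
        _, fst, _ = pairwise_fst(gm, estimator)
        assert fst[0, 1] == pytest.approx(1.0)

    def test_weir_cockerham_matches_literal_formula(self):
        # 10 diploids per pop, one locus, p1 = 0.8 (6 hom + 4 het),
        # p2 = 0.2 (mirrored)
        pop1 = [[2]] * 6 + [[1]] * 4
        pop2 = [[0]] * 6 + [[1]] * 4
        gm = gm_from(pop1 + pop2, ["P1"] * 10 + ["P2"] * 10)
        _, _, raw = pairwise_fst(gm, "weir_cockerham")
        expected = wc_theta_oracle(10, 10, 0.8, 0.2, 0.4, 0.4)
        assert raw[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_estimators_agree_on_balanced_simulation(self):
        gm = simulate_genotypes(n_pops=2, n_per_pop=50, n_loci=2000,
                                target_F=0.15, seed=13)
        _, wc, _ = pairwise_fst(gm, "weir_cockerham")
        _, hu, _ = pairwise_fst(gm, "hudson")
        assert abs(wc[0, 1] - hu[0, 1]) < 0.02

    def test_balding_nichols_target_recovered(self):
        vals = []
        for rep in range(6):
            gm = simulate_genotypes(n_pops=2, n_per_pop=50, n_loci=500,
                                    target_F=0.3, seed=40 + rep)
            _, fst, _ = pairwise_fst(gm, "hudson")
            vals.append(fst[0, 1])
        assert abs(np.mean(vals) - 0.3) < 0.03


class TestFixedDifferences:
    def test_opposite_homozygotes_fixed(self):
        gm = gm_from([[0], [0], [2], [2]], ["A", "A", "B", "B"])
        assert fixed_differences(gm, "A", "B")["count"] == 1

    def test_heterozygote_shares_both_alleles(self):
        gm = gm_from([[0], [0], [1], [2]], ["A", "A", "B", "B"])
        assert fixed_differences(gm, "A", "B")["count"] == 0

    def test_missing_ignored(self):
        gm = gm_from([[0], [0], [2], [-1]], ["A", "A", "B", "B"])
        assert fixed_differences(gm, "A", "B")["count"] == 1

    def test_symmetric_in_populations(self):
        gm = simulate_genotypes(n_pops=2, n_per_pop=10, n_loci=300,
                                target_F=0.5, missing_rate=0.05, seed=3)
        a = fixed_differences(gm, "pop1", "pop2")
        b = fixed_differences(gm, "pop2", "pop1")
        assert a == b


class TestHWE:
    def test_monomorphic_p_one(self):
        assert hwe_exact(5, 0, 0) == 1.0

    def test_matches_full_enumeration(self):
        # 4 diploids, 4 A and 4 a alleles: heterozygote counts {0, 2, 4}
        # P(h) ~ n! / (nAA! nAa! naa!) * 2^h; enumerate directly
        def prob(h):
            aa = (4 - h) // 2
            return (math.factorial(4)
                    / (math.factorial(aa) * math.factorial(h)
                       * math.factorial(aa)) * 2 ** h)

        probs = {h: prob(h) for h in (0, 2, 4)}
        tot = sum(probs.values())
        p_obs = probs[0] / tot
        expected = sum(p / tot for p in probs.values()
                       if p / tot <= p_obs + 1e-12)
        assert hwe_exact(2, 0, 2) == pytest.approx(expected, abs=1e-12)

    def test_null_rejection_rate_conservative(self):
        rng = np.random.default_rng(17)
        rej = 0
        m = 2000
        for _ in range(m):
            p = rng.uniform(0.1, 0.9)
            g = rng.binomial(2, p, size=40)
            pv = hwe_exact(int((g == 0).sum()), int((g == 1).sum()),
                           int((g == 2).sum()))
            rej += pv < 0.05
        assert rej / m <= 0.06

    def test_scan_bonferroni_and_multi_population_flags(self):
        rng = np.random.default_rng(23)
        # loci 0: extreme heterozygote excess in both pops; others neutral
        neutral = rng.binomial(2, 0.5, size=(60, 49)).astype(np.int8)
        bad = np.ones((60, 1), dtype=np.int8)
        gm = gm_from(np.hstack([bad, neutral]),
                     ["P1"] * 30 + ["P2"] * 30)
        res = hwe_scan(gm, alpha=0.05)
        assert res["P1"]["m_tests"] <= 50
        assert 0 in res["P1"]["significant"]
        assert res["multi_population_violations"] == [0]


class TestPCoA:
    def test_collinear_points_single_axis(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        fit = pcoa(D)
        assert fit.percent_variance_[0] == pytest.approx(100.0)

    def test_unit_square_two_equal_axes(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        D = squareform(pdist(pts))
        fit = pcoa(D)
        assert fit.percent_variance_[0] == pytest.approx(50.0)
        assert fit.percent_variance_[1] == pytest.approx(50.0)

    def test_euclidean_distances_recovered_exactly(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 4))
        D = squareform(pdist(pts))
        fit = pcoa(D)
        Dhat = squareform(pdist(fit.coords_))
        np.testing.assert_allclose(Dhat, D, atol=1e-9)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(15, 5))
        fit = pcoa(squareform(pdist(pts)))
        assert fit.percent_variance_.sum() == pytest.approx(100.0, abs=1e-9)

    def test_matches_scikit_bio(self):
        import skbio

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        ours = pcoa(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D), method="eigh")
        lam_theirs = np.sort(theirs.eigvals.values)[::-1]
        lam_ours = ours.eigenvalues_[: len(lam_theirs)]
        np.testing.assert_allclose(lam_ours[:3], lam_theirs[:3], atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            PCoA().fit(np.array([[0, 1.0], [2.0, 0]]))

    def test_sklearn_get_params_roundtrip(self):
        est = PCoA(n_components=3)
        assert PCoA(**est.get_params()).n_components == 3


class TestMantel:
    def _dist(self, rng, n=15):
        return squareform(pdist(rng.random((n, 2))))

    def test_identity_maximal(self):
        rng = np.random.default_rng(1)
        D = self._dist(rng)
        r, p = mantel(D, D.copy(), permutations=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_agrees_with_scikit_bio(self):
        import skbio

        rng = np.random.default_rng(7)
        A = self._dist(rng)
        B = A + rng.normal(0, 0.1, A.shape)
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        B = np.abs(B)
        r_ours, _ = mantel(A, B, permutations=99, seed=0)
        r_skbio, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(A), skbio.DistanceMatrix(B),
            permutations=0)
        assert r_ours == pytest.approx(r_skbio, abs=1e-10)

    def test_constant_matrix_rejected(self):
        D = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValidationError):
            mantel(D, D * 0.0 + (1 - np.eye(5)), permutations=99, seed=0)

    def test_partial_mantel_removes_confounder(self):
        rng = np.random.default_rng(11)
        dz = self._dist(rng, 50)
        noise = rng.normal(0, 0.05, dz.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        dx = np.abs(dz + noise)
        # dx is dz plus noise; after removing dz, correlation with dz ~ 0
        r, _ = partial_mantel(dx, dz.copy(), dz, permutations=99, seed=1)
        assert abs(r) < 0.1

    def test_partial_mantel_keeps_independent_signal(self):
        rng = np.random.default_rng(12)
        pts = rng.random((25, 2))
        dx = squareform(pdist(pts))
        dy = dx + rng.normal(0, 0.02, dx.shape)
        dy = np.abs((dy + dy.T) / 2)
        np.fill_diagonal(dy, 0)
        dz = self._dist(rng, 25)  # unrelated covariate
        r, p = partial_mantel(dx, dy, dz, permutations=199, seed=2)
        assert r > 0.8
        assert p < 0.05


def test_allele_sharing_distance_bounds():
    gm = simulate_genotypes(n_pops=2, n_per_pop=8, n_loci=100,
                            target_F=0.4, missing_rate=0.02, seed=6)
    D = allele_sharing_distance(gm)
    assert np.all(D >= 0) and np.all(D <= 1)
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)


def test_linearized_fst_transform():
    from islandrad import linearized_fst
    fst = np.array([[0.0, 0.2], [0.2, 0.0]])
    lin = linearized_fst(fst)
    assert lin[0, 1] == pytest.approx(0.25)
    assert lin[0, 0] == 0.0
    assert math.isinf(linearized_fst(np.array([[0.0, 1.0],
                                               [1.0, 0.0]]))[0, 1])
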