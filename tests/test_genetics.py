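"""Spatial genetic autocorrelation: metric, r, lr, heterogeneity, Mantel.

Brute-force double-loop oracles recompute every matrix-path statistic from
scratch on small fixtures; the two routes must agree to 1e-12.
"""

import numpy as np
import pandas as pd
import pytest

from raydisp import genetics as gen
from raydisp import synthetic as syn


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------

def brute_locus_distance(ga, gb):
    """Squared single-locus distance from the allele-count definition."""
    alleles = sorted(set(ga) | set(gb))
    ca = np.array([ga.count(a) for a in alleles], float)
    cb = np.array([gb.count(a) for a in alleles], float)
    return 0.5 * ((ca - cb) ** 2).sum()


def brute_distance_matrix(alleles):
    n, L, _ = alleles.shape
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            tot, shared = 0.0, 0
            for k in range(L):
                gi = list(alleles[i, k])
                gj = list(alleles[j, k])
                if 0 in gi or 0 in gj:
                    continue
                tot += brute_locus_distance(gi, gj)
                shared += 1
            D[i, j] = tot * L / shared if shared else np.nan
    np.fill_diagonal(D, 0.0)
    return D


def brute_center(D):
    n = D.shape[0]
    C = np.zeros_like(D)
    rm = D.mean(axis=1)
    cm = D.mean(axis=0)
    gm = D.mean()
    for i in range(n):
        for j in range(n):
            C[i, j] = -0.5 * (D[i, j] - rm[i] - cm[j] + gm)
    return C


def brute_r(D, geo, lower, upper, include_lower):
    C = brute_center(D)
    num = den = 0.0
    n = D.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            d = geo[i, j]
            inside = (d >= lower if include_lower else d > lower) and d <= upper
            if inside:
                num += C[i, j]
                den += 0.5 * (C[i, i] + C[j, j])
    return num / den


def brute_lr(D, geo, ids, n_neighbors):
    C = brute_center(D)
    n = D.shape[0]
    rank = np.argsort(np.argsort(ids))
    out = np.zeros(n)
    for i in range(n):
        order = sorted([j for j in range(n) if j != i],
                       key=lambda j: (geo[i, j], rank[j]))
        nb = order[:n_neighbors]
        num = sum(C[i, j] for j in nb)
        den = sum(0.5 * (C[i, i] + C[j, j]) for j in nb)
        out[i] = num / den
    return out


def brute_mantel_r(A, B):
    a, b = [], []
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a.append(A[i, j])
            b.append(B[i, j])
    return float(np.corrcoef(a, b)[0, 1])


@pytest.fixture(scope="module")
def fixture_matrix(unrelated_genotypes):
    table, coords = unrelated_genotypes
    return gen.genotype_matrix_from_tables(table, coords)


# --------------------------------------------------------------------------
# squared genetic distance
# --------------------------------------------------------------------------

class TestSquaredDistance:
    def test_identical_genotypes_zero(self, fixture_matrix):
        g = fixture_matrix.subset([0, 0])
        D = gen.squared_genetic_distance(g)
        assert D.values[0, 1] == 0.0

    @pytest.mark.parametrize("ga,gb,expected", [
        ((100, 100), (100, 100), 0),
        ((100, 100), (100, 102), 1),
        ((100, 102), (100, 102), 0),
        ((100, 100), (102, 102), 4),
        ((100, 100), (102, 104), 3),
        ((100, 102), (100, 104), 1),
        ((100, 102), (104, 106), 2),
    ])
    def test_single_locus_metric_table(self, ga, gb, expected):
        """All diploid configurations against the published metric values."""
        assert brute_locus_distance(list(ga), list(gb)) == expected
        g = gen.GenotypeMatrix(
            ids=np.array(["a", "b"]), sex=np.array(["F", "F"]),
            coords=np.zeros((2, 2)), loci=["L1"],
            alleles=np.array([[ga], [gb]]),
        )
        D = gen.squared_genetic_distance(g)
        assert D.values[0, 1] == expected

    def test_one_divergent_locus_dominates(self):
        # identical at four loci, AA vs BB at the fifth: distance = 4
        a = [[(100, 100)] * 4 + [(200, 200)]]
        b = [[(100, 100)] * 4 + [(202, 202)]]
        g = gen.GenotypeMatrix(
            ids=np.array(["a", "b"]), sex=np.array(["F", "F"]),
            coords=np.zeros((2, 2)), loci=[f"L{i}" for i in range(5)],
            alleles=np.array(a + b),
        )
        assert gen.squared_genetic_distance(g).values[0, 1] == 4.0

    def test_matrix_equals_bruteforce(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        expected = brute_distance_matrix(fixture_matrix.alleles)
        np.testing.assert_allclose(D.values, expected, atol=1e-12)

    def test_missing_data_rescaled(self):
        alleles = np.array([
            [(100, 100), (200, 202)],
            [(100, 102), (0, 0)],
        ])
        g = gen.GenotypeMatrix(
            ids=np.array(["a", "b"]), sex=np.array(["F", "F"]),
            coords=np.zeros((2, 2)), loci=["L1", "L2"], alleles=alleles,
        )
        D = gen.squared_genetic_distance(g)
        # one shared locus with d2=1, rescaled by 2/1
        assert D.values[0, 1] == 2.0
        assert D.loci_used[0, 1] == 1

    def test_invariance_to_allele_relabeling_and_locus_order(self, fixture_matrix):
        g = fixture_matrix
        D0 = gen.squared_genetic_distance(g).values
        relab = g.alleles.copy()
        relab[relab > 0] = relab[relab > 0] * 3 + 7  # injective relabeling
        g2 = gen.GenotypeMatrix(g.ids, g.sex, g.coords, list(g.loci), relab)
        np.testing.assert_allclose(gen.squared_genetic_distance(g2).values, D0,
                                   atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(g.loci))
        g3 = gen.GenotypeMatrix(g.ids, g.sex, g.coords,
                                [g.loci[k] for k in perm],
                                g.alleles[:, perm, :])
        np.testing.assert_allclose(gen.squared_genetic_distance(g3).values, D0,
                                   atol=1e-12)


# --------------------------------------------------------------------------
# autocorrelation r
# --------------------------------------------------------------------------

class TestAutocorrelation:
    def test_gower_centering_row_sums_zero(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix).values
        C = gen.gower_center(D)
        np.testing.assert_allclose(C.sum(axis=1), 0.0, atol=1e-9)

    def test_matrix_r_equals_bruteforce(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        geo = gen.geographic_distances(fixture_matrix.coords)
        bounds = [150, 300, 450, 700]
        res = gen.autocorr_r_by_class(D, geo, bounds)
        lower = 0.0
        for h, c in enumerate(res):
            expected = brute_r(D.values, geo, lower, bounds[h], h == 0)
            assert c.r == pytest.approx(expected, abs=1e-12)
            lower = bounds[h]

    def test_clustered_clones_positive_within_cluster(self):
        # two spatial clusters of clones: within-cluster r is maximal
        base = np.array([[(100, 102)] * 3, [(104, 106)] * 3])
        alleles = np.array([base[0], base[0], base[0],
                            base[1], base[1], base[1]])
        coords = np.array([[0, 0], [1, 0], [0, 1],
                           [100, 100], [101, 100], [100, 101]], float)
        g = gen.GenotypeMatrix(
            ids=np.array([f"i{k}" for k in range(6)]),
            sex=np.array(["F"] * 6), coords=coords,
            loci=["L1", "L2", "L3"], alleles=alleles,
        )
        D = gen.squared_genetic_distance(g)
        geo = gen.geographic_distances(coords)
        res = gen.autocorr_r_by_class(D, geo, [10, 200])
        assert res[0].r == pytest.approx(1.0)
        assert res[1].r < 0

    def test_all_identical_genotypes_flagged(self):
        alleles = np.array([[(100, 102)]] * 4)
        g = gen.GenotypeMatrix(
            ids=np.array(list("abcd")), sex=np.array(["F"] * 4),
            coords=np.arange(8, dtype=float).reshape(4, 2),
            loci=["L1"], alleles=alleles,
        )
        D = gen.squared_genetic_distance(g)
        geo = gen.geographic_distances(g.coords)
        res = gen.autocorr_r_by_class(D, geo, [100])
        assert np.isnan(res[0].r)
        assert "degenerate: zero denominator" in res[0].flags

    def test_empty_class_reported_missing(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        geo = gen.geographic_distances(fixture_matrix.coords)
        res = gen.autocorr_r_by_class(D, geo, [900, 10_000])
        assert res[1].n_pairs == 0 and np.isnan(res[1].r)

    def test_permutation_null_mean_matches_randomized_data(self, fixture_matrix):
        # randomly rearranged genotypes: observed r behaves like a draw from
        # the permutation distribution (mean within a few permutation SEs)
        D = gen.squared_genetic_distance(fixture_matrix)
        geo = gen.geographic_distances(fixture_matrix.coords)
        C = gen.gower_center(D.values)
        ii, jj = gen._pair_indices(geo, 0, 200, True)
        lo, hi, rp = gen.permutation_envelope_r(C, ii, jj, n_perm=1000, seed=4)
        robs = gen._r_from_pairs(C, ii, jj)
        # fixture genotypes are unrelated founders: already a null draw
        assert lo - 0.05 < robs < hi + 0.05
        assert lo <= rp.mean() <= hi


class TestMultiDclass:
    def test_final_bound_equals_global_r(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        geo = gen.geographic_distances(fixture_matrix.coords)
        umax = geo.max() + 1
        res = gen.multi_dclass(D, geo, [200, umax], n_boot=19, n_perm=19, seed=0)
        expected = brute_r(D.values, geo, 0, umax, False)
        assert res[1].r == pytest.approx(expected, abs=1e-12)
        n = len(fixture_matrix)
        assert res[1].n_pairs == n * (n - 1) // 2

    def test_nonincreasing_bounds_rejected(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        geo = gen.geographic_distances(fixture_matrix.coords)
        with pytest.raises(ValueError):
            gen.multi_dclass(D, geo, [300, 200])


class TestResampling:
    def test_constant_contribution_class_zero_width_ci(self):
        C = np.eye(4)  # c_ij = 0 off-diagonal, c_ii = 1: r* identically 0
        ii = np.array([0, 1, 2])
        jj = np.array([1, 2, 3])
        lo, hi = gen.bootstrap_ci_r(C, ii, jj, n_boot=200, seed=0)
        assert lo == hi == 0.0

    def test_single_pair_degenerate_ci(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        C = gen.gower_center(D.values)
        lo, hi = gen.bootstrap_ci_r(C, np.array([0]), np.array([1]), seed=1)
        assert lo == hi

    def test_envelope_contains_permutation_mean(self, fixture_matrix):
        D = gen.squared_genetic_distance(fixture_matrix)
        geo = gen.geographic_distances(fixture_matrix.coords)
        C = gen.gower_center(D.values)
        ii, jj = gen._pair_indices(geo, 0, 300, True)
        lo, hi, rp = gen.permutation_envelope_r(C, ii, jj, n_perm=300, seed=2)
        assert lo <= rp.mean() <= hi

    def test_envelope_narrows_with_sample_size(self, allele_freqs):
        widths = {}
        for n in (50, 200):
            ped = pd.DataFrame({
                "individual_id": [f"i{k:04d}" for k in range(n)],
                "sex": ["F"] * n, "birth_year": [None] * n,
                "natal_box": [None] * n, "mother_id": [None] * n,
                "father_id": [None] * n,
            })
            table = syn.simulate_genotypes(ped, allele_freqs, seed=n)
            rng = np.random.default_rng(n)
            coords = pd.DataFrame({
                "individual_id": table["individual_id"], "sex": "F",
                "x_m": rng.uniform(0, 500, n), "y_m": rng.uniform(0, 500, n),
            })
            g = gen.genotype_matrix_from_tables(table, coords)
            D = gen.squared_genetic_distance(g)
            geo = gen.geographic_distances(g.coords)
            C = gen.gower_center(D.values)
            ii, jj = gen._pair_indices(geo, 0, 250, True)
            lo, hi, _ = gen.permutation_envelope_r(C, ii, jj, n_perm=300, seed=3)
            widths[n] = hi - lo
        assert widths[200] < widths[50]

    def test_dual_rule_requires_both_criteria(self):
        res = gen.DistanceClassResult("0-100", 0, 100, 10, 0.05,
                                      0.01, 0.09, -0.02, 0.08, False)
        ci_excludes0 = res.ci_lower > 0 or res.ci_upper < 0
        outside = res.r > res.perm_upper or res.r < res.perm_lower
        assert ci_excludes0 and not outside  # envelope criterion fails alone
        res2 = gen.DistanceClassResult("0-100", 0, 100, 10, 0.05,
                                       -0.01, 0.09, -0.02, 0.03, False)
        ci2 = res2.ci_lower > 0 or res2.ci_upper < 0
        out2 = res2.r > res2.perm_upper or res2.r < res2.perm_lower
        assert out2 and not ci2  # CI criterion fails alone


# --------------------------------------------------------------------------
# heterogeneity, lr, Mantel
# --------------------------------------------------------------------------

class TestHeterogeneity:
    def test_identical_groups_zero_statistics(self, fixture_matrix):
        g = fixture_matrix
        het = gen.heterogeneity_tests(g, g, [200, 400, 900], n_perm=49, seed=0)
        assert np.allclose(het.t2[np.isfinite(het.t2)], 0.0, atol=1e-12)
        assert het.omega == pytest.approx(0.0, abs=1e-12)

    def test_structured_vs_unstructured_first_class(self, allele_freqs):
        """Male-structured vs female-random data: the first distance class
        carries the heterogeneity signal more often than later classes."""
        first, later = 0, 0
        for seed in range(8):
            sim = syn.simulate_site("fray_jorge", seed=seed)
            from raydisp.io import breeding_adult_coordinates

            coords = breeding_adult_coordinates(sim["captures"], sim["boxes"],
                                                years=range(3, 9))
            g = gen.genotype_matrix_from_tables(sim["genotypes"], coords)
            het = gen.heterogeneity_tests(
                g.subset(g.sex == "M"), g.subset(g.sex == "F"),
                [150, 300, 450, 600], n_perm=99, seed=seed,
            )
            ps = het.t2_p
            if np.isfinite(ps[0]) and ps[0] <= 0.05:
                first += 1
            later += int(np.nansum(ps[2:] <= 0.05))
        assert first >= later


class TestLocalAutocorrelation:
    def test_lr_equals_bruteforce(self, fixture_matrix):
        g = fixture_matrix
        res = gen.local_autocorr_2d(g, n_neighbors=8, n_perm=19, seed=0)
        expected = brute_lr(
            gen.squared_genetic_distance(g).values,
            gen.geographic_distances(g.coords), g.ids, 8,
        )
        np.testing.assert_allclose(res["lr"].to_numpy(), expected, atol=1e-12)

    def test_neighbors_exclude_self_and_count(self, fixture_matrix):
        res = gen.local_autocorr_2d(fixture_matrix, n_neighbors=5, n_perm=9,
                                    seed=0)
        for ind, nbrs in zip(res["individual_id"], res["neighbors"]):
            ids = nbrs.split(",")
            assert len(ids) == 5 and ind not in ids

    def test_clone_cluster_gets_largest_lr(self, allele_freqs):
        # a clique of clones embedded in a random background
        n = 40
        ped = pd.DataFrame({
            "individual_id": [f"i{k:03d}" for k in range(n)],
            "sex": ["F"] * n, "birth_year": [None] * n, "natal_box": [None] * n,
            "mother_id": [None] * n, "father_id": [None] * n,
        })
        table = syn.simulate_genotypes(ped, allele_freqs, seed=5)
        clone_cols = [c for c in table.columns if c != "individual_id"]
        table.loc[:4, clone_cols] = table.loc[0, clone_cols].to_numpy()
        rng = np.random.default_rng(6)
        coords = pd.DataFrame({
            "individual_id": table["individual_id"], "sex": "F",
            "x_m": np.r_[rng.uniform(0, 10, 5), rng.uniform(200, 800, n - 5)],
            "y_m": np.r_[rng.uniform(0, 10, 5), rng.uniform(200, 800, n - 5)],
        })
        g = gen.genotype_matrix_from_tables(table, coords)
        res = gen.local_autocorr_2d(g, n_neighbors=4, n_perm=99, seed=7)
        top5 = set(res.nlargest(5, "lr")["individual_id"])
        assert top5 == {f"i{k:03d}" for k in range(5)}
        assert (res["p_value"][:5] <= 0.05).all()

    def test_null_rejection_rate(self, fixture_matrix):
        res = gen.local_autocorr_2d(fixture_matrix, n_neighbors=10,
                                    n_perm=199, seed=8)
        assert (res["p_value"] <= 0.05).mean() <= 0.15

    def test_needs_more_individuals_than_neighbors(self, fixture_matrix):
        with pytest.raises(ValueError):
            gen.local_autocorr_2d(fixture_matrix.subset(range(5)), n_neighbors=5)


class TestMantel:
    def test_self_correlation_one(self, fixture_matrix):
        geo = gen.geographic_distances(fixture_matrix.coords)
        res = gen.mantel_test(geo, geo, n_perm=99, seed=0)
        assert res.r_xy == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance(self, fixture_matrix):
        geo = gen.geographic_distances(fixture_matrix.coords)
        res = gen.mantel_test(geo, 3.0 * geo, n_perm=49, seed=1)
        assert res.r_xy == pytest.approx(1.0)

    def test_statistic_equals_bruteforce(self, fixture_matrix):
        D = np.nan_to_num(gen.squared_genetic_distance(fixture_matrix).values)
        geo = gen.geographic_distances(fixture_matrix.coords)
        res = gen.mantel_test(D, geo, n_perm=9, seed=2)
        assert res.r_xy == pytest.approx(brute_mantel_r(D, geo), abs=1e-12)

    def test_constant_matrix_rejected(self):
        M = np.zeros((5, 5))
        with pytest.raises(ValueError, match="constant|symmetric"):
            gen.mantel_test(M, M + 1 - np.eye(5), n_perm=9)

    def test_asymmetric_matrix_rejected(self):
        A = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ValueError):
            gen.mantel_test(A, A, n_perm=9)
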