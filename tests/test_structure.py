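"""LD pruning, Weir-Cockerham FST, PCA, admixture and Evanno delta-K."""

import numpy as np
import pytest

from skyisland import (admixture_fit, evanno_delta_k, evanno_from_stats,
                       fst_by_stratum, ld_prune, pca, wc_fst)
from skyisland.structure import AdmixtureModel, _admixture_lnl

from conftest import make_matrix

# ---------------------------------------------------------------------------
# independent Weir-Cockerham oracle: scalar arithmetic, one site at a time


def _wc_oracle_site(g1, g2):
    """Per-site variance components from the published definitions."""
    r = 2
    n1, n2 = len(g1), len(g2)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    h1 = sum(1 for x in g1 if x == 1) / n1
    h2 = sum(1 for x in g2 if x == 1) / n2
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _wc_oracle_theta(g1_mat, g2_mat):
    num = den = 0.0
    for g1, g2 in zip(g1_mat, g2_mat):
        pooled = sum(g1) + sum(g2)
        if pooled == 0 or pooled == 2 * (len(g1) + len(g2)):
            continue
        a, b, c = _wc_oracle_site(list(g1), list(g2))
        num += a
        den += a + b + c
    return num / den


class TestWcFst:
    def test_fixed_alternate_alleles_give_theta_one(self):
        g = np.array([[0, 0, 2, 2]] * 5)
        geno = make_matrix(g, populations=["A", "A", "B", "B"])
        assert wc_fst(geno, ("A", "B")).theta == pytest.approx(1.0)

    def test_identical_count_tables_give_theta_near_zero(self):
        g = np.array([[0, 1, 2, 0, 1, 2]] * 20)
        geno = make_matrix(g, populations=["A"] * 3 + ["B"] * 3)
        theta = wc_fst(geno, ("A", "B")).theta
        assert theta <= 0.0  # slightly negative is expected

    def test_matches_component_oracle_on_random_small_instances(self):
        """200 random 2x(3..6)-diploid instances, agreement to 1e-8."""
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n1, n2 = rng.integers(3, 7, size=2)
            m = int(rng.integers(5, 30))
            g = rng.integers(0, 3, size=(m, n1 + n2)).astype(np.int8)
            geno = make_matrix(g, populations=["A"] * n1 + ["B"] * n2)
            res = wc_fst(geno, ("A", "B"))
            if res.n_sites_used == 0:
                continue
            oracle = _wc_oracle_theta(g[:, :n1], g[:, n1:])
            assert res.theta == pytest.approx(oracle, abs=1e-8)

    def test_panmictic_split_converges_to_zero(self, panmictic_large):
        geno = panmictic_large
        labels = ["A"] * 10 + ["B"] * 10
        geno2 = make_matrix(geno.genotypes, populations=labels)
        assert abs(wc_fst(geno2, ("A", "B")).theta) < 0.01

    def test_monomorphic_sites_excluded_and_counted(self):
        g = np.array([[0, 0, 0, 0], [0, 1, 2, 1], [2, 2, 2, 2]])
        geno = make_matrix(g, populations=["A", "A", "B", "B"])
        res = wc_fst(geno, ("A", "B"))
        assert res.n_sites_used == 1
        assert res.n_sites_excluded == 2


class TestFstByStratum:
    def test_strata_equal_to_populations_match_wc_fst(self, divergent_pair):
        geno, _ = divergent_pair
        table = fst_by_stratum(geno, geno.populations)
        assert table.loc[0, "theta"] == pytest.approx(wc_fst(geno).theta)

    def test_three_strata_match_oracle(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(40, 9)).astype(np.int8)
        strata = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        table = fst_by_stratum(make_matrix(g, populations=strata), strata)
        cols = {"x": slice(0, 3), "y": slice(3, 6), "z": slice(6, 9)}
        for row in table.itertuples():
            oracle = _wc_oracle_theta(g[:, cols[row.stratum_a]], g[:, cols[row.stratum_b]])
            assert row.theta == pytest.approx(oracle, abs=1e-8)

    def test_undersized_stratum_reported_undefined(self):
        g = np.zeros((5, 5), dtype=np.int8)
        g[:, 0] = 1
        strata = ["a", "a", "b", "b", "c"]
        table = fst_by_stratum(make_matrix(g, populations=strata), strata)
        assert np.isnan(table.set_index(["stratum_a", "stratum_b"])
                        .loc[("a", "c"), "theta"])

    def test_single_stratum_warns_and_returns_empty(self):
        g = np.zeros((3, 4), dtype=np.int8)
        with pytest.warns(UserWarning, match="fewer than two strata"):
            table = fst_by_stratum(make_matrix(g), ["a"] * 4)
        assert table.empty


class TestLdPrune:
    def test_identical_columns_second_removed(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        g[1] = g[0]
        kept = ld_prune(make_matrix(g))
        assert 0 in kept and 1 not in kept

    def test_uncorrelated_sites_all_retained(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(5, 12)).astype(np.int8)
        r2 = np.corrcoef(g) ** 2
        assert np.all(r2[np.triu_indices(5, 1)] < 0.5)  # fixture precondition
        assert list(ld_prune(make_matrix(g))) == [0, 1, 2, 3, 4]

    def test_monomorphic_sites_retained(self):
        g = np.array([[1, 1, 1, 1], [0, 1, 2, 1]], dtype=np.int8)
        assert list(ld_prune(make_matrix(g))) == [0, 1]

    def test_ten_site_instance_matches_greedy_oracle(self):
        rng = np.random.default_rng(99)
        base = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        noise = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        g = np.vstack([base, (base[:2] + noise[:2]) % 3, noise[2:]])[:10]
        kept = ld_prune(make_matrix(g), window_sites=10, step_sites=5,
                        r2_threshold=0.5)
        # independent greedy enumeration on the full 10x10 r^2 matrix
        with np.errstate(invalid="ignore"):
            r2 = np.nan_to_num(np.corrcoef(g.astype(float))) ** 2
        removed = set()
        for i in range(10):
            if i in removed:
                continue
            for j in range(i + 1, 10):
                if j not in removed and r2[i, j] > 0.5:
                    removed.add(j)
        assert list(kept) == [i for i in range(10) if i not in removed]

    def test_no_retained_pair_within_processed_window_exceeds_threshold(self, divergent_pair):
        """Windows are defined over original site indices (the sliding
        100-site frames actually processed), mirroring the pruner."""
        geno, _ = divergent_pair
        kept = ld_prune(geno, window_sites=50, step_sites=5, r2_threshold=0.5)
        kept_set = np.asarray(kept)
        with np.errstate(invalid="ignore"):
            for start in range(0, geno.n_sites - 50, 85):
                inside = kept_set[(kept_set >= start) & (kept_set < start + 50)]
                if len(inside) < 2:
                    continue
                r2 = np.nan_to_num(np.corrcoef(geno.genotypes[inside].astype(float))) ** 2
                np.fill_diagonal(r2, 0.0)
                assert r2.max() <= 0.5 + 1e-12


class TestPca:
    def test_separated_populations_split_on_leading_axis(self, divergent_pair):
        geno, _ = divergent_pair
        res = pca(geno)
        a = res.coords[:10, 0]
        b = res.coords[10:, 0]
        assert a.max() < b.min() or b.max() < a.min()
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_identical_samples_have_zero_variance(self):
        g = np.ones((10, 4), dtype=np.int8)
        res = pca(make_matrix(g))
        assert np.allclose(res.variance_explained, 0.0)

    def test_duplicated_samples_get_identical_coordinates(self, divergent_pair):
        geno, _ = divergent_pair
        g = np.repeat(geno.genotypes[:500], 2, axis=1)
        pops = np.repeat(geno.populations, 2)
        res = pca(make_matrix(g, populations=list(pops)))
        assert np.allclose(res.coords[0::2], res.coords[1::2], atol=1e-8)

    def test_axis_sign_deterministic(self, divergent_pair):
        geno, _ = divergent_pair
        c1 = pca(geno).coords
        c2 = pca(geno).coords
        assert np.array_equal(c1, c2)


class TestAdmixture:
    def test_k1_equals_closed_form_binomial_loglik(self, divergent_pair):
        geno, _ = divergent_pair
        fit = admixture_fit(geno, 1, seed=1)
        g = geno.genotypes.T.astype(float)
        p = np.clip(g.mean(axis=0) / 2, 1e-9, 1 - 1e-9)
        closed = (g * np.log(p) + (2 - g) * np.log(1 - p)).sum()
        assert fit.lnl == pytest.approx(closed, rel=1e-12)

    def test_loglik_monotone_non_decreasing(self, divergent_pair):
        geno, _ = divergent_pair
        fit = admixture_fit(geno, 3, seed=2, max_iter=120)
        assert np.all(np.diff(fit.lnl_path) > -1e-6)

    def test_two_populations_assigned_to_their_source(self, divergent_pair):
        geno, _ = divergent_pair
        fit = admixture_fit(geno.take_sites(np.arange(2000)), 2, seed=3)
        assert np.all(fit.q.max(axis=1) > 0.9)
        assert np.allclose(fit.q.sum(axis=1), 1.0, atol=1e-6)
        lead = fit.q.argmax(axis=1)
        assert len(set(lead[:10])) == 1 and lead[0] != lead[10]

    def test_cluster_label_permutation_leaves_loglik_unchanged(self, divergent_pair):
        geno, _ = divergent_pair
        fit = admixture_fit(geno.take_sites(np.arange(500)), 2, seed=4)
        g = geno.genotypes[:500].T.astype(float)
        assert _admixture_lnl(g, fit.q[:, ::-1], fit.p[::-1]) == \
            pytest.approx(fit.lnl, rel=1e-12)

    def test_k_exceeding_samples_rejected(self, divergent_pair):
        geno, _ = divergent_pair
        with pytest.raises(ValueError, match="exceeds sample count"):
            AdmixtureModel(n_clusters=100).fit(geno)


class TestEvanno:
    def test_worked_table(self):
        table = evanno_from_stats([1, 2, 3, 4], [-1000, -800, -790, -788],
                                  [5, 5, 5, 5])
        assert table.delta_k[1] == pytest.approx(38.0)
        assert table.delta_k[2] == pytest.approx(1.6)
        assert np.isnan(table.delta_k[0]) and np.isnan(table.delta_k[3])
        assert table.best_k == 2

    def test_zero_sd_floored_not_crashing(self):
        table = evanno_from_stats([1, 2, 3], [-100, -50, -49], [0.0, 0.0, 0.0])
        assert table.sd_floor_applied
        assert np.isfinite(table.delta_k[1])

    def test_two_k_range_best_undetermined(self):
        table = evanno_from_stats([1, 2], [-100, -50], [1, 1])
        assert table.best_k is None
        assert np.all(np.isnan(table.delta_k))

    def test_simulated_two_populations_select_k2(self, divergent_pair):
        geno, _ = divergent_pair
        geno = geno.take_sites(np.arange(600))
        rng = np.random.default_rng(12)
        runs = {k: [admixture_fit(geno, k, seed=int(rng.integers(2 ** 31)),
                                  max_iter=150)
                    for _ in range(10)]
                for k in range(1, 5)}
        assert evanno_delta_k(runs).best_k == 2

    def test_single_replicate_rejected(self, divergent_pair):
        geno, _ = divergent_pair
        runs = {1: [admixture_fit(geno.take_sites(np.arange(50)), 1, seed=0)],
                2: [admixture_fit(geno.take_sites(np.arange(50)), 2, seed=0)],
                3: [admixture_fit(geno.take_sites(np.arange(50)), 3, seed=0)]}
        with pytest.raises(ValueError, match="at least 2 replicate"):
            evanno_delta_k(runs)
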