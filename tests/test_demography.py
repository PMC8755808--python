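"""Model catalogue, expected SFS, composite likelihood, AIC selection and
derived quantities."""

import numpy as np
import pytest
from scipy.optimize import minimize as sp_minimize

from skyisland import (DemographicModel, JointSFS, SimulationConfig,
                       bootstrap_ci, build_model, composite_loglik,
                       derive_quantities, expected_sfs, fit_model, joint_sfs,
                       select_model, simulate_dataset)
from skyisland.demography import ExpectedSFS, _objective



class TestCatalogue:
    @pytest.mark.parametrize("cid,k", [
        ("i", 4), ("ii", 6), ("iii", 6), ("iv", 8), ("v", 9), ("vi", 7),
        ("vii", 9), ("viii", 7), ("ix", 9), ("x", 9), ("3pop", 13)])
    def test_free_parameter_counts(self, cid, k):
        labels = ("a", "b", "c") if cid == "3pop" else ("a", "b")
        assert build_model(cid, labels).space.k == k

    def test_null_model_fixes_migration_and_growth_to_zero(self):
        entry = build_model("i")
        assert entry.space.fixed == {"m12": 0.0, "m21": 0.0, "g1": 0.0, "g2": 0.0}
        model = entry.instantiate(dict(ne1=1e4, ne2=1e4, ne_anc=1e4, t_div=1e4))
        assert np.all(model.migration == 0)

    def test_bottleneck_expansion_signs_enforced_by_bounds(self):
        space = build_model("ix").space
        bounds = {p.name: (p.lower, p.upper) for p in space.free}
        assert bounds["ratio1"][0] >= 1.0      # population 1: larger in the past
        assert bounds["ratio2"][1] <= 1.0      # population 2: smaller in the past
        rev = {p.name: (p.lower, p.upper) for p in build_model("x").space.free}
        assert rev["ratio1"][1] <= 1.0
        assert rev["ratio2"][0] >= 1.0

    def test_unknown_id_lists_catalogue(self):
        with pytest.raises(ValueError, match="3pop"):
            build_model("xv")

    def test_event_models_instantiate_with_event_inside_divergence(self):
        entry = build_model("v")
        values = {p.name: np.sqrt(p.lower * p.upper) if p.log_scale else 0.0
                  for p in entry.space.free}
        values["t_event"] = values["t_div"] * 2  # clamped below t_div
        model = entry.instantiate(values)
        times = [e.time for e in model.events if e.kind == "size_change"]
        assert times and all(t < model.t_div for t in times)


class TestExpectedSfs:
    def test_constant_size_single_population_follows_inverse_i(self):
        model = DemographicModel.single_population(10000)
        exp = expected_sfs(model, [12], 20000, seed=1, folded=False)
        probs = exp.probs[1:12]
        theory = (1 / np.arange(1, 12))
        theory /= theory.sum()
        z = (probs - theory) / np.maximum(exp.mc_stderr[1:12], 1e-12)
        assert np.all(np.abs(z) < 3.5)

    def test_symmetric_island_model_symmetric_within_mc_error(self):
        model = DemographicModel.two_population(10000, 10000, 10000, 200000,
                                                m12=2e-5, m21=2e-5)
        exp = expected_sfs(model, [8, 8], 20000, seed=2, folded=False)
        se = np.sqrt(exp.mc_stderr ** 2 + exp.mc_stderr.T ** 2)
        z = np.abs(exp.probs - exp.probs.T) / np.maximum(se, 1e-15)
        assert z.max() < 3.5

    def test_matches_independent_coalescent_simulator(self):
        """Cross-simulator oracle (msprime) under an asymmetric-migration
        divergence model; also pins down the migration-rate convention."""
        import msprime

        ne1, ne2, anc, t, m12 = 10000, 5000, 8000, 20000, 1e-4
        model = DemographicModel.two_population(ne1, ne2, anc, t, m12=m12, m21=0.0,
                                                labels=("p1", "p2"))
        exp = expected_sfs(model, [4, 4], 40000, seed=3, folded=False)

        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=ne1)
        dem.add_population(name="p2", initial_size=ne2)
        dem.add_population(name="anc", initial_size=anc)
        dem.add_population_split(time=t, derived=["p1", "p2"], ancestral="anc")
        # forward migration p1 -> p2 is the backwards rate of lineages
        # moving p2 -> p1, which is msprime's (source=p2, dest=p1)
        dem.set_migration_rate(source="p2", dest="p1", rate=m12)
        reps = msprime.sim_ancestry(samples={"p1": 2, "p2": 2}, demography=dem,
                                    num_replicates=3000, random_seed=11, ploidy=2)
        acc = np.zeros((5, 5))
        n_rep = 0
        for ts in reps:
            sets = [ts.samples(population=0), ts.samples(population=1)]
            acc += ts.allele_frequency_spectrum(sample_sets=sets, mode="branch",
                                                polarised=True, span_normalise=True)
            n_rep += 1
        ms_probs = acc / acc.sum()
        poly = np.ones((5, 5), dtype=bool)
        poly[0, 0] = poly[4, 4] = False
        diff = np.abs(exp.probs[poly] - ms_probs[poly])
        assert diff.max() < 0.012  # ~3 combined MC standard errors

    def test_fixed_seed_is_bitwise_deterministic(self):
        model = DemographicModel.single_population(5000)
        a = expected_sfs(model, [10], 500, seed=9)
        b = expected_sfs(model, [10], 500, seed=9)
        assert np.array_equal(a.probs, b.probs)

    def test_few_replicates_warn(self):
        model = DemographicModel.single_population(5000)
        with pytest.warns(UserWarning, match="replicates"):
            expected_sfs(model, [6], 50, seed=1)

    def test_three_population_no_migration_equal_splits_reduce_to_pairwise(self):
        tri = DemographicModel.three_population(
            ne=(10000, 8000, 6000), ne_anc_12=9000, ne_anc=7000,
            t1=15000, t2=15000, labels=("a", "b", "c"))
        pair = DemographicModel.two_population(10000, 8000, 7000, 15000,
                                               labels=("a", "b"))
        e3 = expected_sfs(tri, [6, 6, 4], 30000, seed=4, folded=False)
        e2 = expected_sfs(pair, [6, 6], 30000, seed=5, folded=False)
        marg = e3.probs.sum(axis=2)
        # sites segregating only in the third population fall on the
        # pairwise-monomorphic corners, which the 2-pop spectrum excludes
        marg[0, 0] = marg[6, 6] = 0.0
        marg /= marg.sum()
        p2 = e2.probs.copy()
        p2[0, 0] = p2[6, 6] = 0.0
        p2 /= p2.sum()
        assert np.abs(marg - p2).max() < 0.01


class TestCompositeLoglik:
    @staticmethod
    def _exp_1d(probs, hap=3):
        arr = np.zeros(hap + 1)
        arr[1:hap] = probs
        return ExpectedSFS(pops=("A",), hap_sizes=(hap,), probs=arr, folded=False,
                           includes_monomorphic=False, p_monomorphic=0.0,
                           n_replicates=1000, seed=0, mc_stderr=np.zeros(hap + 1),
                           mean_total_length=1.0)

    def test_worked_arithmetic(self):
        obs = JointSFS(pops=("A",), hap_sizes=(3,), counts=[0, 3, 1, 0])
        exp = self._exp_1d([0.75, 0.25])
        assert composite_loglik(obs, exp) == pytest.approx(-2.2493, abs=5e-5)

    def test_zero_count_cells_contribute_nothing(self):
        obs = JointSFS(pops=("A",), hap_sizes=(3,), counts=[0, 3, 0, 0])
        a = composite_loglik(obs, self._exp_1d([0.75, 0.25]))
        b = composite_loglik(obs, self._exp_1d([0.75, 1e-12]))
        assert a == b == pytest.approx(3 * np.log(0.75))

    def test_maximized_at_empirical_frequencies(self):
        """Constrained-optimization oracle on a 6-cell example."""
        m = np.array([5.0, 9, 1, 3, 7, 2])

        def neg(p5):
            p = np.append(p5, 1 - p5.sum())
            if np.any(p <= 0):
                return 1e9
            return -(m * np.log(p)).sum()

        res = sp_minimize(neg, np.full(5, 1 / 6), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 20000})
        p_hat = np.append(res.x, 1 - res.x.sum())
        assert np.allclose(p_hat, m / m.sum(), atol=1e-4)

    def test_cell_mismatch_raises(self):
        obs = JointSFS(pops=("A",), hap_sizes=(4,), counts=[0, 1, 1, 1, 0])
        with pytest.raises(ValueError, match="cell mismatch"):
            composite_loglik(obs, self._exp_1d([0.75, 0.25]))


class TestSelection:
    @staticmethod
    def _fit(model_id, lnl, k, key=("x",)):
        from skyisland.demography import FitResult
        params = {"ne1": 1e4, "ne2": 1e4, "ne_anc": 1e4, "t_div": 1e4,
                  "m12": 0.0, "m21": 0.0}
        f = FitResult(model_id=model_id, labels=("a", "b"), params=params,
                      free_names=(), lnl=lnl, k=k, mu=3e-9, generation_time=2.0,
                      obs_key=key)
        return f

    def test_aic_arithmetic(self):
        assert self._fit("i", -100.0, 3).aic == 206.0

    def test_tie_broken_by_smaller_k(self):
        sel = select_model([self._fit("iv", -50.0, 6), self._fit("i", -50.0, 4)])
        assert sel.best_id == "i"

    def test_worked_ranking_of_four_fits(self):
        fits = [self._fit("i", -120.0, 4), self._fit("ii", -110.0, 6),
                self._fit("iii", -112.0, 6), self._fit("iv", -109.0, 8)]
        sel = select_model(fits)
        # AIC: i=248, ii=232, iii=236, iv=234
        assert list(sel.table["model"]) == ["ii", "iv", "iii", "i"]
        assert list(sel.table["delta_AIC"]) == [0.0, 2.0, 4.0, 16.0]

    def test_fits_on_different_data_refused(self):
        with pytest.raises(ValueError, match="different observed"):
            select_model([self._fit("i", -1.0, 4, key=("x",)),
                          self._fit("ii", -1.0, 6, key=("y",))])


class TestDerivedQuantities:
    def test_nm_is_source_size_times_forward_rate(self):
        params = dict(ne1=910_000, ne2=320_000, ne_anc=170_000, t_div=525_000,
                      m12=1e-5, m21=6e-6)
        d = derive_quantities(params, labels=("Wilhelm", "Huon"))
        assert d["nm"]["Wilhelm->Huon"] == pytest.approx(9.1)
        assert d["nm_display"]["Wilhelm->Huon"] == 9.1
        assert d["t_div_years"] == pytest.approx(1_050_000)

    def test_display_rounding_half_away_from_zero(self):
        params = dict(ne1=470_000, ne2=350_000, t_div=50_000, m12=1e-5, m21=2e-7)
        d = derive_quantities(params, labels=("a", "b"))
        assert d["nm_display"]["a->b"] == 4.7
        assert d["nm_display"]["b->a"] == 0.1  # 0.07 rounds up
        assert d["t_div_years"] == 100_000

    def test_zero_migration_gives_zero_migrants(self):
        params = dict(ne1=1e5, ne2=1e5, t_div=1e4, m12=0.0, m21=0.0)
        d = derive_quantities(params, labels=("a", "b"))
        assert d["nm"]["a->b"] == 0.0


@pytest.fixture(scope="module")
def small_migration_obs():
    model = DemographicModel.two_population(30000, 30000, 30000, 60000,
                                            m12=2e-5, m21=2e-5,
                                            labels=("pop1", "pop2"))
    cfg = SimulationConfig(model=model, samples_per_pop=(6, 6), n_sites=4000,
                           callable_length=3_000_000, seed=55, site_mode="poisson")
    geno, _ = simulate_dataset(cfg)
    return joint_sfs(geno, folded=True, callable_length=3_000_000)


class TestFitting:
    def test_warm_start_never_worse_than_truth(self, small_migration_obs):
        """Ascent: one start at the generating values must end at least as
        good as the start (same likelihood surface via common random
        numbers)."""
        truth = dict(ne1=30000, ne2=30000, ne_anc=30000, t_div=60000,
                     m12=2e-5, m21=2e-5)
        fit = fit_model(small_migration_obs, "ii", seed=3, search_reps=1000,
                        refine_reps=3000, search_maxfev=150, refine_maxfev=80,
                        start_values=[truth])
        entry = build_model("ii", ("pop1", "pop2"))
        fun = _objective(entry, small_migration_obs,
                         fit.diagnostics["final_eval_reps"],
                         fit.diagnostics["final_eval_seed"])
        lnl_truth = -fun(entry.space.to_vector(truth))
        assert fit.lnl >= lnl_truth - 1e-9

    def test_aic_identity_and_nm_consistency(self, small_migration_obs):
        fit = fit_model(small_migration_obs, "i", n_starts=4, seed=1,
                        search_reps=800, refine_reps=2000, search_maxfev=100,
                        refine_maxfev=60)
        assert fit.aic == 2 * fit.k - 2 * fit.lnl
        for key, nm in fit.derived["nm"].items():
            src = key.split("->")[0]
            assert nm == fit.derived["ne"][src] * fit.derived["migration"][key]

    def test_same_inputs_same_seed_identical_result(self, small_migration_obs):
        kw = dict(n_starts=3, seed=7, search_reps=500, refine_reps=1000,
                  search_maxfev=60, refine_maxfev=40)
        f1 = fit_model(small_migration_obs, "i", **kw)
        f2 = fit_model(small_migration_obs, "i", **kw)
        assert f1.lnl == f2.lnl
        assert f1.params == f2.params


def test_bootstrap_intervals_deterministic_and_ordered(small_migration_obs):
    fit = fit_model(small_migration_obs, "i", n_starts=3, seed=2,
                    search_reps=500, refine_reps=1500, search_maxfev=80,
                    refine_maxfev=50)
    with pytest.warns(UserWarning, match="bootstrap"):
        ci1 = bootstrap_ci(fit, small_migration_obs, n_boot=3, seed=5,
                           n_starts=1, search_reps=400, refine_reps=800,
                           search_maxfev=40, refine_maxfev=30)
        ci2 = bootstrap_ci(fit, small_migration_obs, n_boot=3, seed=5,
                           n_starts=1, search_reps=400, refine_reps=800,
                           search_maxfev=40, refine_maxfev=30)
    assert (ci1["lower"] <= ci1["upper"]).all()
    assert np.allclose(ci1[["lower", "upper"]], ci2[["lower", "upper"]])
    assert list(ci1.index) == list(fit.free_names)
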