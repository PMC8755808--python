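"""Generator-level checks: neutral-theory expectations, determinism,
planted relatives, and the covariate panel."""

import numpy as np
import pytest

from skyisland import (DemographicModel, SimulationConfig, inject_halfsibs,
                       joint_sfs, kinship_matrix, simulate_covariate_panel,
                       simulate_dataset, wc_fst, write_dataset)
from skyisland.elevation import ElevationRecord, spearman_fst_floor


def test_same_config_same_seed_gives_identical_vcf_bytes(tmp_path):
    model = DemographicModel.two_population(5000, 5000, 5000, 10000,
                                            labels=("A", "B"))
    cfg = SimulationConfig(model=model, samples_per_pop=(3, 3), n_sites=300, seed=9)
    for sub in ("a", "b"):
        geno, truth = simulate_dataset(cfg)
        write_dataset(geno, truth, tmp_path / sub)
    assert (tmp_path / "a" / "dataset.vcf").read_bytes() == \
        (tmp_path / "b" / "dataset.vcf").read_bytes()


def test_deep_divergence_gives_high_fst(divergent_pair):
    geno, _ = divergent_pair
    res = wc_fst(geno, ("A", "B"))
    assert res.theta >= 0.8


def test_all_sites_segregate_with_dosages_in_range(divergent_pair):
    geno, _ = divergent_pair
    g = geno.genotypes
    assert set(np.unique(g)) <= {0, 1, 2}
    totals = g.sum(axis=1)
    assert np.all(totals > 0)
    assert np.all(totals < 2 * geno.n_samples)


def test_segregating_sites_match_watterson_expectation():
    """Poisson mode: E[S] = 4*Ne*mu*L * sum_{i<2n} 1/i for one population."""
    ne, mu, n_loci, L = 20000, 3e-9, 300, 3_000_000
    model = DemographicModel.single_population(ne, mu=mu)
    cfg = SimulationConfig(model=model, samples_per_pop=(6,), n_sites=n_loci,
                           callable_length=L, seed=101, site_mode="poisson")
    geno, truth = simulate_dataset(cfg)
    expected = 4 * ne * mu * L * sum(1 / i for i in range(1, 12))
    # standard error from the observed per-locus dispersion
    locus = (geno.sites["pos"].to_numpy() - 1) // (L // n_loci)
    per_locus = np.bincount(locus.astype(int), minlength=n_loci)
    se = per_locus.std(ddof=1) * np.sqrt(n_loci)
    assert abs(truth.realized_snps - expected) < 3 * se


def test_unfolded_single_population_sfs_proportional_to_inverse_i():
    model = DemographicModel.single_population(10000)
    cfg = SimulationConfig(model=model, samples_per_pop=(6,), n_sites=120_000,
                           callable_length=10 ** 7, seed=5)
    geno, _ = simulate_dataset(cfg)
    spec = joint_sfs(geno, folded=False)
    counts = spec.counts[1:12]
    n = counts.sum()
    probs = (1 / np.arange(1, 12))
    probs /= probs.sum()
    expected = n * probs
    z = (counts - expected) / np.sqrt(n * probs * (1 - probs))
    assert np.all(np.abs(z) < 4.0)


def test_symmetric_island_model_gives_symmetric_joint_sfs():
    model = DemographicModel.two_population(8000, 8000, 8000, 160000,
                                            m12=3e-5, m21=3e-5)
    cfg = SimulationConfig(model=model, samples_per_pop=(5, 5), n_sites=80_000,
                           callable_length=10 ** 7, seed=21)
    geno, _ = simulate_dataset(cfg)
    spec = joint_sfs(geno, folded=False)
    c = spec.counts
    diff = c - c.T
    se = np.sqrt(c + c.T + 1.0)
    assert np.max(np.abs(diff) / se) < 4.0


class TestInjectHalfsibs:
    def test_planted_pair_estimates_half_sib_kinship(self, panmictic_halfsib):
        geno, truth = panmictic_halfsib
        kin = kinship_matrix(geno)
        a, b = truth.pedigree[0]["samples"]
        ia, ib = geno.sample_ids.index(a), geno.sample_ids.index(b)
        assert kin.phi[ia, ib] == pytest.approx(0.125, abs=0.015)

    def test_duplicated_sample_estimates_self_kinship(self, panmictic_halfsib):
        geno, _ = panmictic_halfsib
        g = geno.genotypes.copy()
        g[:, 1] = g[:, 0]
        dup = geno.take_sites(np.arange(geno.n_sites))
        dup.genotypes = g
        kin = kinship_matrix(dup)
        assert kin.phi[0, 1] == pytest.approx(0.5, abs=0.01)

    def test_empty_pair_spec_returns_matrix_unchanged(self, panmictic_halfsib):
        geno, _ = panmictic_halfsib
        out = inject_halfsibs(geno, [], seed=1)
        assert out is geno

    def test_unknown_sample_raises(self, panmictic_halfsib):
        geno, _ = panmictic_halfsib
        with pytest.raises(ValueError, match="unknown sample"):
            inject_halfsibs(geno, [("nope", geno.sample_ids[0])], seed=1)

    def test_other_samples_untouched(self, panmictic_halfsib):
        geno, truth = panmictic_halfsib
        pair = truth.pedigree[0]["samples"]
        untouched = [i for i, s in enumerate(geno.sample_ids) if s not in pair]
        assert len(untouched) == geno.n_samples - 2


class TestCovariatePanel:
    base = DemographicModel.two_population(20000, 20000, 20000, 40000)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            simulate_covariate_panel(1, lambda f: 1e-5, self.base, seed=1)

    def test_migration_decreasing_in_floor_gives_positive_correlation(self):
        panel = simulate_covariate_panel(
            12, lambda f: 2e-4 * np.exp(-f / 600.0), self.base, seed=3,
            samples_per_pop=(8, 8), n_sites=2000)
        records = []
        for geno, floor, truth in panel:
            theta = wc_fst(geno).theta_clamped
            records.append(ElevationRecord(species=truth.model_params["labels"][0]
                                           + f"_{floor:.0f}", fst=min(theta, 1.0),
                                           floor_m=floor))
            assert truth.migration_rate == pytest.approx(2e-4 * np.exp(-floor / 600.0))
            assert "non_monotone_mapping" not in truth.flags
        res = spearman_fst_floor(records, seed=11)
        assert res.r > 0
        assert res.p < 0.05

    def test_non_monotone_mapping_flagged_in_truth(self):
        panel = simulate_covariate_panel(
            5, lambda f: 1e-5 * (1 + np.sin(f / 300.0)), self.base, seed=4,
            samples_per_pop=(4, 4), n_sites=200)
        assert all(t.flags.get("non_monotone_mapping") for _, _, t in panel)


def test_degenerate_model_rejected_with_field_name():
    with pytest.raises(ValueError, match="ne"):
        DemographicModel.two_population(0, 1000, 1000, 1000)
    with pytest.raises(ValueError, match="size_changes"):
        DemographicModel.two_population(1000, 1000, 1000, 1000,
                                        size_changes=((5000, 0, 2000),))
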