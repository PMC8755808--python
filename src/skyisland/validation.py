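"""Simulation-based validation experiments for the demographic machinery.

Two standing experiments exercised by the test suite and the acceptance
script:

* :func:`parameter_recovery_experiment` — simulate replicate datasets
  under catalogue model iv at a fixed truth, refit the model, and score
  how often current sizes, ancestral size and divergence time land within
  +/-25% and migration rates within a factor of 3.  Note that at this
  sampling depth the (T, ancestral Ne) profile of the composite
  likelihood is nearly degenerate (see the methods note), so the
  divergence-time column scatters far more than the other parameters.

* :func:`model_selection_experiment` — AIC model choice between a
  divergence model with migration (ii) and its no-migration twin (i), on
  data simulated with and without migration.  Both fits share one seed so
  the common-random-numbers likelihood noise largely cancels in the AIC
  difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import fit_model, select_model
from .models import DemographicModel
from .sfs import joint_sfs
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RECOVERY_TRUTH", "parameter_recovery_experiment",
           "model_selection_experiment"]

#: generating values for the recovery experiment (catalogue model iv with
#: zero growth): sizes in diploids, time in generations, forward rates
RECOVERY_TRUTH = dict(ne1=50_000.0, ne2=20_000.0, ne_anc=40_000.0,
                      t_div=100_000.0, m12=5e-5, m21=1e-5)

_SIZE_KEYS = ("ne1", "ne2", "ne_anc", "t_div")
_MIG_KEYS = ("m12", "m21")


def parameter_recovery_experiment(n_datasets: int = 10, seed: int = 0,
                                  samples_per_pop: tuple[int, int] = (10, 10),
                                  callable_length: int = 10_000_000,
                                  n_loci: int = 30_000,
                                  n_starts: int = 20,
                                  refine_reps: int = 10_000) -> pd.DataFrame:
    """Fit catalogue model iv to replicate datasets simulated under it.

    Returns one row per dataset with estimate/truth ratios and the joint
    success flag (sizes and divergence time within +/-25%, migration
    within 3x).
    """
    truth_model = DemographicModel.two_population(
        RECOVERY_TRUTH["ne1"], RECOVERY_TRUTH["ne2"], RECOVERY_TRUTH["ne_anc"],
        RECOVERY_TRUTH["t_div"], m12=RECOVERY_TRUTH["m12"],
        m21=RECOVERY_TRUTH["m21"], labels=("pop1", "pop2"))
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_datasets):
        data_seed = int(rng.integers(2 ** 31))
        fit_seed = int(rng.integers(2 ** 31))
        cfg = SimulationConfig(model=truth_model, samples_per_pop=samples_per_pop,
                               n_sites=n_loci, callable_length=callable_length,
                               seed=data_seed, site_mode="poisson")
        geno, _ = simulate_dataset(cfg)
        obs = joint_sfs(geno, folded=True, callable_length=callable_length)
        fit = fit_model(obs, "iv", n_starts=n_starts, seed=fit_seed,
                        refine_reps=refine_reps, search_maxfev=100,
                        refine_maxfev=60, max_events_per_rep=1500,
                        n_refine=1, scan_spans=(0.1,))
        row = {"data_seed": data_seed, "lnCL": fit.lnl}
        for k, tv in RECOVERY_TRUTH.items():
            row[f"{k}_ratio"] = fit.params[k] / tv
        row["sizes_ok"] = all(0.75 <= row[f"{k}_ratio"] <= 1.25 for k in _SIZE_KEYS)
        row["migration_ok"] = all(1 / 3 <= row[f"{k}_ratio"] <= 3 for k in _MIG_KEYS)
        row["success"] = row["sizes_ok"] and row["migration_ok"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SelectionOutcome:
    migration_data_prefers_migration: int
    null_data_prefers_null: int
    n_replicates: int
    details: pd.DataFrame


def model_selection_experiment(n_replicates: int = 10, seed: int = 0,
                               samples_per_pop: tuple[int, int] = (6, 6),
                               callable_length: int = 3_000_000,
                               n_loci: int = 6000,
                               n_starts: int = 8) -> SelectionOutcome:
    """AIC choice between models i (null) and ii (migration) on data
    simulated under each; counts how often the generating class wins."""
    base = dict(ne1=30_000, ne2=30_000, ne_anc=30_000, t_div=60_000)
    mig_model = DemographicModel.two_population(**base, m12=2e-5, m21=2e-5,
                                                labels=("pop1", "pop2"))
    null_model = DemographicModel.two_population(**base, labels=("pop1", "pop2"))
    rng = np.random.default_rng(seed)
    rows = []
    wins = {"migration": 0, "null": 0}
    for arm, model in (("migration", mig_model), ("null", null_model)):
        for _ in range(n_replicates):
            data_seed = int(rng.integers(2 ** 31))
            fit_seed = int(rng.integers(2 ** 31))
            cfg = SimulationConfig(model=model, samples_per_pop=samples_per_pop,
                                   n_sites=n_loci, callable_length=callable_length,
                                   seed=data_seed, site_mode="poisson")
            geno, _ = simulate_dataset(cfg)
            obs = joint_sfs(geno, folded=True, callable_length=callable_length)
            kw = dict(seed=fit_seed, search_reps=800, refine_reps=3000,
                      search_maxfev=80, refine_maxfev=50, ridge_scan=False,
                      max_events_per_rep=800)
            fit_i = fit_model(obs, "i", n_starts=n_starts, **kw)
            fit_ii = fit_model(obs, "ii", n_starts=n_starts, **kw)
            # nested warm start: the migration model must never lose to its
            # null twin through optimizer luck alone, so also climb from
            # the null optimum with migration switched on at several scales
            anchor = {k: fit_i.params[k] for k in ("ne1", "ne2", "ne_anc", "t_div")}
            warm = [dict(anchor, m12=m, m21=m) for m in (1e-8, 1e-6, 3e-5)]
            fit_ii_warm = fit_model(obs, "ii", start_values=warm, **kw)
            if fit_ii_warm.lnl > fit_ii.lnl:
                fit_ii = fit_ii_warm
            # ... and symmetrically let the null model climb from the
            # migration optimum projected onto m=0, so neither model can
            # win through extra optimization passes alone
            proj = {k: fit_ii.params[k] for k in ("ne1", "ne2", "ne_anc", "t_div")}
            fit_i_warm = fit_model(obs, "i",
                                   start_values=[dict(fit_i.params), proj], **kw)
            if fit_i_warm.lnl > fit_i.lnl:
                fit_i = fit_i_warm
            sel = select_model([fit_i, fit_ii])
            expected = "ii" if arm == "migration" else "i"
            if sel.best_id == expected:
                wins[arm] += 1
            rows.append({"arm": arm, "data_seed": data_seed,
                         "aic_i": fit_i.aic, "aic_ii": fit_ii.aic,
                         "best": sel.best_id})
    return SelectionOutcome(
        migration_data_prefers_migration=wins["migration"],
        null_data_prefers_null=wins["null"],
        n_replicates=n_replicates,
        details=pd.DataFrame(rows))
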