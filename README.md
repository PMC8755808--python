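# skyisland

Comparative population genomics of montane taxa ("sky islands"):
a tested, reusable pipeline for asking how strongly barriers and
elevational distributions structure populations, and what demographic
history produced that structure.

Given multi-sample SNP calls (VCF) and a sample map (population,
elevation, species), the package provides:

* **Site filtering** — depth ∈ [10, 100], quality ≥ 20, indel proximity,
  biallelic-only, no missing data;
* **Kinship QC** — the robust shared-heterozygote / opposite-homozygote
  estimator φ = (N_het,het − 2·N_AA,aa)/(N_het(i)+N_het(j)); pairs with
  φ > 0.06 are flagged (duplicates ≈ 0.5, half-sibs ≈ 0.125) and one
  member greedily excluded;
* **Structure statistics** — LD pruning (window 100, step 5, r² 0.5),
  Weir–Cockerham FST (multilocus θ̂ = Σa/Σ(a+b+c), with
  elevation-stratum contrasts), genotype PCA, maximum-likelihood
  admixture proportions (EM) and the Evanno ΔK choice of cluster number;
* **Joint site-frequency spectra** — folded or unfolded, 1–3
  populations, with monomorphic mass from the callable genome length and
  a fastsimcoal2-compatible `.obs` text dialect;
* **Demographic inference** — a catalogue of ten two-population
  isolation-with-migration scenarios (null, migration, growth,
  bottleneck/expansion events, and combinations) plus a three-population
  variant, fitted by maximizing the composite multinomial likelihood
  lnCL = Σ_c m_c ln p̂_c, where the expected spectrum p̂ comes from
  coalescent simulation (branch-length weighting, common random
  numbers).  Models are ranked by AIC = 2k − 2 lnCL, and fits report
  derived quantities on the field's scale: divergence time in years
  (T × generation time, default 2 y) and effective migrants per
  generation Nm[A→B] = Ne_A × m[A→B];
* **Elevation regression** — Spearman correlation between per-species
  FST and altitudinal floor with exact or Monte-Carlo permutation
  p-values;
* **A coalescent synthetic-data generator** — Hudson-style structured
  coalescent over the same model catalogue, with planted half-sib pairs,
  negative-binomial depths / Gaussian qualities for the filters to cut,
  and a species-level elevation covariate panel.

Everything is driven either from Python, from per-stage CLI subcommands
(`skyisland simulate|filter|kinship|prune|fst|pca|admixture|sfs|fit|elevation|run`),
or end-to-end from one YAML config (`skyisland run --config ...`).

## Worked example

Simulate two populations of six diploids exchanging ~0.6 migrants per
generation since splitting 60,000 generations (120,000 years) ago, run
the pipeline stages, and let AIC decide between the null model (i) and
the migration model (ii):

```python
import skyisland as sk

model = sk.DemographicModel.two_population(
    ne1=30000, ne2=30000, ne_anc=30000, t_div=60000,
    m12=2e-5, m21=2e-5, labels=("wilhelm", "huon"))
cfg = sk.SimulationConfig(model=model, samples_per_pop=(6, 6), n_sites=6000,
                          callable_length=3_000_000, seed=7, site_mode="poisson")
geno, truth = sk.simulate_dataset(cfg)

filtered, counts = sk.filter_sites(geno)
kin = sk.kinship_matrix(filtered)
fst = sk.wc_fst(filtered, ("wilhelm", "huon"))
obs = sk.joint_sfs(filtered, folded=True, callable_length=3_000_000)
fits = [sk.fit_model(obs, mid, n_starts=8, seed=1, search_reps=800,
                     refine_reps=4000, search_maxfev=100, refine_maxfev=60)
        for mid in ("i", "ii")]
sel = sk.select_model(fits)
```

This prints (about two minutes on one CPU):

```
simulated 6384 SNPs for 12 diploids
filters removed 300 sites (depth 274, qual 26); 6084 remain
relatives above 0.06: []
Weir-Cockerham FST = 0.161 over 6084 sites
model  k          lnCL           AIC  delta_AIC
   ii  6 -64826.618637 129665.237274   0.000000
    i  4 -64906.240380 129820.480759 155.243485
best model ii: T_DIV = 184,440 y, Nm wilhelm->huon = 0.7, Nm huon->wilhelm = 0.6
```

The migration model beats the null model by ~155 AIC units, and the
derived migrant numbers (0.7 and 0.6 per generation) recover the
generating value (0.6).  The divergence time lands at 184 ky against a
truth of 120 ky: with samples this small the composite likelihood is
nearly flat along a ridge where divergence time trades off against
ancestral size, so T estimates are order-of-magnitude statements (see
`docs/methods.md`), best accompanied by `bootstrap_ci` intervals.

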