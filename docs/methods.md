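# Methods

`skyisland` re-implements, as one tested pipeline, the population-genomic
workflow used in comparative studies of montane bird divergence: SNP site
filtering, kinship-based sample QC, population-structure statistics, joint
site-frequency spectra (SFS), and composite-likelihood fitting of a
catalogue of isolation-with-migration (IM) demographic models.  A
coalescent synthetic-data generator stands in for resequencing data so
every stage can be exercised, and validated, at desk scale.

## The coalescent engine

All genealogies come from a Hudson-style structured coalescent over 1–3
demes (`skyisland._coalescent`).  Loci are independent, non-recombining,
and carry at most a handful of mutations each; this matches the intended
use of the downstream statistics, which assume (LD-pruned) unlinked SNPs.
A demographic model — current diploid sizes Ne, per-generation exponential
growth rates, a forward migration matrix, instantaneous size changes and
divergence joins — is flattened into piecewise epochs; within an epoch,
waiting times for coalescence (rate k(k−1)/4Ne(t) for k haploid lineages)
and migration are drawn as competing exponentials, with the exact
closed-form inversion for exponentially growing sizes.  Migration follows
the forward convention of the literature ("M A to B" = probability an
individual in B originated in A per generation) and is converted to the
backward lineage-jump rate internally; the convention is pinned down by a
cross-simulator test against msprime with asymmetric rates.

Two consumption modes share the kernel:

* **branch mode** records every branch as a (descendant bitmask, length)
  pair, so mutations can be dropped onto genealogies and produce diploid
  genotypes;
* **expected mode** bins branch lengths by the joint-SFS cell they
  subtend, yielding Monte-Carlo expected branch lengths E[ℓ_c] per cell
  with standard errors.

## Synthetic data

`simulate_dataset` writes biallelic, fully segregating SNP matrices in two
site modes.  In `fixed_snps` mode exactly `n_sites` loci carry one SNP
each; genealogies are accepted with probability proportional to their
total length (batch rejection sampling) before a single mutation is placed
proportionally to branch length, so the site-configuration law is
E[ℓ_c]/E[T] — the same law as the expectation model — rather than the
short-tree-biased within-tree law E[ℓ_c/T].  In `poisson` mode the
`callable_length` is partitioned into `n_sites` loci and each receives
Poisson(μ·L·T) mutations, so the realized SNP count is random and, with
the callable length, carries absolute information about Ne.  Read depths
are negative-binomial per sample×site (default mean 32, dispersion 12) and
site qualities Gaussian (mean 50, sd 12); with twenty samples these
defaults send roughly 5–10% of sites through the default filters, so the
filtering stage always has realistic casualties.  Half-sib pairs are
planted by gamete-dropping from three Hardy–Weinberg parents at the
population allele frequencies; the elevation covariate panel ties a
species' symmetric migration rate to its altitudinal floor through a
user-supplied mapping.  All randomness derives from one seed; identical
configurations give byte-identical VCFs.

What the generator does **not** emulate: linkage within loci,
recombination maps, sequencing error in genotype calls (depth/quality are
annotations, not error processes), reference bias, and selection.  Passing
tests therefore validate the statistical machinery, not robustness to
those real-data artefacts.

## Site filters and kinship

Filters mirror a standard short-read recipe: per-sample depth within
[10, 100] (a site fails if any sample is outside; a summed-depth variant
is exposed), site quality ≥ 20, exclusion within 5 bp of an indel record
(the window is a convention; callers differ), biallelic-only, and
no-missing-data.  Rules are evaluated simultaneously, each removed site is
attributed to every rule it violates, and filtering is idempotent.

Kinship uses the robust shared-heterozygote/opposite-homozygote estimator
(KING-robust family) on called genotypes:
φ = (N_het,het − 2·N_AA,aa)/(N_het(i) + N_het(j)).  It needs no genotype
likelihoods, is invariant to allele relabelling, and hits the pedigree
expectations used for QC decisions (duplicates ≈ 0.5, half-sibs ≈ 0.125,
unrelated ≈ 0).  Samples are excluded greedily — repeatedly dropping the
sample in the most pairs above the 0.06 threshold, breaking ties toward
more missing data then the lexicographically larger id — so exactly one
member of an isolated flagged pair is removed.

## Structure statistics

* **LD pruning** follows the indep-pairwise semantics: sliding windows of
  100 sites advanced by 5, removing the later member of any retained pair
  with dosage r² > 0.5; monomorphic sites have undefined correlation and
  are kept.
* **FST** is the Weir–Cockerham variance-component estimator; per-site
  components a, b, c from sample sizes, allele frequencies and observed
  heterozygosities, multilocus estimate Σa/Σ(a+b+c) (ratio of sums), sites
  monomorphic in the pooled sample excluded and counted.  Negative
  multilocus estimates are reported as computed, with a clamped
  convenience value.
* **PCA** operates on centered, variance-standardized genotype dosages
  (sign fixed by making each component's first nonzero loading positive).
  The alternative reading — PCA of a pairwise-FST matrix — does not
  produce per-sample coordinates and is not implemented.
* **Admixture** is the maximum-likelihood binomial ancestry mixture
  (dosage ~ Binomial(2, Σ_k q_ik p_kj)) fitted by EM, which is monotone in
  the log-likelihood.  The Bayesian MCMC machinery of STRUCTURE is
  deliberately replaced: replicate "runs" differ by random initialization,
  and multi-start dispersion plays the role of MCMC dispersion in the
  Evanno ΔK statistic, ΔK(K) = |m(L(K+1)) − 2m(L(K)) + m(L(K−1))|/sd(L(K)),
  maximized over interior K (sd floored at 1e-6, recorded).

## Joint SFS

Spectra are 1–3 dimensional arrays over alternate (unfolded) or minor
(folded) allele counts; the default is folded because no outgroup
polarization is assumed.  Folding maps each cell onto its complement when
the pooled count exceeds half the pooled sample size; exact-half cells
keep the lexicographically smaller representative, making folding
idempotent and mass-conserving.  Monomorphic mass (callable length minus
segregating sites) makes absolute Ne identifiable at fixed μ; without it
only scaled parameters are meaningful and fits are reported as such.  The
text dialect mirrors fastsimcoal2 observed-SFS files ("1 observations"
header, `d<pop>_<count>` labels, joint layout with population 1 on rows).

## Demographic inference

The catalogue holds ten two-population scenarios — (i) null, (ii)
migration, (iii) exponential growth, (iv) both, (v)–(viii) a single past
instantaneous size-change event in both daughter populations (bottleneck
variants: past/current ratio > 1, i.e. decline toward the present;
sudden-expansion variants: ratio < 1), with and without migration, and
(ix)/(x) a bottleneck in one population with an expansion in the other —
plus a three-population variant with topology ((1,2),3) and six free
migration rates.  Event models place one event time strictly inside the
divergence interval with one size ratio per population; this is one
defensible concretization of "a demographic event leading to a
bottleneck/expansion" given that finer specification is not available.
Search bounds are log-uniform: Ne ∈ [10³, 10⁷], T ∈ [10², 10⁷]
generations, m ∈ [10⁻¹⁰, 10⁻²], growth ∈ [−10⁻³, 10⁻³] (linear); they
bracket published passerine-scale estimates by well over an order of
magnitude and are overridable.

**Expected SFS.** Cell probabilities come from coalescent simulation by
branch-length weighting: p_c = μ·E[ℓ_c] per site with the remaining mass
on the monomorphic class (absolute mode), or normalized over polymorphic
cells otherwise.  A floor of 1/(10·R·cells) keeps cells positive.  A fixed
seed makes the expectation, and hence the whole likelihood surface,
deterministic (common random numbers).

**Composite likelihood.** lnCL = Σ_c m_c ln p̂_c (+ the monomorphic term
when the observed spectrum carries that mass).  Because p̂ is itself a
Monte-Carlo estimate, E[ln p̂] = ln p − Var(p̂)/(2p²): the bias varies
systematically across parameter space (deep-tree regions have different
relative cell variances), which would tilt parameter and model
comparisons.  The first-order Jensen correction, computed from the
per-cell Monte-Carlo standard errors, is therefore added back.  In
recovery experiments this debiasing removed a systematic migration-rate
distortion.

**Optimization.** Bounded Nelder–Mead on log₁₀-transformed parameters,
multi-start (100 by default, mirroring common practice; experiments here
use 20).  Starts combine moment-based values — Watterson θ per population
for Ne, net and raw between-population divergence for T, an island-model
FST heuristic (Nm = (1/F−1)/4) for migration — swept over a ×{0.3, 1, 3}
divergence-time grid, jittered copies, and log-uniform random draws.
Growth rates are pinned at zero while polishing informed starts (a
homotopy: free growth opens short-divergence trap basins whose inflated
Monte-Carlo noise flatters the raw likelihood) and explored from the
random starts.  The best start of every divergence-time bucket is
polished; basins are then compared at 3× the refinement replicate count
(noisy argmax would systematically favor high-variance regions); the two
best candidates are refined; the nearly flat (T, ancestral Ne) ridge is
walked by alternating 5×5 log-grid scans — summarized by a least-squares
quadratic surface whose minimum, not the noisy pointwise argmin, is
taken — with short all-parameter polishes that recouple the remaining
parameters, each endgame stage on a fresh derived seed; and the reported
likelihood comes from one high-precision evaluation at 10× the
refinement replicate count, so AIC differences between models fitted
with a shared seed are not dominated by evaluation noise.  Runaway
parameter regions (e.g. extreme migration × size combinations) are cut
off by a per-replicate simulation event budget and scored as infeasible.

**Known limitation — (T, Ne_anc) ridge.**  For two-population IM models
at realistic sampling depth (10+10 diploids) with appreciable migration,
the composite likelihood is nearly degenerate along a ridge where larger
divergence times trade off against smaller ancestral sizes: in a direct
measurement at 3×10⁵ SNPs, a point with T at 1.49× and Ne_anc at 0.72× of
the generating values was separated from the truth by only ≈3 lnCL units.
Current sizes and migration rates are recovered reliably; divergence-time
point estimates from data of this shape should be treated as
order-of-magnitude, and their uncertainty assessed with the parametric
bootstrap.

**Selection and derived quantities.**  AIC = 2k − 2 lnCL exactly;
ascending sort with ties broken by smaller k then catalogue order.
Derived values: divergence time in years = T × generation time (default
2 y); effective migrants per generation Nm[A→B] = Ne_A × m[A→B]; display
rounding follows the field's convention (Ne to the nearest 10⁴, Nm to one
decimal, half away from zero).  Default scaling constants: μ = 3×10⁻⁹ per
site per generation (passerines; 2×10⁻⁹ exposed for the kingfisher),
generation time 2 years.  Confidence intervals are parametric-bootstrap
percentiles: spectra resampled from the fitted model at the observed site
count and refit with reduced starts (warm-started at the point estimate).

## Elevation regression

Spearman rank correlation (average ranks for ties) between per-species
FST and altitudinal floor, with a permutation p-value: exact enumeration
for n ≤ 10, seeded Monte-Carlo otherwise.  Species exclusions are always
configuration, never hard-coded, and undefined correlations (constant
inputs) are reported as such.

## Validation experiments and problem sizes

The standing experiments (`skyisland.validation`) run at sizes chosen to
exercise the machinery thoroughly on a single CPU: parameter recovery
fits catalogue model iv (20 starts, 10⁴ refinement replicates) to ten
datasets of ≈30,000 SNPs (10+10 diploids, 10⁷ bp callable) simulated at
Ne₁ = 50,000, Ne₂ = 20,000, Ne_anc = 40,000, T = 100,000 generations,
m₁₂ = 5×10⁻⁵, m₂₁ = 10⁻⁵; model selection contrasts models i and ii on
ten datasets each of ≈6,000 loci (6+6 diploids, 3×10⁶ bp) simulated with
and without symmetric migration 2×10⁻⁵.  Both fits share one seed (so
common-random-numbers noise cancels in the AIC difference) and the
comparison is symmetrized by nested warm starts — the migration model is
also climbed from the null optimum with migration switched on, and the
null model from the migration optimum projected onto m = 0 — so neither
model can win through unequal optimization effort; what remains is the
likelihood-ratio signal that AIC is meant to judge.  Neutral
checks (Watterson's E[S], the 1/i unfolded spectrum, island-model
symmetry) run at 2–3×10⁴ replicates against 3–4 Monte-Carlo standard
errors.
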