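"""Coalescent synthetic-data generator.

Generates datasets with the statistical structure the analysis pipeline
assumes: independent non-recombining loci under a structured-coalescent
demographic model, diploid genotypes, negative-binomial read depths and
Gaussian site qualities (so the site filters have realistic casualties),
planted half-sib pairs, and a species-level elevation covariate panel.

Two site modes are supported:

* ``"fixed_snps"`` (default) — exactly ``n_sites`` SNPs, one segregating
  mutation per locus, placed on each genealogy proportionally to branch
  length (every site segregates in the pooled sample by construction);
* ``"poisson"`` — ``n_sites`` loci partitioning ``callable_length`` bp;
  each locus receives Poisson(mu * L_locus * tree length) mutations, so the
  realized SNP count is random and, together with ``callable_length``,
  carries absolute information about Ne.

All randomness derives from the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _coalescent
from .models import DemographicModel
from .variants import GenotypeMatrix, write_sample_map, write_vcf

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_dataset",
    "inject_halfsibs",
    "simulate_covariate_panel",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Inputs for one synthetic dataset."""

    model: DemographicModel
    samples_per_pop: tuple[int, ...]
    n_sites: int = 5000
    callable_length: int = 10_000_000
    seed: int = 0
    halfsib_pairs: tuple[tuple[str, str], ...] = ()  # (population, pair id)
    depth_model: tuple[float, float] = (32.0, 12.0)  # NB mean, dispersion k
    qual_model: tuple[float, float] = (50.0, 12.0)   # Normal mean, sd
    site_mode: str = "fixed_snps"

    def __post_init__(self) -> None:
        self.samples_per_pop = tuple(int(x) for x in self.samples_per_pop)
        if len(self.samples_per_pop) != self.model.n_pops:
            raise ValueError("samples_per_pop must match the model's population count")
        if any(s < 2 for s in self.samples_per_pop):
            raise ValueError("need at least 2 diploids per population (field 'samples_per_pop')")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.callable_length < self.n_sites:
            raise ValueError("callable_length must be >= n_sites")
        if self.site_mode not in ("fixed_snps", "poisson"):
            raise ValueError(f"unknown site_mode {self.site_mode!r}")
        if self.depth_model[0] <= 0 or self.depth_model[1] <= 0:
            raise ValueError("depth_model mean and dispersion must be positive")
        for pop, _pair_id in self.halfsib_pairs:
            if pop not in self.model.labels:
                raise ValueError(f"halfsib pair names unknown population {pop!r}")


@dataclass
class TruthRecord:
    """Ground truth written next to each synthetic dataset."""

    model_params: dict
    samples_per_pop: tuple[int, ...]
    seed: int
    pedigree: list = field(default_factory=list)   # planted relationships
    elevation_floor: float | None = None
    migration_rate: float | None = None
    flags: dict = field(default_factory=dict)
    realized_snps: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


def _model_params(model: DemographicModel) -> dict:
    return {
        "labels": list(model.labels),
        "ne": list(model.ne),
        "growth": list(model.growth),
        "migration": model.migration.tolist(),
        "events": [
            {"time": e.time, "kind": e.kind, "pop": e.pop, "dest": e.dest, "size": e.size}
            for e in model.events],
        "mu": model.mu,
        "generation_time": model.generation_time,
    }


def _sample_frame(model: DemographicModel, samples_per_pop, species: str,
                  elevation: float | None) -> pd.DataFrame:
    rows = []
    for pop, n in zip(model.labels, samples_per_pop):
        for i in range(n):
            rows.append({"sample_id": f"{pop}_{i:02d}", "population": pop,
                         "elevation_m": elevation, "species": species})
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig, species: str = "synthetic",
                     elevation: float | None = None,
                     ) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate biallelic diploid genotypes under the configured model."""
    rng = np.random.default_rng(config.seed)
    kernel_seed = int(rng.integers(2 ** 31))
    mut_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    depth_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    qual_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    base_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    sib_seed = int(rng.integers(2 ** 31))

    hap_sizes = [2 * s for s in config.samples_per_pop]
    n_hap = sum(hap_sizes)
    if config.site_mode == "fixed_snps":
        # exactly one segregating mutation per locus: accept genealogies
        # with probability proportional to their total length (rejection
        # against the running batch envelope), then drop one mutation on
        # the accepted tree proportionally to branch length, so the site
        # configuration distribution is E[l_c]/E[T] as in the expectation
        # model, not the short-tree-biased within-tree law E[l_c/T]
        site_lo, site_hi = [], []
        n_left = config.n_sites
        envelope = 0.0
        batch_no = 0
        while n_left > 0:
            batch = int(min(max(4 * n_left, 1000), 25_000))
            mask_lo, mask_hi, br_len, t_total = _coalescent.simulate_branches(
                config.model, hap_sizes, batch, kernel_seed + batch_no)
            batch_no += 1
            new_env = max(envelope, float(t_total.max()))
            if new_env > envelope and site_lo:
                # re-thin earlier acceptances against the raised envelope
                keep = mut_rng.random(len(site_lo)) < envelope / new_env
                site_lo = [m for m, k in zip(site_lo, keep) if k]
                site_hi = [m for m, k in zip(site_hi, keep) if k]
                n_left = config.n_sites - len(site_lo)
            envelope = new_env
            accept = np.flatnonzero(mut_rng.random(batch) * envelope < t_total)
            take = accept[:n_left]
            cum = np.cumsum(br_len[take], axis=1)
            u = mut_rng.random(len(take)) * cum[:, -1]
            branch = (cum < u[:, None]).sum(axis=1)
            site_lo.extend(mask_lo[take, branch])
            site_hi.extend(mask_hi[take, branch])
            n_left = config.n_sites - len(site_lo)
        locus_len = config.callable_length / config.n_sites
        pos = (np.arange(config.n_sites) * locus_len).astype(np.int64) + 1
        hap = _coalescent.masks_to_haplotypes(
            np.array(site_lo, dtype=np.uint64), np.array(site_hi, dtype=np.uint64),
            n_hap)
        n_snps = config.n_sites
    else:
        mask_lo, mask_hi, br_len, t_total = _coalescent.simulate_branches(
            config.model, hap_sizes, config.n_sites, kernel_seed)
        cum = np.cumsum(br_len, axis=1)
        tot = cum[:, -1]
        locus_len = config.callable_length / config.n_sites
        n_mut = mut_rng.poisson(config.model.mu * locus_len * t_total)
        site_rep = np.repeat(np.arange(config.n_sites), n_mut)
        u = mut_rng.random(site_rep.size) * tot[site_rep]
        branch = (cum[site_rep] < u[:, None]).sum(axis=1)
        offset = np.concatenate([np.arange(k) for k in n_mut if k > 0]) if site_rep.size else \
            np.zeros(0, dtype=np.int64)
        pos = (site_rep * locus_len).astype(np.int64) + offset + 1
        n_snps = len(site_rep)
        hap = _coalescent.masks_to_haplotypes(
            mask_lo[site_rep, branch], mask_hi[site_rep, branch], n_hap)
    dosage = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)

    ref_idx = base_rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + base_rng.integers(1, 4, size=n_snps)) % 4
    n_dip = n_hap // 2
    mean_d, k_d = config.depth_model
    depth = depth_rng.negative_binomial(
        k_d, k_d / (k_d + mean_d), size=(n_snps, n_dip)).astype(np.int32)
    qual = np.maximum(qual_rng.normal(config.qual_model[0], config.qual_model[1], n_snps), 0.0)

    sites = pd.DataFrame({
        "chrom": "chr1", "pos": pos, "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
        "qual": np.round(qual, 2), "is_indel": False, "dist_indel": np.inf,
        "multiallelic": False,
    })
    samples = _sample_frame(config.model, config.samples_per_pop, species, elevation)
    geno = GenotypeMatrix(sites=sites, genotypes=dosage, samples=samples, depth=depth)

    truth = TruthRecord(model_params=_model_params(config.model),
                        samples_per_pop=config.samples_per_pop, seed=config.seed,
                        realized_snps=n_snps)
    if config.halfsib_pairs:
        pairs = []
        for pop, pair_id in config.halfsib_pairs:
            ids = [s for s, p in zip(geno.sample_ids, geno.populations) if p == pop]
            if len(ids) < 3:
                raise ValueError(
                    f"population {pop!r} needs >= 3 samples to plant half-sibs")
            pairs.append((ids[-2], ids[-1]))
            truth.pedigree.append({"pair_id": pair_id, "population": pop,
                                   "relationship": "half_sib",
                                   "samples": [ids[-2], ids[-1]]})
        geno = inject_halfsibs(geno, pairs, sib_seed)
    return geno, truth


# ---------------------------------------------------------------------------
# planted relatives

def _gametes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per site from a diploid dosage vector."""
    out = (genotypes // 2).astype(np.int8)
    het = genotypes == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def inject_halfsibs(geno: GenotypeMatrix, pair_spec, seed: int) -> GenotypeMatrix:
    """Replace designated sample pairs by simulated half-siblings.

    For each ``(sample_a, sample_b)`` pair (both from the same population),
    three virtual parents are drawn from Hardy-Weinberg proportions at the
    population's allele frequencies; the two designated samples become
    offspring sharing exactly one parent (gamete dropping).  All other
    samples are untouched; an empty ``pair_spec`` returns the matrix
    unchanged.
    """
    if not pair_spec:
        return geno
    rng = np.random.default_rng(seed)
    gts = geno.genotypes.copy()
    ids = geno.sample_ids
    pops = geno.populations
    for a, b in pair_spec:
        for s in (a, b):
            if s not in ids:
                raise ValueError(f"half-sib pair names unknown sample {s!r}")
        ia, ib = ids.index(a), ids.index(b)
        if pops[ia] != pops[ib]:
            raise ValueError(f"half-sib pair {a}/{b} spans two populations")
        cols = geno.pop_columns(pops[ia])
        if cols.size < 3:
            raise ValueError(
                f"population {pops[ia]!r} needs >= 3 samples to plant half-sibs")
        freq = geno.genotypes[:, cols].mean(axis=1) / 2.0
        parents = rng.binomial(2, freq[:, None], size=(geno.n_sites, 3)).astype(np.int8)
        shared, other_a, other_b = parents[:, 0], parents[:, 1], parents[:, 2]
        gts[:, ia] = _gametes(shared, rng) + _gametes(other_a, rng)
        gts[:, ib] = _gametes(shared, rng) + _gametes(other_b, rng)
    return GenotypeMatrix(sites=geno.sites, genotypes=gts, samples=geno.samples,
                          depth=geno.depth)


# ---------------------------------------------------------------------------
# covariate panel

def simulate_covariate_panel(n_species: int, floor_to_migration, base_model: DemographicModel,
                             seed: int, samples_per_pop: tuple[int, ...] = (10, 10),
                             n_sites: int = 2000,
                             floors: np.ndarray | None = None,
                             ) -> list[tuple[GenotypeMatrix, float, TruthRecord]]:
    """Simulate one dataset per species with migration tied to its
    elevational floor.

    ``floor_to_migration`` maps a floor in metres to a symmetric forward
    migration rate; a non-monotone mapping is accepted but flagged in each
    species' truth record.
    """
    if n_species < 5:
        raise ValueError(f"covariate panel needs >= 5 species, got {n_species}")
    if base_model.n_pops != 2:
        raise ValueError("covariate panel expects a two-population base model")
    if floors is None:
        floors = np.linspace(100.0, 3000.0, n_species)
    floors = np.asarray(floors, dtype=float)
    if floors.shape != (n_species,):
        raise ValueError("floors must have one entry per species")
    rates = np.array([float(floor_to_migration(f)) for f in floors])
    diffs = np.diff(rates[np.argsort(floors)])
    monotone = bool(np.all(diffs <= 0) or np.all(diffs >= 0))

    rng = np.random.default_rng(seed)
    out = []
    for i, (floor, m) in enumerate(zip(floors, rates)):
        mig = np.array([[0.0, m], [m, 0.0]])
        model = base_model.with_migration(mig)
        cfg = SimulationConfig(model=model, samples_per_pop=samples_per_pop,
                               n_sites=n_sites, callable_length=max(n_sites, 10 * n_sites),
                               seed=int(rng.integers(2 ** 31)))
        geno, truth = simulate_dataset(cfg, species=f"species_{i:02d}", elevation=floor)
        truth.elevation_floor = float(floor)
        truth.migration_rate = float(m)
        if not monotone:
            truth.flags["non_monotone_mapping"] = True
        out.append((geno, float(floor), truth))
    return out


# ---------------------------------------------------------------------------
# dataset bundle

def write_dataset(geno: GenotypeMatrix, truth: TruthRecord, outdir,
                  prefix: str = "dataset") -> dict[str, Path]:
    """Write the VCF, sample-map TSV and truth JSON for one dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "sample_map": outdir / f"{prefix}.samples.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_vcf(geno, paths["vcf"])
    write_sample_map(geno.samples, paths["sample_map"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
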