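"""End-to-end pipeline: filtering -> kinship -> structure -> SFS ->
demographic inference, driven by one declarative YAML configuration.

Every stage's settings are validated before any stage runs; all randomness
flows from named seeds in the config (a missing seed is an error, never an
implicit clock seed).  Re-running with an identical config reproduces
identical outputs.  A stage failure aborts with the stage name while the
outputs of completed stages stay on disk.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, relatedness, sfs, simulate, structure, variants
from .models import build_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative pipeline settings (see ``from_yaml``)."""

    output_dir: str
    seeds: dict
    input: dict = field(default_factory=dict)      # vcf+sample_map or simulate block
    filters: dict = field(default_factory=dict)
    kinship: dict = field(default_factory=dict)
    prune: dict = field(default_factory=dict)
    admixture: dict = field(default_factory=dict)
    sfs_options: dict = field(default_factory=dict)
    demography: dict = field(default_factory=dict)
    elevation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in (
            "output_dir", "seeds", "input", "filters", "kinship", "prune",
            "admixture", "sfs_options", "demography", "elevation")}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def validate(self) -> None:
        if not self.output_dir:
            raise ValueError("output_dir is required")
        if not isinstance(self.seeds, dict) or not self.seeds:
            raise ValueError("explicit seeds are required (no implicit clock seeds)")
        if "simulate" in self.input:
            sim = self.input["simulate"]
            for key in ("catalogue_id", "params", "samples_per_pop"):
                if key not in sim:
                    raise ValueError(f"input.simulate requires {key!r}")
            if "simulate" not in self.seeds:
                raise ValueError("seeds.simulate is required for simulated input")
        elif "vcf" in self.input:
            for key in ("vcf", "sample_map"):
                if key not in self.input:
                    raise ValueError(f"input requires {key!r}")
        else:
            raise ValueError("input must define either a 'simulate' block or 'vcf'")
        variants.SiteFilterConfig(**self.filters)
        if self.admixture:
            if self.admixture.get("k_max", 4) < 2:
                raise ValueError("admixture.k_max must be >= 2")
            if "admixture" not in self.seeds:
                raise ValueError("seeds.admixture is required when admixture runs")
        if self.demography.get("models") and "fit" not in self.seeds:
            raise ValueError("seeds.fit is required when demographic models are fitted")


def _log(lines: list[str], outdir: Path, msg: str) -> None:
    stamp = datetime.datetime.now(datetime.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    lines.append(f"{stamp}\t{msg}")
    (outdir / "pipeline.log").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order and write the report bundle."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"stages": []}

    def stage(name: str):
        def wrap(fn):
            _log(log, outdir, f"stage {name}: start")
            try:
                fn()
            except Exception as exc:  # persist completed outputs, then abort
                _log(log, outdir, f"stage {name}: FAILED: {exc}")
                (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
                raise PipelineError(name, exc) from exc
            report["stages"].append(name)
            _log(log, outdir, f"stage {name}: done")
        return wrap

    state: dict = {}

    @stage("input")
    def _input():
        if "simulate" in config.input:
            sim = config.input["simulate"]
            entry = build_model(sim["catalogue_id"],
                                tuple(sim.get("labels", ("pop1", "pop2"))))
            model = entry.instantiate(sim["params"])
            cfg = simulate.SimulationConfig(
                model=model, samples_per_pop=tuple(sim["samples_per_pop"]),
                n_sites=sim.get("n_sites", 5000),
                callable_length=sim.get("callable_length", 10_000_000),
                seed=int(config.seeds["simulate"]),
                halfsib_pairs=tuple(tuple(p) for p in sim.get("halfsib_pairs", [])),
                site_mode=sim.get("site_mode", "fixed_snps"))
            geno, truth = simulate.simulate_dataset(cfg)
            simulate.write_dataset(geno, truth, outdir, prefix="input")
        else:
            geno = variants.read_vcf(config.input["vcf"], config.input["sample_map"])
        state["geno_raw"] = geno

    @stage("filter")
    def _filter():
        cfg = variants.SiteFilterConfig(**config.filters)
        geno, counts = variants.filter_sites(state["geno_raw"], cfg)
        pd.Series(counts).rename("sites").to_csv(outdir / "filter_counts.tsv", sep="\t")
        report["filter"] = counts
        state["geno"] = geno

    @stage("kinship")
    def _kinship():
        thr = config.kinship.get("threshold", relatedness.RELATEDNESS_THRESHOLD)
        kin = relatedness.kinship_matrix(state["geno"])
        kin.to_frame().to_csv(outdir / "kinship.tsv", sep="\t")
        excluded = relatedness.flag_related(kin, threshold=thr)
        (outdir / "excluded_samples.txt").write_text("\n".join(excluded) + "\n")
        report["kinship"] = {"threshold": thr, "excluded": excluded}
        state["geno"] = state["geno"].drop_samples(excluded) if excluded else state["geno"]

    @stage("prune")
    def _prune():
        retained = structure.ld_prune(
            state["geno"],
            window_sites=config.prune.get("window_sites", 100),
            step_sites=config.prune.get("step_sites", 5),
            r2_threshold=config.prune.get("r2_threshold", 0.5))
        report["prune"] = {"retained": int(len(retained)),
                           "total": state["geno"].n_sites}
        state["geno_pruned"] = state["geno"].take_sites(retained)

    @stage("structure")
    def _structure():
        geno = state["geno_pruned"]
        pops = list(dict.fromkeys(geno.populations))
        fst_rows = []
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                res = structure.wc_fst(geno, (pops[i], pops[j]))
                fst_rows.append({"pop_a": pops[i], "pop_b": pops[j],
                                 "theta": res.theta, "theta_clamped": res.theta_clamped,
                                 "n_sites_used": res.n_sites_used})
        fst_df = pd.DataFrame(fst_rows)
        fst_df.to_csv(outdir / "fst.tsv", sep="\t", index=False)
        report["fst"] = fst_rows
        coords = structure.pca(geno)
        coords.to_frame().to_csv(outdir / "pca.tsv", sep="\t")
        if config.admixture:
            k_max = config.admixture.get("k_max", 4)
            n_rep = config.admixture.get("replicates", 10)
            rng = np.random.default_rng(int(config.seeds["admixture"]))
            runs = {}
            for k in range(1, k_max + 1):
                runs[k] = [structure.admixture_fit(geno, k, seed=int(rng.integers(2 ** 31)))
                           for _ in range(n_rep)]
                for rep, f in enumerate(runs[k]):
                    pd.DataFrame(f.q, index=geno.sample_ids).to_csv(
                        outdir / f"admixture_Q_K{k}_rep{rep}.tsv", sep="\t")
            table = structure.evanno_delta_k(runs)
            table.to_frame().to_csv(outdir / "evanno.tsv", sep="\t", index=False)
            report["evanno_best_k"] = table.best_k
            state["evanno"] = table

    @stage("sfs")
    def _sfs():
        geno = state["geno"]
        spec = sfs.joint_sfs(
            geno, folded=config.sfs_options.get("folded", True),
            callable_length=config.sfs_options.get("callable_length"))
        sfs.write_obs(spec, outdir / "observed.obs")
        report["sfs"] = {"segregating": spec.n_segregating,
                         "monomorphic": spec.monomorphic_count}
        state["obs"] = spec

    models = config.demography.get("models", [])
    if models:
        @stage("fit")
        def _fit():
            obs = state["obs"]
            rng = np.random.default_rng(int(config.seeds["fit"]))
            fits = []
            for mid in models:
                fit = demography.fit_model(
                    obs, mid, n_starts=config.demography.get("n_starts", 100),
                    seed=int(rng.integers(2 ** 31)),
                    search_reps=config.demography.get("search_reps", 1000),
                    refine_reps=config.demography.get("refine_reps", 10000))
                fits.append(fit)
            sel = demography.select_model(fits) if len(fits) > 1 else None
            ranked = sel.fits if sel else fits
            rows = []
            for f in ranked:
                row = {"model": f.model_id, "k": f.k, "lnCL": f.lnl, "AIC": f.aic}
                for lab, ne in f.derived["ne"].items():
                    row[f"Ne_{lab}"] = ne
                row["Ne_ancestral"] = f.params.get("ne_anc")
                row["T_DIV_years"] = f.derived.get("t_div_years")
                for key, m in f.derived["migration"].items():
                    row[f"M_{key}"] = m
                for key, nm in f.derived["nm_display"].items():
                    row[f"Nm_{key}"] = nm
                rows.append(row)
            pd.DataFrame(rows).to_csv(outdir / "demography.tsv", sep="\t", index=False)
            report["best_model"] = sel.best_id if sel else fits[0].model_id
            report["fits"] = [{"model": f.model_id, "lnCL": f.lnl, "AIC": f.aic,
                               "params": f.params} for f in ranked]
    else:
        _log(log, outdir, "no demographic models listed; stopping after sfs")

    if config.elevation.get("records"):
        @stage("elevation")
        def _elevation():
            from . import elevation as elev
            records = elev.read_records(config.elevation["records"])
            res = elev.spearman_fst_floor(
                records, exclude=config.elevation.get("exclude", ()),
                seed=int(config.seeds.get("elevation", 0)))
            res.to_frame().to_csv(outdir / "elevation.tsv", sep="\t", index=False)
            report["elevation"] = {"r": res.r, "p": res.p, "n": res.n}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    _log(log, outdir, "pipeline complete")
    return report
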