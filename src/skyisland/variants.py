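"""Genotype container, VCF I/O, and the SNP site filters.

The central container is :class:`GenotypeMatrix`: biallelic diploid
alt-allele dosages (sites x samples, values 0/1/2, -1 = missing) with site
metadata and per-sample read depths, plus the sample map (population,
elevation, species).  Site filtering mirrors a standard short-read
filtering recipe: per-sample depth bounds, a minimum site quality,
exclusion of sites near indels, biallelic-only, and no-missing-data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "GenotypeMatrix",
    "SiteFilterConfig",
    "read_vcf",
    "write_vcf",
    "read_sample_map",
    "write_sample_map",
    "filter_sites",
]

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "is_indel", "dist_indel", "multiallelic"]


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str
    elevation_m: float | None = None
    species: str | None = None


def _samples_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy().reset_index(drop=True)
    else:
        df = pd.DataFrame([{
            "sample_id": r.sample_id, "population": r.population,
            "elevation_m": r.elevation_m, "species": r.species,
        } for r in records])
    for col in ("elevation_m", "species"):
        if col not in df.columns:
            df[col] = None
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample ids: {', '.join(dupes)}")
    return df[["sample_id", "population", "elevation_m", "species"]]


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes with site and sample metadata."""

    sites: pd.DataFrame          # SITE_COLUMNS
    genotypes: np.ndarray        # (n_sites, n_samples) int8, -1 missing
    samples: pd.DataFrame        # sample_id, population, elevation_m, species
    depth: np.ndarray | None = None  # (n_sites, n_samples) int32, -1 unknown

    def __post_init__(self) -> None:
        self.samples = _samples_frame(self.samples)
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.genotypes.shape:
                raise ValueError("depth shape must match genotypes")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic accessors ----------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def populations(self) -> np.ndarray:
        return self.samples["population"].to_numpy()

    def sample_records(self) -> list[SampleRecord]:
        return [SampleRecord(r.sample_id, r.population,
                             None if pd.isna(r.elevation_m) else float(r.elevation_m),
                             None if pd.isna(r.species) else r.species)
                for r in self.samples.itertuples()]

    def pop_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples belonging to one population."""
        cols = np.flatnonzero(self.populations == label)
        if cols.size == 0:
            raise ValueError(f"no samples in population {label!r}")
        return cols

    # -- subsetting ----------------------------------------------------
    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx],
            genotypes=self.genotypes[idx],
            samples=self.samples,
            depth=None if self.depth is None else self.depth[idx])

    def drop_samples(self, sample_ids) -> "GenotypeMatrix":
        drop = set(sample_ids)
        missing = drop - set(self.sample_ids)
        if missing:
            raise ValueError(f"unknown samples: {', '.join(sorted(missing))}")
        keep = np.array([s not in drop for s in self.sample_ids])
        return GenotypeMatrix(
            sites=self.sites,
            genotypes=self.genotypes[:, keep],
            samples=self.samples.loc[keep],
            depth=None if self.depth is None else self.depth[:, keep])

    def equal_genotypes(self, other: "GenotypeMatrix") -> bool:
        return (self.sample_ids == other.sample_ids
                and self.n_sites == other.n_sites
                and bool(np.array_equal(self.genotypes, other.genotypes)))


# ---------------------------------------------------------------------------
# sample map I/O

def read_sample_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample map needs columns {sorted(required)}, got {list(df.columns)}")
    return _samples_frame(df)


def write_sample_map(samples: pd.DataFrame, path) -> None:
    _samples_frame(samples).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=skyisland
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a VCF v4.2 with GT:DP fields (1-based positions)."""
    buf = io.StringIO()
    buf.write(_VCF_HEADER)
    for chrom in geno.sites["chrom"].unique():
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(geno.sample_ids))
    buf.write("\n")
    gts = geno.genotypes
    dp = geno.depth
    for i, site in enumerate(geno.sites.itertuples()):
        qual = "." if pd.isna(site.qual) else f"{site.qual:.4g}"
        fields = [str(site.chrom), str(int(site.pos)), ".", site.ref, site.alt,
                  qual, "PASS", f"NS={int((gts[i] >= 0).sum())}", "GT:DP"]
        for j in range(geno.n_samples):
            d = "." if dp is None or dp[i, j] < 0 else str(int(dp[i, j]))
            fields.append(f"{_GT_STRINGS[int(gts[i, j])]}:{d}")
        buf.write("\t".join(fields))
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def _indel_distances(snp_chrom, snp_pos, indel_chrom, indel_pos) -> np.ndarray:
    """Distance from each SNP to the nearest indel record (inf if none)."""
    out = np.full(len(snp_pos), np.inf)
    indel_by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(indel_chrom):
        indel_by_chrom[c] = np.sort(indel_pos[indel_chrom == c])
    for c, ip in indel_by_chrom.items():
        mask = snp_chrom == c
        if not mask.any():
            continue
        p = snp_pos[mask]
        j = np.searchsorted(ip, p)
        left = np.where(j > 0, np.abs(p - ip[np.maximum(j - 1, 0)]), np.inf)
        right = np.where(j < len(ip), np.abs(ip[np.minimum(j, len(ip) - 1)] - p), np.inf)
        out[mask] = np.minimum(left, right)
    return out


def read_vcf(path, sample_map) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    ``sample_map`` is a path to a sample-map TSV or an equivalent
    DataFrame; every VCF sample must appear in it.  Indel records are used
    to annotate each SNP with the distance to its nearest indel and are
    then dropped from the matrix; multi-allelic SNPs are carried with a
    flag (removed later by :func:`filter_sites`).
    """
    from cyvcf2 import VCF

    if not isinstance(sample_map, pd.DataFrame):
        sample_map = read_sample_map(sample_map)
    sample_map = _samples_frame(sample_map)

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    known = set(sample_map["sample_id"])
    unmapped = [s for s in vcf_samples if s not in known]
    if unmapped:
        raise ValueError(
            f"VCF samples absent from the sample map: {', '.join(unmapped)}")
    samples = sample_map.set_index("sample_id").loc[vcf_samples].reset_index()

    rows = []
    gt_rows = []
    dp_rows = []
    for lineno, v in enumerate(vcf, start=1):
        alts = v.ALT if v.ALT else ["."]
        is_indel = bool(v.is_indel)
        multi = len(alts) > 1
        gt = np.asarray(v.gt_types, dtype=np.int8)
        if gt.shape[0] != len(vcf_samples):
            raise ValueError(f"malformed genotype row for record {lineno} "
                             f"({v.CHROM}:{v.POS}): {gt.shape[0]} calls")
        gt = np.where(gt == 3, np.int8(-1), gt)
        dp_fmt = v.format("DP")
        if dp_fmt is None:
            dp = np.full(len(vcf_samples), -1, dtype=np.int32)
        else:
            dp = dp_fmt.reshape(-1).astype(np.int32)
            dp = np.where(dp < 0, -1, dp)
        rows.append((v.CHROM, int(v.POS), v.REF, ",".join(alts),
                     np.nan if v.QUAL is None else float(v.QUAL), is_indel, np.inf, multi))
        gt_rows.append(gt)
        dp_rows.append(dp)
    vcf.close()

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    gts = np.array(gt_rows, dtype=np.int8) if gt_rows else np.zeros((0, len(vcf_samples)), np.int8)
    dps = np.array(dp_rows, dtype=np.int32) if dp_rows else np.zeros((0, len(vcf_samples)), np.int32)

    indels = sites["is_indel"].to_numpy()
    if indels.any():
        dist = _indel_distances(sites["chrom"].to_numpy(), sites["pos"].to_numpy(),
                                sites.loc[indels, "chrom"].to_numpy(),
                                sites.loc[indels, "pos"].to_numpy())
        sites["dist_indel"] = dist
    keep = ~indels
    return GenotypeMatrix(sites=sites.loc[keep], genotypes=gts[keep],
                          samples=samples, depth=dps[keep])


# ---------------------------------------------------------------------------
# site filters

@dataclass
class SiteFilterConfig:
    """Thresholds for the SNP site filters.

    Depth bounds are inclusive of the endpoints (a site fails when depth is
    strictly below ``min_depth`` or strictly above ``max_depth``); quality
    fails strictly below ``min_qual``.  ``depth_mode`` selects whether the
    depth rule applies to each sample's depth ("per_sample", default) or to
    the site's summed depth ("site_sum").
    """

    min_depth: int = 10
    max_depth: int = 100
    min_qual: float = 20.0
    indel_proximity_bp: int = 5
    biallelic_only: bool = True
    require_complete: bool = True
    depth_mode: str = "per_sample"

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if min(self.min_depth, self.min_qual, self.indel_proximity_bp) < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.depth_mode not in ("per_sample", "site_sum"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")


def filter_sites(geno: GenotypeMatrix, cfg: SiteFilterConfig | None = None,
                 ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply all site filters simultaneously.

    Returns the surviving matrix and per-rule removal counts; a site
    violating several rules is counted under each of them, so the union of
    the violation sets (not the sum of counts) equals the removed total.
    """
    if cfg is None:
        cfg = SiteFilterConfig()
    n = geno.n_sites
    violations: dict[str, np.ndarray] = {}

    if geno.depth is not None:
        if cfg.depth_mode == "per_sample":
            known = geno.depth >= 0
            bad = known & ((geno.depth < cfg.min_depth) | (geno.depth > cfg.max_depth))
            violations["depth"] = bad.any(axis=1)
        else:
            total = np.where(geno.depth >= 0, geno.depth, 0).sum(axis=1)
            violations["depth"] = (total < cfg.min_depth) | (total > cfg.max_depth)
    qual = geno.sites["qual"].to_numpy(dtype=float)
    violations["qual"] = ~np.isnan(qual) & (qual < cfg.min_qual)
    violations["indel_proximity"] = (
        geno.sites["dist_indel"].to_numpy(dtype=float) <= cfg.indel_proximity_bp)
    if cfg.biallelic_only:
        violations["multiallelic"] = geno.sites["multiallelic"].to_numpy(dtype=bool)
    if cfg.require_complete:
        violations["missing"] = (geno.genotypes < 0).any(axis=1)

    removed = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for rule, mask in violations.items():
        counts[rule] = int(mask.sum())
        removed |= mask
    counts["removed_total"] = int(removed.sum())
    counts["retained"] = int(n - removed.sum())
    return geno.take_sites(~removed), counts
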