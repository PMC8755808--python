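"""Population structure: LD pruning, Weir-Cockerham FST, PCA, maximum-
likelihood admixture proportions, and the Evanno delta-K statistic.

FST follows the Weir & Cockerham variance-component estimator: per-site
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed from sample sizes, allele
frequencies and observed heterozygosities, and the multilocus estimate is
the ratio of sums theta = sum(a) / sum(a+b+c) — not a mean of per-site
ratios.

The admixture model is the standard binomial ancestry mixture (genotype
dosage g_ij ~ Binomial(2, sum_k q_ik p_kj)), fitted by EM, whose
log-likelihood is monotone non-decreasing per iteration.  Replicate
multi-start fits across K feed the Evanno delta-K table used to choose the
supported number of clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variants import GenotypeMatrix

__all__ = [
    "ld_prune", "FstResult", "wc_fst", "fst_by_stratum",
    "PcaResult", "GenotypePCA", "pca",
    "AdmixtureFit", "AdmixtureModel", "admixture_fit",
    "EvannoTable", "evanno_delta_k", "evanno_from_stats",
]


def _dosage(geno) -> np.ndarray:
    if isinstance(geno, GenotypeMatrix):
        return geno.genotypes.astype(np.float64)
    return np.asarray(geno, dtype=np.float64)


# ---------------------------------------------------------------------------
# LD pruning

def ld_prune(geno, window_sites: int = 100, step_sites: int = 5,
             r2_threshold: float = 0.5) -> np.ndarray:
    """Sliding-window LD pruning on genotype dosages (composite r^2).

    Within each window of ``window_sites`` consecutive sites (advanced by
    ``step_sites``), pairs of retained sites with squared dosage
    correlation above ``r2_threshold`` lose their later member; the earlier
    site is kept.  Monomorphic sites have undefined correlation, treated as
    r^2 = 0 (always retained).  Returns the retained site indices.
    """
    g = _dosage(geno)
    if np.any(g < 0):
        raise ValueError("LD pruning requires complete genotypes")
    n_sites = g.shape[0]
    removed = np.zeros(n_sites, dtype=bool)
    if n_sites == 0:
        return np.zeros(0, dtype=np.int64)
    start = 0
    while True:
        stop = min(start + window_sites, n_sites)
        win = np.arange(start, stop)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(g[win])
        r2 = np.nan_to_num(r, nan=0.0) ** 2
        for a in range(len(win)):
            if removed[win[a]]:
                continue
            for b in range(a + 1, len(win)):
                if removed[win[b]]:
                    continue
                if r2[a, b] > r2_threshold:
                    removed[win[b]] = True
        if stop >= n_sites:
            break
        start += step_sites
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST

@dataclass
class FstResult:
    pair: tuple[str, str]
    a: np.ndarray                 # per-site among-population component
    b: np.ndarray
    c: np.ndarray
    used: np.ndarray              # per-site inclusion mask
    theta: float = field(init=False)
    theta_clamped: float = field(init=False)

    def __post_init__(self) -> None:
        denom = (self.a + self.b + self.c)[self.used].sum()
        num = self.a[self.used].sum()
        self.theta = float(num / denom) if denom != 0 else float("nan")
        self.theta_clamped = max(self.theta, 0.0) if np.isfinite(self.theta) else self.theta

    @property
    def per_site(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.used, self.a / (self.a + self.b + self.c), np.nan)

    @property
    def n_sites_used(self) -> int:
        return int(self.used.sum())

    @property
    def n_sites_excluded(self) -> int:
        return int((~self.used).sum())


def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-site Weir-Cockerham variance components for two populations.

    ``g1``/``g2`` are (sites x diploids) dosage arrays without missing
    calls.  Returns (a, b, c, used): sites monomorphic in the pooled sample
    are excluded.
    """
    r = 2.0
    n1, n2 = g1.shape[1], g2.shape[1]
    p1 = g1.mean(axis=1) / 2.0
    p2 = g2.mean(axis=1) / 2.0
    h1 = (g1 == 1).mean(axis=1)
    h2 = (g2 == 1).mean(axis=1)

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    used = (pbar > 0) & (pbar < 1)
    return a, b, c, used


def wc_fst(geno: GenotypeMatrix, pop_labels: tuple[str, str] | None = None) -> FstResult:
    """Multilocus Weir-Cockerham FST between exactly two populations."""
    if pop_labels is None:
        uniq = list(dict.fromkeys(geno.populations))
        if len(uniq) != 2:
            raise ValueError(f"exactly two populations required, found {uniq}")
        pop_labels = (uniq[0], uniq[1])
    c1 = geno.pop_columns(pop_labels[0])
    c2 = geno.pop_columns(pop_labels[1])
    if len(c1) < 2 or len(c2) < 2:
        raise ValueError("each population needs at least 2 diploids")
    g = geno.genotypes
    if np.any(g[:, np.concatenate([c1, c2])] < 0):
        raise ValueError("FST requires complete genotypes (run filters first)")
    a, b, c, used = _wc_components(g[:, c1].astype(float), g[:, c2].astype(float))
    return FstResult(pair=tuple(pop_labels), a=a, b=b, c=c, used=used)


def fst_by_stratum(geno: GenotypeMatrix, stratum_labels, min_size: int = 2) -> pd.DataFrame:
    """Pairwise Weir-Cockerham FST between all strata (e.g. elevation bands).

    Strata with fewer than ``min_size`` diploids appear with an undefined
    (NaN) estimate rather than being dropped.  A single stratum yields an
    empty table with a warning.
    """
    stratum_labels = np.asarray(stratum_labels)
    if stratum_labels.shape[0] != geno.n_samples:
        raise ValueError("one stratum label per sample required")
    strata = list(dict.fromkeys(stratum_labels))
    if len(strata) < 2:
        warnings.warn("fewer than two strata; empty FST table", stacklevel=2)
        return pd.DataFrame(columns=["stratum_a", "stratum_b", "n_a", "n_b",
                                     "theta", "n_sites_used"])
    rows = []
    for i in range(len(strata)):
        for j in range(i + 1, len(strata)):
            ca = np.flatnonzero(stratum_labels == strata[i])
            cb = np.flatnonzero(stratum_labels == strata[j])
            row = {"stratum_a": strata[i], "stratum_b": strata[j],
                   "n_a": len(ca), "n_b": len(cb),
                   "theta": np.nan, "n_sites_used": 0}
            if len(ca) >= min_size and len(cb) >= min_size:
                a, b, c, used = _wc_components(
                    geno.genotypes[:, ca].astype(float), geno.genotypes[:, cb].astype(float))
                denom = (a + b + c)[used].sum()
                row["theta"] = float(a[used].sum() / denom) if denom != 0 else np.nan
                row["n_sites_used"] = int(used.sum())
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    coords: np.ndarray              # (samples, axes)
    variance_explained: np.ndarray  # fraction per axis, non-increasing
    loadings: np.ndarray            # (axes, sites)
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


class GenotypePCA(BaseEstimator, TransformerMixin):
    """PCA of centered, variance-standardized genotype dosages.

    Zero-variance sites are skipped; axis signs are fixed by making the
    first nonzero loading of each component positive, so results are
    deterministic.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, geno, y=None) -> "GenotypePCA":
        x = _dosage(geno)
        if np.any(x < 0):
            raise ValueError("PCA requires complete genotypes")
        n_samples = x.shape[1]
        if n_samples < 3:
            raise ValueError("PCA needs at least 3 samples")
        x = x.T  # samples x sites
        std = x.std(axis=0, ddof=0)
        keep = std > 0
        self._keep_ = keep
        xs = (x[:, keep] - x[:, keep].mean(axis=0)) / std[keep]
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        ncomp = self.n_components or min(n_samples, int(keep.sum()))
        u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
        for k in range(vt.shape[0]):
            nz = np.flatnonzero(np.abs(vt[k]) > 1e-12)
            if nz.size and vt[k, nz[0]] < 0:
                vt[k] *= -1.0
                u[:, k] *= -1.0
        self.coords_ = u * s
        total = (s ** 2).sum()
        self.variance_explained_ = (s ** 2) / total if total > 0 else np.zeros_like(s)
        self.components_ = vt
        self.mean_ = xs.mean(axis=0)
        return self

    def transform(self, geno) -> np.ndarray:
        x = _dosage(geno).T
        x = x[:, self._keep_]
        xs = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0, ddof=0), 1e-12)
        return xs @ self.components_.T


def pca(geno: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    est = GenotypePCA(n_components=n_components).fit(geno)
    ids = geno.sample_ids if isinstance(geno, GenotypeMatrix) else \
        [f"s{i}" for i in range(est.coords_.shape[0])]
    return PcaResult(coords=est.coords_, variance_explained=est.variance_explained_,
                     loadings=est.components_, sample_ids=ids)


# ---------------------------------------------------------------------------
# admixture

_P_EPS = 1e-9


@dataclass
class AdmixtureFit:
    k: int
    q: np.ndarray        # samples x K ancestry proportions (rows sum to 1)
    p: np.ndarray        # K x sites cluster allele frequencies
    lnl: float
    seed: int
    iterations: int
    converged: bool
    lnl_path: np.ndarray


def _admixture_lnl(g: np.ndarray, q: np.ndarray, p: np.ndarray) -> float:
    f = np.clip(q @ p, _P_EPS, 1 - _P_EPS)
    return float((g * np.log(f) + (2 - g) * np.log(1 - f)).sum())


class AdmixtureModel(BaseEstimator):
    """Maximum-likelihood admixture proportions by EM.

    The model: each individual's alleles are independent draws from K
    cluster allele-frequency vectors mixed by its ancestry proportions
    (genotype dosage binomial in sum_k q_ik p_kj).  EM (block relaxation of
    Q and P) makes the log-likelihood monotone non-decreasing.  Replicate
    runs differ by ``random_state``; their dispersion feeds the Evanno
    delta-K statistic.
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 500, tol: float = 1e-4,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, geno, y=None) -> "AdmixtureModel":
        g = _dosage(geno).T  # samples x sites
        if np.any(g < 0):
            raise ValueError("admixture requires complete genotypes")
        n, m = g.shape
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds sample count {n}")
        rng = np.random.default_rng(self.random_state)
        q = rng.dirichlet(np.ones(k), size=n)
        p = np.clip(rng.uniform(0.05, 0.95, size=(k, m)), _P_EPS, 1 - _P_EPS)
        if k == 1:
            p = np.clip(g.mean(axis=0, keepdims=True) / 2.0, _P_EPS, 1 - _P_EPS)
            q = np.ones((n, 1))
        lnl = _admixture_lnl(g, q, p)
        path = [lnl]
        converged = k == 1
        it = 0
        for it in range(1, self.max_iter + 1):
            if k == 1:
                break
            f = np.clip(q @ p, _P_EPS, 1 - _P_EPS)
            # responsibilities: expected derived / ancestral allele counts
            ra = g / f          # n x m
            rb = (2 - g) / (1 - f)
            # per-cluster expected allele counts
            a_num = p * (q.T @ ra)            # k x m derived-allele counts
            b_num = (1 - p) * (q.T @ rb)      # k x m ancestral-allele counts
            p = np.clip(a_num / np.maximum(a_num + b_num, _P_EPS), _P_EPS, 1 - _P_EPS)
            # update Q holding new P's responsibilities
            f = np.clip(q @ p, _P_EPS, 1 - _P_EPS)
            ra = g / f
            rb = (2 - g) / (1 - f)
            q_new = q * (ra @ p.T + rb @ (1 - p).T) / (2.0 * m)
            q = q_new / q_new.sum(axis=1, keepdims=True)
            new_lnl = _admixture_lnl(g, q, p)
            path.append(new_lnl)
            if abs(new_lnl - lnl) < self.tol:
                lnl = new_lnl
                converged = True
                break
            lnl = new_lnl
        self.q_ = q
        self.p_ = p
        self.lnl_ = lnl
        self.n_iter_ = it
        self.converged_ = converged
        self.lnl_path_ = np.array(path)
        return self


def admixture_fit(geno, k: int, seed: int = 0, max_iter: int = 500,
                  tol: float = 1e-4) -> AdmixtureFit:
    est = AdmixtureModel(n_clusters=k, max_iter=max_iter, tol=tol,
                         random_state=seed).fit(geno)
    return AdmixtureFit(k=k, q=est.q_, p=est.p_, lnl=est.lnl_, seed=seed,
                        iterations=est.n_iter_, converged=est.converged_,
                        lnl_path=est.lnl_path_)


# ---------------------------------------------------------------------------
# Evanno delta-K

_SD_FLOOR = 1e-6


@dataclass
class EvannoTable:
    ks: np.ndarray
    mean_lnl: np.ndarray
    sd_lnl: np.ndarray
    delta_k: np.ndarray      # NaN at the range endpoints
    best_k: int | None
    sd_floor_applied: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.ks, "mean_lnL": self.mean_lnl,
                             "sd_lnL": self.sd_lnl, "delta_K": self.delta_k})


def evanno_from_stats(ks, mean_lnl, sd_lnl) -> EvannoTable:
    """Delta-K from per-K replicate means and standard deviations.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K);
    undefined at the endpoints.  Zero standard deviations receive a small
    floor (recorded) rather than producing a division failure.
    """
    ks = np.asarray(ks, dtype=int)
    mean_lnl = np.asarray(mean_lnl, dtype=float)
    sd_lnl = np.asarray(sd_lnl, dtype=float)
    if not np.all(np.diff(ks) == 1):
        raise ValueError("K values must be consecutive")
    floor_applied = bool(np.any(sd_lnl < _SD_FLOOR))
    sd = np.maximum(sd_lnl, _SD_FLOOR)
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        delta[i] = abs(mean_lnl[i + 1] - 2 * mean_lnl[i] + mean_lnl[i - 1]) / sd[i]
    interior = np.flatnonzero(np.isfinite(delta))
    best = int(ks[interior[np.argmax(delta[interior])]]) if interior.size else None
    return EvannoTable(ks=ks, mean_lnl=mean_lnl, sd_lnl=sd_lnl, delta_k=delta,
                       best_k=best, sd_floor_applied=floor_applied)


def evanno_delta_k(runs: dict[int, list[AdmixtureFit]]) -> EvannoTable:
    """Evanno table from replicate admixture fits per K (K ascending)."""
    ks = sorted(runs)
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"K={k} needs at least 2 replicate fits")
    mean = [float(np.mean([f.lnl for f in runs[k]])) for k in ks]
    sd = [float(np.std([f.lnl for f in runs[k]], ddof=1)) for k in ks]
    return evanno_from_stats(ks, mean, sd)
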