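"""Demographic model fitting on the joint SFS.

The machinery mirrors the classic SFS model-testing workflow: for a
candidate model, the expected joint SFS is obtained by coalescent
simulation (branch-length weighting: the probability that a mutation
produces sample configuration c is proportional to the expected total
length of branches subtending exactly that partition), the fit to the
observed spectrum is scored with the composite multinomial likelihood
lnCL = sum_c m_c ln p_c, parameters are optimized by bounded multi-start
Nelder-Mead on log-transformed parameters with common random numbers (the
expected-SFS seed is fixed within a fit, so the likelihood surface is
deterministic), and models are ranked by AIC = 2k - 2 lnCL.

When the observed spectrum carries monomorphic mass (callable length), the
probability of a site being non-segregating, 1 - mu * E[total tree
length], enters the likelihood and absolute parameters (Ne in diploids, T
in generations) are identifiable at fixed mu; otherwise cell probabilities
are normalized over polymorphic cells and only scaled parameters are
meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._coalescent import EventBudgetExceeded, expected_branch_lengths
from .models import (CATALOGUE_IDS, GENERATION_TIME, MU_PASSERINE,
                     CatalogueEntry, DemographicModel, build_model)
from .sfs import JointSFS, _fold_cell

__all__ = [
    "ExpectedSFS", "expected_sfs", "composite_loglik",
    "FitResult", "fit_model", "ModelSelection", "select_model",
    "derive_quantities", "bootstrap_ci",
]


# ---------------------------------------------------------------------------
# expected SFS

@dataclass
class ExpectedSFS:
    pops: tuple[str, ...]
    hap_sizes: tuple[int, ...]
    probs: np.ndarray               # cell probabilities over the SFS array
    folded: bool
    includes_monomorphic: bool
    p_monomorphic: float            # probability mass of a non-segregating site
    n_replicates: int
    seed: int
    mc_stderr: np.ndarray
    mean_total_length: float        # generations
    p_monomorphic_se: float = 0.0   # MC standard error of p_monomorphic

    @property
    def floor(self) -> float:
        return 1.0 / (10.0 * self.n_replicates * self.probs.size)


def _fold_array(arr: np.ndarray, hap_sizes: tuple[int, ...]) -> np.ndarray:
    from itertools import product
    out = np.zeros_like(arr)
    for cell in product(*(range(h + 1) for h in hap_sizes)):
        out[_fold_cell(cell, hap_sizes)] += arr[cell]
    return out


def _corner_mask(shape: tuple[int, ...]) -> np.ndarray:
    mask = np.ones(shape, dtype=bool)
    mask[(0,) * len(shape)] = False
    mask[tuple(s - 1 for s in shape)] = False
    return mask


def expected_sfs(model: DemographicModel, hap_sizes, n_replicates: int, seed: int,
                 folded: bool = True, include_monomorphic: bool = False,
                 max_events_per_rep: int | None = None) -> ExpectedSFS:
    """Model-expected joint SFS by coalescent simulation.

    Cell probabilities are proportional to expected branch lengths per
    sample configuration; with ``include_monomorphic`` they are absolute
    per-site probabilities ``mu * E[length_c]`` with the remaining mass on
    the monomorphic class, otherwise they are normalized over polymorphic
    cells.  A small floor keeps every cell strictly positive for the
    likelihood.  Fixed seed implies identical output.
    """
    if n_replicates < 100:
        warnings.warn("fewer than 100 expected-SFS replicates: Monte-Carlo "
                      "error will dominate", stacklevel=2)
    hap_sizes = tuple(int(h) for h in hap_sizes)
    mean_len, stderr, t_total, t_total_se = expected_branch_lengths(
        model, hap_sizes, n_replicates, seed, max_events_per_rep=max_events_per_rep)
    if folded:
        mean_len = _fold_array(mean_len, hap_sizes)
        stderr = np.sqrt(_fold_array(stderr ** 2, hap_sizes))
    poly = _corner_mask(mean_len.shape)
    probs = np.zeros_like(mean_len)
    p_mono_se = 0.0
    if include_monomorphic:
        probs[poly] = model.mu * mean_len[poly]
        p_mono = max(1.0 - probs.sum(), 0.0)
        stderr = model.mu * stderr
        p_mono_se = model.mu * t_total_se
    else:
        tot = mean_len[poly].sum()
        probs[poly] = mean_len[poly] / tot if tot > 0 else 0.0
        stderr = stderr / tot if tot > 0 else stderr
        p_mono = 0.0
    floor = 1.0 / (10.0 * n_replicates * probs.size)
    probs[poly] = np.maximum(probs[poly], floor)
    return ExpectedSFS(pops=tuple(model.labels), hap_sizes=hap_sizes, probs=probs,
                       folded=folded, includes_monomorphic=include_monomorphic,
                       p_monomorphic=p_mono, n_replicates=n_replicates, seed=seed,
                       mc_stderr=stderr, mean_total_length=t_total,
                       p_monomorphic_se=p_mono_se)


def composite_loglik(obs: JointSFS, exp: ExpectedSFS) -> float:
    """Composite multinomial log-likelihood sum_c m_c ln p_c.

    The monomorphic class enters exactly when the observed spectrum
    carries monomorphic mass and the expectation models it; zero-count
    cells contribute exactly zero.
    """
    if obs.counts.shape != exp.probs.shape:
        raise ValueError(f"cell mismatch: obs {obs.counts.shape} vs exp {exp.probs.shape}")
    if obs.folded != exp.folded:
        raise ValueError("folding state mismatch between observed and expected SFS")
    poly = _corner_mask(obs.counts.shape)
    m = obs.counts[poly]
    p = exp.probs[poly]
    nz = m > 0
    lnl = float((m[nz] * np.log(p[nz])).sum())
    # first-order Monte-Carlo debiasing: E[ln p_hat] = ln p - Var(p_hat)/(2 p^2),
    # and the bias varies systematically across parameter space (deep-tree
    # regions have different relative cell variances), so the raw simulated
    # likelihood would tilt parameter comparisons; add the Jensen term back
    se = exp.mc_stderr[poly]
    lnl += float((m[nz] * (se[nz] ** 2) / (2.0 * p[nz] ** 2)).sum())
    if obs.monomorphic_count is not None and exp.includes_monomorphic:
        if obs.monomorphic_count > 0:
            p0 = max(exp.p_monomorphic, 1e-300)
            lnl += float(obs.monomorphic_count) * np.log(p0)
            lnl += float(obs.monomorphic_count) * exp.p_monomorphic_se ** 2 / (2.0 * p0 ** 2)
    return lnl


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    model_id: str
    labels: tuple[str, ...]
    params: dict                    # all parameters, free and fixed
    free_names: tuple[str, ...]
    lnl: float
    k: int
    mu: float
    generation_time: float
    obs_key: tuple
    diagnostics: dict = field(default_factory=dict)
    aic: float = field(init=False)
    derived: dict = field(init=False)

    def __post_init__(self) -> None:
        self.aic = 2.0 * self.k - 2.0 * self.lnl
        self.derived = derive_quantities(self, self.mu, self.generation_time)

    def to_model(self) -> DemographicModel:
        entry = build_model(self.model_id, self.labels, self.mu, self.generation_time)
        return entry.instantiate(self.params)


def _obs_key(obs: JointSFS) -> tuple:
    return (obs.pops, obs.hap_sizes, obs.folded, round(obs.total, 6),
            None if obs.monomorphic_count is None else round(obs.monomorphic_count, 6))


def _objective(entry: CatalogueEntry, obs: JointSFS, n_reps: int, kernel_seed: int,
               max_events_per_rep: int = 3000):
    include_mono = obs.monomorphic_count is not None

    def fun(x: np.ndarray) -> float:
        x, _ = entry.space.clip_vector(x)
        values = entry.space.from_vector(x)
        try:
            model = entry.instantiate(values)
            exp = expected_sfs(model, obs.hap_sizes, n_reps, kernel_seed,
                               folded=obs.folded, include_monomorphic=include_mono,
                               max_events_per_rep=max_events_per_rep)
        except (ValueError, EventBudgetExceeded):
            return 1e300
        return -composite_loglik(obs, exp)

    return fun


def _moment_starts(obs: JointSFS, entry: CatalogueEntry) -> list[dict]:
    """Data-informed starting values from diversity and divergence moments.

    Per-population Ne from Watterson's theta on the marginal spectra;
    divergence time either from net between-population divergence (d_xy
    minus mean within-population diversity, appropriate without migration)
    or from raw d_xy (appropriate when migration erodes net divergence);
    migration either negligible or from the island-model heuristic
    Nm = (1/FST - 1)/4.  Needs monomorphic mass (an absolute site count);
    returns several variants to seed the multi-start search.
    """
    if obs.monomorphic_count is None:
        return []
    mu = entry.mu
    length = obs.total + obs.monomorphic_count
    npop = len(obs.pops)

    ne = []
    pi = []
    for i in range(npop):
        marg = obs.marginal(i)
        h = marg.hap_sizes[0]
        counts = marg.counts.copy()
        s_i = counts[1:h].sum()
        a_h = sum(1.0 / j for j in range(1, h))
        theta = max(s_i / (length * a_h), 1e-12)
        ne.append(theta / (4.0 * mu))
        freqs = np.arange(h + 1) / h
        pi.append(float((counts * 2 * freqs * (1 - freqs) * h / (h - 1)).sum()) / length)

    def dxy(i: int, j: int) -> float:
        axes = tuple(a for a in range(npop) if a not in (i, j))
        joint = obs.counts.sum(axis=axes) if axes else obs.counts
        hi, hj = obs.hap_sizes[i], obs.hap_sizes[j]
        x = (np.arange(hi + 1) / hi)[:, None]
        y = (np.arange(hj + 1) / hj)[None, :]
        jj = joint if (i < j or npop == 2) else joint.T
        if jj.shape != (hi + 1, hj + 1):
            jj = jj.T
        return float((jj * (x * (1 - y) + y * (1 - x))).sum()) / length

    def t_split(i: int, j: int, net: bool) -> float:
        d = dxy(i, j) - (0.5 * (pi[i] + pi[j]) if net else 0.0)
        return max(d / (2.0 * mu), 500.0)

    def m_fst(i: int, j: int) -> float:
        d = dxy(i, j)
        fst = 1.0 - 0.5 * (pi[i] + pi[j]) / d if d > 0 else 1.0
        fst = min(max(fst, 1e-3), 1.0 - 1e-3)
        nm = (1.0 / fst - 1.0) / 4.0
        return nm / max(ne[i], 1.0)

    variants = []
    for t_net in (True, False):
        for mig_scaled in (True, False):
            values: dict = {}
            for p in entry.space.free:
                name = p.name
                if name.startswith("ne_anc"):
                    v = float(np.mean(ne))
                elif name.startswith("ne"):
                    v = ne[int(name[2]) - 1]
                elif name in ("t_div", "t1"):
                    v = t_split(0, 1, t_net)
                elif name == "t2":
                    v = max(t_split(0, 2, t_net), t_split(1, 2, t_net),
                            t_split(0, 1, t_net))
                elif name == "t_event":
                    v = 0.5 * t_split(0, 1, t_net)
                elif name.startswith("m"):
                    v = m_fst(int(name[1]) - 1, int(name[2]) - 1) if mig_scaled else 1e-8
                elif name.startswith("g"):
                    v = 0.0
                elif name.startswith("ratio"):
                    v = float(np.sqrt(p.lower * p.upper)) if p.lower > 0 else 1.0
                else:
                    v = float(np.sqrt(p.lower * p.upper)) if p.log_scale \
                        else 0.5 * (p.lower + p.upper)
                values[name] = min(max(v, p.lower), p.upper)
            variants.append(values)
    return variants


def _quadratic_surface_min(pts: np.ndarray, vals: np.ndarray, span: float,
                           ) -> np.ndarray:
    """Least-squares quadratic fit over 2-D scan points; its minimum
    clipped to the scan box (falls back to the pointwise argmin when the
    fitted surface is not convex)."""
    t, a = pts[:, 0], pts[:, 1]
    design = np.column_stack([np.ones_like(t), t, a, t * t, a * a, t * a])
    c = np.linalg.lstsq(design, vals, rcond=None)[0]
    hess = np.array([[2 * c[3], c[5]], [c[5], 2 * c[4]]])
    if np.all(np.linalg.eigvalsh(hess) > 0):
        step = np.linalg.solve(hess, -c[1:3])
    else:
        step = pts[int(np.argmin(vals))]
    return np.clip(step, -span, span)


def fit_model(obs: JointSFS, catalogue_id: str, n_starts: int = 100, seed: int = 0,
              search_reps: int = 1500, refine_reps: int = 10000,
              search_maxfev: int = 150, refine_maxfev: int = 100,
              refine_top: int = 4, mu: float = MU_PASSERINE,
              generation_time: float = GENERATION_TIME,
              start_values: list[dict] | None = None,
              ridge_scan: bool = True,
              max_events_per_rep: int = 3000,
              n_refine: int = 2,
              scan_spans: tuple = (0.12, 0.06)) -> FitResult:
    """Fit one catalogue model to an observed spectrum.

    Multi-start bounded Nelder-Mead on log-transformed parameters: every
    start draws initial values from the parameter space (log-uniform where
    flagged) and is refined on a likelihood surface made deterministic by
    a fixed expected-SFS seed (common random numbers).  The search stage
    uses ``search_reps`` coalescent replicates per evaluation; the
    ``refine_top`` best starts are polished at ``refine_reps`` replicates
    and the best end point is reported.
    """
    if len(obs.pops) not in (2, 3):
        raise ValueError("model fitting requires a 2- or 3-population spectrum")
    entry = build_model(catalogue_id, obs.pops, mu, generation_time)
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(2 ** 31))
    # drawn second so fits of different models with one seed share it
    final_eval_seed = int(rng.integers(2 ** 31))
    # growth jitter is kept small: large growth rates compound over the
    # divergence time and create pathological basins
    jitter_sd = np.array([0.5 if p.log_scale else 0.01 * (p.upper - p.lower)
                          for p in entry.space.free])
    t_mults = (0.3, 1.0, 3.0)
    if start_values is not None:
        starts = [entry.space.clip_vector(entry.space.to_vector(v))[0]
                  for v in start_values]
        buckets = [len(t_mults)] * len(starts)  # nothing pinned for explicit starts
    else:
        # moment-based starts swept over a divergence-time grid (the
        # likelihood ridge along T is the hard search direction), jittered
        # copies, and pure random draws; each start remembers its T bucket
        # so that every divergence-time regime gets a polished candidate
        starts = []
        buckets = []
        moments = []
        moment_buckets = []
        t_keys = ("t_div", "t1", "t2", "t_event")
        for base in _moment_starts(obs, entry):
            for bi, mult in enumerate(t_mults):
                v = dict(base)
                for key in t_keys:
                    if key in v:
                        v[key] = v[key] * mult
                moments.append(v)
                moment_buckets.append(bi)
        moment_vecs = [entry.space.clip_vector(entry.space.to_vector(m))[0]
                       for m in moments]
        starts.extend(moment_vecs[:n_starts])
        buckets.extend(moment_buckets[:n_starts])
        if moment_vecs:
            n_jitter = max((4 * n_starts) // 5 - len(starts), 0)
            for i in range(n_jitter):
                j = i % len(moment_vecs)
                x = moment_vecs[j] + rng.normal(0.0, jitter_sd)
                starts.append(entry.space.clip_vector(x)[0])
                buckets.append(moment_buckets[j])
        while len(starts) < n_starts:
            starts.append(entry.space.to_vector(entry.space.sample(rng)))
            buckets.append(len(t_mults))  # random-draw bucket
    if not starts:
        raise ValueError("at least one start required")

    # informed starts are optimized with growth pinned at zero (a homotopy:
    # free growth opens pathological short-T basins whose Monte-Carlo noise
    # flatters the likelihood); random starts explore the full space
    names = list(entry.space.names)
    growth_dims = np.array([n.startswith("g") for n in names])
    n_random_bucket = len(t_mults)

    def _nm(fun, x0, maxfev, scale, pinned):
        free = ~pinned if pinned.any() else np.ones(len(x0), dtype=bool)

        def sub(y):
            x = x0.copy()
            x[free] = y
            return fun(x)

        steps = np.array([scale if p.log_scale else 2 * scale * (p.upper - p.lower) / 10
                          for p in entry.space.free])[free]
        y0 = x0[free]
        sim = np.tile(y0, (len(y0) + 1, 1))
        for i in range(len(y0)):
            sim[i + 1, i] += steps[i]
        res = minimize(sub, y0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 0.1,
                                "adaptive": True, "initial_simplex": sim})
        x = x0.copy()
        x[free] = res.x
        return x, float(res.fun)

    fun_search = _objective(entry, obs, search_reps, kernel_seed, max_events_per_rep)
    results = []  # (fun, x, start_index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # screen every start with one evaluation, polish the promising ones
        screen = np.array([fun_search(x0) for x0 in starts])
        n_polish = max(min(len(starts), 3), len(starts) // 4)
        # polish the screen-best start of every T bucket first, then the
        # globally best remaining starts
        polish_idx: list[int] = []
        for b in sorted(set(buckets)):
            members = [i for i, bb in enumerate(buckets) if bb == b]
            polish_idx.append(min(members, key=lambda i: screen[i]))
        for idx in np.argsort(screen):
            if len(polish_idx) >= max(n_polish, len(set(buckets))):
                break
            if int(idx) not in polish_idx:
                polish_idx.append(int(idx))
        for idx in polish_idx:
            pinned = growth_dims if buckets[idx] < n_random_bucket else \
                np.zeros(len(names), dtype=bool)
            x, f = _nm(fun_search, starts[idx], search_maxfev, 0.3, pinned)
            results.append((f, x, idx))
        # choose the winning basins with a low-noise comparison (deep-tree
        # regions have inflated Monte-Carlo noise which a noisy argmax
        # would systematically favor), refine the two best, and resolve the
        # nearly flat (T, ancestral-Ne) ridge with nested low-noise scans
        final_reps = 3 * refine_reps
        fun_refine = _objective(entry, obs, refine_reps, kernel_seed, max_events_per_rep)
        fun_final = _objective(entry, obs, final_reps, kernel_seed, max_events_per_rep)
        order = np.argsort([r[0] for r in results])
        cand = [int(i) for i in order[: max(1, refine_top)]]
        for b in sorted({buckets[r[2]] for r in results}):
            members = [i for i, r in enumerate(results) if buckets[r[2]] == b]
            best_b = min(members, key=lambda i: results[i][0])
            if best_b not in cand:
                cand.append(best_b)
        cand_scores = [fun_final(results[i][1]) for i in cand]
        refined = []
        for j in np.argsort(cand_scores)[: max(1, n_refine)]:
            pick = cand[int(j)]
            pinned = growth_dims if buckets[results[pick][2]] < n_random_bucket \
                else np.zeros(len(names), dtype=bool)
            x, _ = _nm(fun_refine, results[pick][1], refine_maxfev, 0.15, pinned)
            refined.append((fun_final(x), x, results[pick][2]))
        refined.sort(key=lambda z: z[0])
        best_fun, best_x, best_start = refined[0]

        t_i = names.index("t_div") if "t_div" in names else (
            names.index("t2") if "t2" in names else None)
        a_i = names.index("ne_anc") if "ne_anc" in names else None
        if ridge_scan and t_i is not None and a_i is not None:
            # alternate (T, ancestral-Ne) ridge scans with short
            # all-parameter polishes: each scan fits a quadratic surface to
            # a 5x5 grid (averaging Monte-Carlo noise over all 25 points —
            # a noisy pointwise argmin resolves nothing on a ridge this
            # flat) and moves to its minimum; the polish then recouples the
            # remaining parameters, whose optima shift with T.  Every
            # stage draws a fresh common-random-numbers seed so no single
            # noise realization tilts all decisions.
            center = best_x.copy()
            scan_reps = (8 * refine_reps) // 5
            for span in scan_spans:
                fun_scan = _objective(entry, obs, scan_reps,
                                      int(rng.integers(2 ** 31)),
                                      max_events_per_rep)
                grid = np.linspace(-span, span, 5)
                pts = []
                vals = []
                for dt in grid:
                    for da in grid:
                        x = center.copy()
                        x[t_i] += dt
                        x[a_i] += da
                        pts.append((dt, da))
                        vals.append(fun_scan(x))
                step = _quadratic_surface_min(np.array(pts), np.array(vals), span)
                center[t_i] += step[0]
                center[a_i] += step[1]
                center, _ = entry.space.clip_vector(center)
                fun_polish = _objective(entry, obs, scan_reps,
                                        int(rng.integers(2 ** 31)),
                                        max_events_per_rep)
                center, _ = _nm(fun_polish, center, 32, 0.04,
                                np.zeros(len(names), dtype=bool))
                center, _ = entry.space.clip_vector(center)
            best_x = center

        # high-precision final evaluation on a fresh seed: parameters that
        # were partly fitted to one noise realization must not be credited
        # for it, and AIC differences between models fitted with the same
        # seed should reflect data, not evaluation noise
        eval_reps = 8 * refine_reps
        eval_seed = final_eval_seed
        fun_eval = _objective(entry, obs, eval_reps, eval_seed, max_events_per_rep)
        best_fun = fun_eval(best_x)
        if start_values is not None:
            # ascent contract for explicit starts: never end below the
            # best provided starting point on the evaluation surface
            for x0 in starts:
                f0 = fun_eval(x0)
                if f0 < best_fun:
                    best_fun = f0
                    best_x = x0.copy()
    if best_x is None or not np.isfinite(best_fun):
        raise RuntimeError(f"all optimization starts failed for model {catalogue_id}")
    best_x, clamped = entry.space.clip_vector(best_x)
    params = entry.space.from_vector(best_x)
    diagnostics = {
        "n_starts": len(starts), "best_start": int(best_start),
        "screen_lnls": [-float(v) for v in screen],
        "polished_lnls": [-float(r[0]) for r in results],
        "clamped": clamped, "kernel_seed": kernel_seed,
        "search_reps": search_reps, "refine_reps": refine_reps,
        "final_eval_reps": eval_reps,
        "final_eval_seed": eval_seed,
    }
    return FitResult(model_id=catalogue_id, labels=obs.pops, params=params,
                     free_names=entry.space.names, lnl=-float(best_fun),
                     k=entry.space.k, mu=mu, generation_time=generation_time,
                     obs_key=_obs_key(obs), diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# model selection

@dataclass
class ModelSelection:
    fits: list[FitResult]
    table: pd.DataFrame
    best_id: str


def select_model(fits: list[FitResult]) -> ModelSelection:
    """Rank fits of different models to the same spectrum by AIC.

    Ties are broken by smaller k, then catalogue order; fits on different
    observed data are refused.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    keys = {f.obs_key for f in fits}
    if len(keys) != 1:
        raise ValueError("fits were computed on different observed spectra")
    order = sorted(fits, key=lambda f: (f.aic, f.k, CATALOGUE_IDS.index(f.model_id)))
    best_aic = order[0].aic
    table = pd.DataFrame([{
        "model": f.model_id, "k": f.k, "lnCL": f.lnl, "AIC": f.aic,
        "delta_AIC": f.aic - best_aic,
    } for f in order])
    return ModelSelection(fits=order, table=table, best_id=order[0].model_id)


# ---------------------------------------------------------------------------
# derived quantities

def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def derive_quantities(fit_or_params, mu: float = MU_PASSERINE,
                      generation_time: float = GENERATION_TIME,
                      labels: tuple[str, ...] | None = None) -> dict:
    """Derived demographic quantities from fitted parameters.

    Divergence time in years is T_generations x generation time; the
    effective number of migrants per generation Nm[A->B] is the source
    size times the forward migration rate, Ne_A x m[A->B].  Values are
    reported at full precision plus display rounding (Ne to the nearest
    10^4, Nm to one decimal, half away from zero).
    """
    if isinstance(fit_or_params, FitResult):
        params = fit_or_params.params
        labels = fit_or_params.labels
    else:
        params = dict(fit_or_params)
        if labels is None:
            labels = tuple(f"pop{i + 1}" for i in range(3 if "ne3" in params else 2))
    npop = len(labels)
    ne = {labels[i]: float(params[f"ne{i + 1}"]) for i in range(npop)}
    out: dict = {
        "ne": ne,
        "ne_display": {k: int(round(v / 1e4) * 1e4) for k, v in ne.items()},
        "nm": {}, "nm_display": {}, "migration": {},
    }
    t_key = "t_div" if "t_div" in params else "t2"
    if t_key in params:
        t_gen = float(params[t_key])
        out["t_div_generations"] = t_gen
        out["t_div_years"] = t_gen * generation_time
    for i in range(npop):
        for j in range(npop):
            if i == j:
                continue
            m = float(params.get(f"m{i + 1}{j + 1}", 0.0))
            key = f"{labels[i]}->{labels[j]}"
            out["migration"][key] = m
            nm = ne[labels[i]] * m
            out["nm"][key] = nm
            out["nm_display"][key] = _round_half_away(nm, 1)
    return out


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(fit: FitResult, obs: JointSFS, n_boot: int = 50, seed: int = 0,
                 level: float = 0.95, n_starts: int = 5,
                 search_reps: int = 500, refine_reps: int = 2000,
                 search_maxfev: int = 120, refine_maxfev: int = 60) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for the free parameters.

    Spectra are resampled from the fitted model's expected cell
    probabilities at the observed site count, each replicate is refit with
    a reduced number of starts (always including the point estimate as one
    start), and percentile intervals are reported.
    """
    if n_boot < 20:
        warnings.warn("fewer than 20 bootstrap replicates: intervals will be "
                      "unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    model = fit.to_model()
    include_mono = obs.monomorphic_count is not None
    exp = expected_sfs(model, obs.hap_sizes, refine_reps,
                       int(rng.integers(2 ** 31)), folded=obs.folded,
                       include_monomorphic=include_mono)
    poly = _corner_mask(exp.probs.shape)
    cell_p = exp.probs[poly]
    n_sites = obs.counts[poly].sum()
    if include_mono:
        probs = np.append(cell_p, exp.p_monomorphic)
        n_total = int(round(n_sites + obs.monomorphic_count))
    else:
        probs = cell_p / cell_p.sum()
        n_total = int(round(n_sites))

    rows = []
    for b in range(n_boot):
        draw = rng.multinomial(n_total, probs / probs.sum())
        counts = np.zeros_like(obs.counts)
        if include_mono:
            counts[poly] = draw[:-1]
            mono = float(draw[-1])
        else:
            counts[poly] = draw
            mono = None
        boot_obs = JointSFS(pops=obs.pops, hap_sizes=obs.hap_sizes, counts=counts,
                            folded=obs.folded, monomorphic_count=mono,
                            callable_length=obs.callable_length)
        entry = build_model(fit.model_id, fit.labels, fit.mu, fit.generation_time)
        start_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        starts = [dict(fit.params)] + [entry.space.sample(start_rng)
                                       for _ in range(max(n_starts - 1, 0))]
        boot_fit = fit_model(boot_obs, fit.model_id,
                             seed=int(rng.integers(2 ** 31)),
                             search_reps=search_reps, refine_reps=refine_reps,
                             search_maxfev=search_maxfev, refine_maxfev=refine_maxfev,
                             refine_top=1, mu=fit.mu,
                             generation_time=fit.generation_time,
                             start_values=starts)
        rows.append({name: boot_fit.params[name] for name in fit.free_names})
    boot = pd.DataFrame(rows)
    alpha = (1.0 - level) / 2.0
    out = pd.DataFrame({
        "estimate": [fit.params[n] for n in fit.free_names],
        "lower": boot.quantile(alpha),
        "upper": boot.quantile(1.0 - alpha),
    }, index=list(fit.free_names))
    out.index.name = "parameter"
    return out
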