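"""Structured-coalescent engine for independent, non-recombining loci.

Simulates Hudson-style genealogies backwards in time for 1-3 demes with
piecewise demography: exponential-growth epochs, instantaneous size
changes, divergence joins, and backward migration.  A
:class:`~skyisland.models.DemographicModel` is first flattened into a phase
schedule (:func:`compile_phases`); the hot loop runs under numba.

Two consumption modes share one kernel:

* expected mode — per-replicate branch lengths are binned by the
  sample-configuration cell they subtend, giving Monte-Carlo expected
  branch lengths per joint-SFS cell (means and standard errors);
* branch mode — every branch is recorded as (descendant bitmask, length),
  so mutations can be dropped onto genealogies and yield genotypes.

Branch lengths are in generations; population sizes are diploid Ne, so the
pairwise coalescence rate for haploid lineages within a deme of size N is
1/(2N) per generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import DemographicModel

__all__ = ["Phases", "compile_phases", "expected_branch_lengths", "simulate_branches",
           "EventBudgetExceeded"]


class EventBudgetExceeded(RuntimeError):
    """The simulation exceeded its event budget (runaway parameter region)."""

_MAX_HAPLOIDS = 128  # two uint64 bitmask words


@dataclass
class Phases:
    """Flattened demography: one row per epoch, oldest epoch open-ended."""

    phase_end: np.ndarray   # (P,) generations; last entry inf
    sizes: np.ndarray       # (P, D) diploid size at phase start (backward)
    growth: np.ndarray      # (P, D) forward growth rate within the phase
    migration: np.ndarray   # (P, D, D) backward rate [from_deme, to_deme]
    join_src: np.ndarray    # (P, 2) deme joined away at phase end, -1 = none
    join_dst: np.ndarray    # (P, 2)


def compile_phases(model: DemographicModel) -> Phases:
    """Flatten model events into per-epoch arrays for the kernel.

    Growth applies from the present until the population's first event
    (size change or join); older epochs are constant-size.  Backward
    migration between demes i and j is taken from the forward matrix
    (``backward[j -> i] = forward[i -> j]``) and only while both demes are
    extant.
    """
    d = model.n_pops
    times = sorted({e.time for e in model.events})
    bounds = [t for t in times if t > 0]
    n_phases = len(bounds) + 1
    phase_end = np.array(bounds + [np.inf])

    sizes = np.empty((n_phases, d))
    growth = np.zeros((n_phases, d))
    mig = np.zeros((n_phases, d, d))
    join_src = np.full((n_phases, 2), -1, dtype=np.int64)
    join_dst = np.full((n_phases, 2), -1, dtype=np.int64)

    cur_size = np.array(model.ne, dtype=float)
    cur_growth = np.array(model.growth, dtype=float)
    active = np.ones(d, dtype=bool)
    idx = {lab: i for i, lab in enumerate(model.labels)}

    t_prev = 0.0
    for p in range(n_phases):
        sizes[p] = cur_size
        growth[p] = np.where(active, cur_growth, 0.0)
        for i in range(d):
            for j in range(d):
                if i != j and active[i] and active[j]:
                    # lineage in j jumps to i at the forward i->j rate
                    mig[p, j, i] = model.migration[i, j]
        if p == n_phases - 1:
            break
        t_b = phase_end[p]
        # advance trajectories to the boundary
        expo = np.clip(-np.where(active, cur_growth, 0.0) * (t_b - t_prev), -700.0, 700.0)
        cur_size = np.clip(cur_size * np.exp(expo), 1e-12, 1e300)
        nj = 0
        for ev in model.events:
            if ev.time != t_b:
                continue
            if ev.kind == "size_change":
                i = idx[ev.pop]
                cur_size[i] = ev.size
                cur_growth[i] = 0.0
            else:  # join
                s, dst = idx[ev.pop], idx[ev.dest]
                active[s] = False
                if ev.size is not None:
                    cur_size[dst] = ev.size
                cur_growth[dst] = 0.0
                join_src[p, nj] = s
                join_dst[p, nj] = dst
                nj += 1
        t_prev = t_b
    return Phases(phase_end, sizes, growth, mig, join_src, join_dst)


# ---------------------------------------------------------------------------
# kernel


@njit(cache=True, fastmath=True)
def _run_reps(seed, n_reps, init_deme, init_pop, dims,
              phase_end, sizes, growth, migration, join_src, join_dst,
              want_expected, cell_sum, cell_sumsq,
              want_branches, br_mask_lo, br_mask_hi, br_len,
              t_total, max_events, status):
    np.random.seed(seed)
    events_left = max_events
    status[0] = 0
    n = init_deme.shape[0]
    n_demes = sizes.shape[1]
    ncells = cell_sum.shape[0]
    d1, d2 = dims[1], dims[2]

    deme = np.empty(n, dtype=np.int64)
    c0 = np.empty(n, dtype=np.int64)
    c1 = np.empty(n, dtype=np.int64)
    c2 = np.empty(n, dtype=np.int64)
    cell = np.empty(n, dtype=np.int64)
    birth = np.empty(n, dtype=np.float64)
    mlo = np.empty(n, dtype=np.uint64)
    mhi = np.empty(n, dtype=np.uint64)
    # branch lengths are binned per cell only when a branch is finalized
    # (a lineage's cell never changes while it is alive)
    local = np.zeros(ncells, dtype=np.float64)
    touched = np.empty(2 * n, dtype=np.int64)
    kd = np.empty(n_demes, dtype=np.int64)
    n_phases = phase_end.shape[0]
    mig_row = np.empty((n_phases, n_demes), dtype=np.float64)
    for p in range(n_phases):
        for d in range(n_demes):
            s = 0.0
            for e in range(n_demes):
                s += migration[p, d, e]
            mig_row[p, d] = s

    for rep in range(n_reps):
        for i in range(n):
            deme[i] = init_deme[i]
            c0[i] = 0
            c1[i] = 0
            c2[i] = 0
            p = init_pop[i]
            if p == 0:
                c0[i] = 1
            elif p == 1:
                c1[i] = 1
            else:
                c2[i] = 1
            cell[i] = (c0[i] * d1 + c1[i]) * d2 + c2[i]
            birth[i] = 0.0
            if i < 64:
                mlo[i] = np.uint64(1) << np.uint64(i)
                mhi[i] = np.uint64(0)
            else:
                mlo[i] = np.uint64(0)
                mhi[i] = np.uint64(1) << np.uint64(i - 64)
        k = n
        nbr = 0
        t = 0.0
        phase = 0
        tps = 0.0
        ttot = 0.0
        for d in range(n_demes):
            kd[d] = 0
        for i in range(k):
            kd[deme[i]] += 1

        while k > 1:
            events_left -= 1
            if events_left < 0:
                status[0] = 1  # event budget exhausted (runaway parameter region)
                return

            best_w = np.inf
            best_kind = -1  # 0 coal, 1 migration
            best_deme = -1
            for d in range(n_demes):
                if kd[d] >= 2:
                    g = growth[phase, d]
                    if g == 0.0:
                        nd = sizes[phase, d]
                    else:
                        ex = -g * (t - tps)
                        if ex > 700.0:  # size trajectory clamped against overflow
                            ex = 700.0
                        elif ex < -700.0:
                            ex = -700.0
                        nd = sizes[phase, d] * np.exp(ex)
                        if nd < 1e-12:
                            nd = 1e-12
                    lam = kd[d] * (kd[d] - 1) / (4.0 * nd)
                    e = -np.log(np.random.random())
                    if g == 0.0 or lam <= 0.0:
                        w = e / lam if lam > 0.0 else np.inf
                    else:
                        arg = 1.0 + g * e / lam
                        w = np.inf if arg <= 0.0 else np.log(arg) / g
                    if w < best_w:
                        best_w = w
                        best_kind = 0
                        best_deme = d
                if kd[d] >= 1:
                    mr = mig_row[phase, d] * kd[d]
                    if mr > 0.0:
                        w = -np.log(np.random.random()) / mr
                        if w < best_w:
                            best_w = w
                            best_kind = 1
                            best_deme = d

            if t + best_w >= phase_end[phase]:
                t = phase_end[phase]
                for jj in range(2):
                    s = join_src[phase, jj]
                    if s >= 0:
                        dst = join_dst[phase, jj]
                        for i in range(k):
                            if deme[i] == s:
                                deme[i] = dst
                        kd[dst] += kd[s]
                        kd[s] = 0
                tps = t
                phase += 1
                continue

            t += best_w

            if best_kind == 0:
                # choose two distinct lineages in best_deme
                r1 = int(np.random.random() * kd[best_deme])
                r2 = int(np.random.random() * (kd[best_deme] - 1))
                if r2 >= r1:
                    r2 += 1
                a = -1
                b = -1
                seen = 0
                for i in range(k):
                    if deme[i] == best_deme:
                        if seen == r1:
                            a = i
                        if seen == r2:
                            b = i
                        seen += 1
                if a > b:
                    a, b = b, a
                len_a = t - birth[a]
                len_b = t - birth[b]
                ttot += len_a + len_b
                if want_branches:
                    br_mask_lo[rep, nbr] = mlo[a]
                    br_mask_hi[rep, nbr] = mhi[a]
                    br_len[rep, nbr] = len_a
                    br_mask_lo[rep, nbr + 1] = mlo[b]
                    br_mask_hi[rep, nbr + 1] = mhi[b]
                    br_len[rep, nbr + 1] = len_b
                if want_expected:
                    local[cell[a]] += len_a
                    local[cell[b]] += len_b
                    touched[nbr] = cell[a]
                    touched[nbr + 1] = cell[b]
                nbr += 2
                c0[a] += c0[b]
                c1[a] += c1[b]
                c2[a] += c2[b]
                cell[a] = (c0[a] * d1 + c1[a]) * d2 + c2[a]
                mlo[a] |= mlo[b]
                mhi[a] |= mhi[b]
                birth[a] = t
                last = k - 1
                if b != last:
                    deme[b] = deme[last]
                    c0[b] = c0[last]
                    c1[b] = c1[last]
                    c2[b] = c2[last]
                    cell[b] = cell[last]
                    mlo[b] = mlo[last]
                    mhi[b] = mhi[last]
                    birth[b] = birth[last]
                k = last
                kd[best_deme] -= 1
            else:
                r = int(np.random.random() * kd[best_deme])
                a = -1
                seen = 0
                for i in range(k):
                    if deme[i] == best_deme:
                        if seen == r:
                            a = i
                            break
                        seen += 1
                u = np.random.random() * mig_row[phase, best_deme]
                acc = 0.0
                dest = 0
                for e2 in range(n_demes):
                    acc += migration[phase, best_deme, e2]
                    if u < acc:
                        dest = e2
                        break
                deme[a] = dest
                kd[best_deme] -= 1
                kd[dest] += 1

        t_total[rep] = ttot
        if want_expected:
            for i in range(nbr):
                c = touched[i]
                if local[c] != 0.0:
                    cell_sum[c] += local[c]
                    cell_sumsq[c] += local[c] * local[c]
                    local[c] = 0.0


def _init_arrays(model: DemographicModel, hap_sizes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hap_sizes = [int(h) for h in hap_sizes]
    if len(hap_sizes) != model.n_pops:
        raise ValueError("one haploid sample size per model population required")
    if any(h < 1 for h in hap_sizes):
        raise ValueError("haploid sample sizes must be >= 1")
    n = sum(hap_sizes)
    if n > _MAX_HAPLOIDS:
        raise ValueError(f"at most {_MAX_HAPLOIDS} haploid samples supported, got {n}")
    init_deme = np.concatenate([np.full(h, d, dtype=np.int64)
                                for d, h in enumerate(hap_sizes)])
    init_pop = init_deme.copy()
    dims = np.ones(3, dtype=np.int64)
    for i, h in enumerate(hap_sizes):
        dims[i] = h + 1
    return init_deme, init_pop, dims


def expected_branch_lengths(model: DemographicModel, hap_sizes, n_reps: int, seed: int,
                            max_events_per_rep: int | None = None,
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Monte-Carlo expected branch length (generations) per joint-SFS cell.

    Returns ``(mean, stderr, mean_total_length, se_total_length)`` where
    ``mean`` has shape
    ``(h1+1, ..)`` over derived-allele-count cells (entry ``(0,..,0)`` and
    the all-samples corner stay zero: such branches do not exist).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    init_deme, init_pop, dims = _init_arrays(model, hap_sizes)
    ph = compile_phases(model)
    ncells = int(np.prod(dims))
    cell_sum = np.zeros(ncells)
    cell_sumsq = np.zeros(ncells)
    t_total = np.zeros(n_reps)
    dummy = np.zeros((1, 1))
    dummy_m = np.zeros((1, 1), dtype=np.uint64)
    status = np.zeros(1, dtype=np.int64)
    budget = (max_events_per_rep or 10 ** 9) * n_reps
    _run_reps(seed & 0x7FFFFFFF, n_reps, init_deme, init_pop, dims,
              ph.phase_end, ph.sizes, ph.growth, ph.migration,
              ph.join_src, ph.join_dst,
              True, cell_sum, cell_sumsq,
              False, dummy_m, dummy_m, dummy,
              t_total, budget, status)
    if status[0] != 0:
        raise EventBudgetExceeded(
            f"exceeded {budget} simulation events across {n_reps} replicates")
    mean = cell_sum / n_reps
    var = np.maximum(cell_sumsq / n_reps - mean ** 2, 0.0)
    stderr = np.sqrt(var / n_reps)
    shape = tuple(int(x) for x in dims[:model.n_pops])
    if model.n_pops == 1:
        shape = (int(dims[0]),)
    t_se = float(t_total.std(ddof=0) / np.sqrt(n_reps))
    return (mean.reshape(tuple(dims)).reshape(shape),
            stderr.reshape(tuple(dims)).reshape(shape),
            float(t_total.mean()), t_se)


def simulate_branches(model: DemographicModel, hap_sizes, n_reps: int, seed: int,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate genealogies and record every branch.

    Returns ``(mask_lo, mask_hi, lengths, t_total)``: per replicate, the
    2n-2 branches as descendant bitmasks over haploid sample indices (two
    64-bit words) with lengths in generations, plus total tree length.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    init_deme, init_pop, dims = _init_arrays(model, hap_sizes)
    n = init_deme.shape[0]
    if n < 2:
        raise ValueError("need at least two haploid samples")
    ph = compile_phases(model)
    nbr = 2 * n - 2
    mask_lo = np.zeros((n_reps, nbr), dtype=np.uint64)
    mask_hi = np.zeros((n_reps, nbr), dtype=np.uint64)
    br_len = np.zeros((n_reps, nbr))
    t_total = np.zeros(n_reps)
    dummy = np.zeros(1)
    status = np.zeros(1, dtype=np.int64)
    _run_reps(seed & 0x7FFFFFFF, n_reps, init_deme, init_pop, dims,
              ph.phase_end, ph.sizes, ph.growth, ph.migration,
              ph.join_src, ph.join_dst,
              False, dummy, dummy.copy(),
              True, mask_lo, mask_hi, br_len,
              t_total, np.int64(10 ** 15), status)
    return mask_lo, mask_hi, br_len, t_total


def masks_to_haplotypes(mask_lo: np.ndarray, mask_hi: np.ndarray, n_hap: int) -> np.ndarray:
    """Expand per-site descendant bitmasks into a (sites, haploids) 0/1 array."""
    bits_lo = (mask_lo[:, None] >> np.arange(64, dtype=np.uint64)[None, :]) & np.uint64(1)
    if n_hap <= 64:
        return bits_lo[:, :n_hap].astype(np.int8)
    bits_hi = (mask_hi[:, None] >> np.arange(64, dtype=np.uint64)[None, :]) & np.uint64(1)
    return np.concatenate([bits_lo, bits_hi[:, : n_hap - 64]], axis=1).astype(np.int8)
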