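"""Rank correlation between population differentiation and altitudinal floor.

If montane populations are recruited from the lowlands and differentiate
upslope, species whose distributions bottom out higher should show larger
between-mountain FST.  The test is a Spearman rank correlation between
per-species FST and the altitudinal floor (the lowest elevation at which
the species occurs), with a permutation p-value: exact enumeration for
small panels (n <= 10), seeded Monte-Carlo otherwise.  Species exclusions
are configuration, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ElevationRecord", "SpearmanResult", "spearman_fst_floor", "read_records"]

_EXACT_MAX_N = 10


@dataclass(frozen=True)
class ElevationRecord:
    species: str
    fst: float
    floor_m: float
    region: str | None = None
    include: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst <= 1.0:
            raise ValueError(f"FST for {self.species} must lie in [0,1], got {self.fst}")
        if self.floor_m < 0:
            raise ValueError(f"floor for {self.species} must be >= 0, got {self.floor_m}")


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int
    method: str                  # "exact" or "monte-carlo"
    n_permutations: int
    exclusions: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "r": self.r, "p": self.p, "n": self.n, "method": self.method,
            "n_permutations": self.n_permutations,
            "exclusions": ",".join(self.exclusions) or "-",
        }])


def _spearman_r(x_rank_centered: np.ndarray, y_rank_centered: np.ndarray) -> float:
    denom = np.linalg.norm(x_rank_centered) * np.linalg.norm(y_rank_centered)
    return float(x_rank_centered @ y_rank_centered / denom)


def spearman_fst_floor(records, exclude=(), p_method: str = "auto",
                       n_mc: int = 9999, seed: int = 0,
                       alternative: str = "two-sided") -> SpearmanResult:
    """Spearman correlation of FST against altitudinal floor.

    ``exclude`` is a list of species labels dropped before testing
    (records with ``include=False`` are dropped too).  Average ranks
    handle ties; the permutation null permutes the floor ranks.  With a
    constant FST or floor the correlation is undefined and reported as
    NaN.
    """
    exclude = tuple(exclude)
    kept = [r for r in records if r.include and r.species not in exclude]
    n = len(kept)
    if n < 5:
        raise ValueError(f"need >= 5 records after exclusions, got {n}")
    fst = np.array([r.fst for r in kept])
    floor = np.array([r.floor_m for r in kept])
    if np.ptp(fst) == 0 or np.ptp(floor) == 0:
        return SpearmanResult(r=float("nan"), p=float("nan"), n=n,
                              method="undefined", n_permutations=0, exclusions=exclude)
    rx = rankdata(fst)
    ry = rankdata(floor)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    r_obs = _spearman_r(rxc, ryc)

    def extreme(r_perm: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "less":
            return r_perm <= r_obs + 1e-12
        return np.abs(r_perm) >= abs(r_obs) - 1e-12

    if p_method == "exact" or (p_method == "auto" and n <= _EXACT_MAX_N):
        denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
        count = 0
        total = 0
        perm_iter = permutations(ryc)
        while True:
            chunk = np.array(list(islice(perm_iter, 100_000)))
            if chunk.size == 0:
                break
            r_perm = chunk @ rxc / denom
            count += int(extreme(r_perm).sum())
            total += len(chunk)
        return SpearmanResult(r=r_obs, p=count / total, n=n, method="exact",
                              n_permutations=total, exclusions=exclude)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(ryc) for _ in range(n_mc)])
    r_perm = perms @ rxc / (np.linalg.norm(rxc) * np.linalg.norm(ryc))
    count = int(extreme(r_perm).sum())
    p = (1 + count) / (1 + n_mc)
    return SpearmanResult(r=r_obs, p=p, n=n, method="monte-carlo",
                          n_permutations=n_mc, exclusions=exclude)


def read_records(path) -> list[ElevationRecord]:
    """Read a records TSV (species, fst, floor_m[, region, include])."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples():
        records.append(ElevationRecord(
            species=str(row.species), fst=float(row.fst), floor_m=float(row.floor_m),
            region=getattr(row, "region", None),
            include=bool(getattr(row, "include", True))))
    return records
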