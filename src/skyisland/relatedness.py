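"""Pairwise kinship from called genotypes and relative exclusion.

Close relatives bias both structure statistics and SFS-based demographic
inference, so they are screened out before any downstream stage.  The
estimator is the robust within-pair kinship built from shared-heterozygote
and opposite-homozygote counts (the KING-robust family):

    phi_ij = (N_het,het - 2 * N_AA,aa) / (N_het(i) + N_het(j))

which is ~0.5 for duplicate samples, ~0.25 for parent-offspring or full
sibs, ~0.125 for half-sibs and ~0 for unrelated pairs from one panmictic
population, and is invariant to ref/alt allele relabelling.  Counts are
taken over sites where both genotypes are called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .variants import GenotypeMatrix

__all__ = ["KinshipMatrix", "KinshipEstimator", "kinship_matrix", "flag_related"]

#: pairs with fewer informative sites than this are flagged unreliable
MIN_INFORMATIVE_SITES = 100
#: kinship above this marks a pair as closely related
RELATEDNESS_THRESHOLD = 0.06


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients with exclusion bookkeeping."""

    samples: list[str]
    phi: np.ndarray               # (n, n); diagonal 0.5 by convention; NaN undefined
    n_informative: np.ndarray     # (n, n) sites with both genotypes called
    n_missing: np.ndarray         # (n,) missing genotype count per sample
    unreliable: np.ndarray        # (n, n) bool, too few informative sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.samples, columns=self.samples)

    def pairs_above(self, threshold: float = RELATEDNESS_THRESHOLD) -> list[tuple[str, str, float]]:
        """Off-diagonal pairs with kinship strictly above the threshold."""
        out = []
        n = len(self.samples)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isfinite(self.phi[i, j]) and self.phi[i, j] > threshold:
                    out.append((self.samples[i], self.samples[j], float(self.phi[i, j])))
        return out


class KinshipEstimator(BaseEstimator):
    """Robust pairwise kinship estimator over called genotypes.

    Parameters
    ----------
    min_informative : int
        Pairs with fewer jointly-called sites are flagged unreliable.

    Attributes (after :meth:`fit`)
    ------------------------------
    phi_ : ndarray of shape (n_samples, n_samples)
    n_informative_ : ndarray of shape (n_samples, n_samples)
    sample_ids_ : list of str
    """

    def __init__(self, min_informative: int = MIN_INFORMATIVE_SITES):
        self.min_informative = min_informative

    def fit(self, geno: GenotypeMatrix, y=None) -> "KinshipEstimator":
        if geno.n_samples < 2:
            raise ValueError("kinship needs at least two samples")
        g = geno.genotypes
        valid = (g >= 0).astype(np.float64)
        het = (g == 1).astype(np.float64)
        hom0 = (g == 0).astype(np.float64)
        hom2 = (g == 2).astype(np.float64)

        n_both_het = het.T @ het
        n_opp = hom0.T @ hom2 + hom2.T @ hom0
        # het count of sample i restricted to sites where j is also called
        het_i = het.T @ valid
        denom = het_i + het_i.T
        n_inf = valid.T @ valid

        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (n_both_het - 2.0 * n_opp) / denom
        phi[denom == 0] = np.nan
        phi[n_inf == 0] = np.nan
        np.fill_diagonal(phi, 0.5)

        self.sample_ids_ = geno.sample_ids
        self.phi_ = phi
        self.n_informative_ = n_inf.astype(np.int64)
        self.n_missing_ = (g < 0).sum(axis=0).astype(np.int64)
        return self

    def to_matrix(self) -> KinshipMatrix:
        unreliable = self.n_informative_ < self.min_informative
        np.fill_diagonal(unreliable, False)
        return KinshipMatrix(samples=self.sample_ids_, phi=self.phi_,
                             n_informative=self.n_informative_,
                             n_missing=self.n_missing_, unreliable=unreliable)


def kinship_matrix(geno: GenotypeMatrix, min_informative: int = MIN_INFORMATIVE_SITES,
                   ) -> KinshipMatrix:
    """Estimate the pairwise kinship matrix (run after site filtering)."""
    return KinshipEstimator(min_informative=min_informative).fit(geno).to_matrix()


def flag_related(kin: KinshipMatrix, threshold: float = RELATEDNESS_THRESHOLD) -> list[str]:
    """Greedy exclusion list so no remaining pair exceeds the threshold.

    Repeatedly removes the sample participating in the most above-threshold
    pairs; ties are broken toward the sample with more missing genotypes,
    then the lexicographically larger id.  With a single flagged pair this
    drops exactly one of the two members.
    """
    n = len(kin.samples)
    adj = np.zeros((n, n), dtype=bool)
    with np.errstate(invalid="ignore"):
        above = np.isfinite(kin.phi) & (kin.phi > threshold)
    adj[above] = True
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    excluded: list[str] = []
    while True:
        degree = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        degree[~alive] = 0
        if degree.max(initial=0) == 0:
            break
        worst = np.flatnonzero(degree == degree.max())
        pick = max(worst, key=lambda i: (kin.n_missing[i], kin.samples[i]))
        alive[pick] = False
        excluded.append(kin.samples[pick])
    return sorted(excluded)
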