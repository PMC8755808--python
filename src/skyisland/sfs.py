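"""Joint site-frequency spectra and the fastsimcoal2-style .obs dialect.

A :class:`JointSFS` is a 1-3 dimensional array counting SNPs by how many
sampled allele copies carry the alternate (unfolded) or minor (folded)
allele in each population.  The optional monomorphic mass (callable genome
length minus segregating sites) is what lets a composite-likelihood fit
identify absolute Ne at a fixed mutation rate; without it only scaled
parameters are identifiable.

The text dialect mirrors the fastsimcoal2 observed-SFS files: a
"1 observations" header, ``d<pop>_<count>`` axis labels, tab-separated
counts; the joint 2-D layout has pop 1 on rows and pop 0 on columns as in
``jointMAFpop1_0.obs`` files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path

import numpy as np

from .variants import GenotypeMatrix

__all__ = ["JointSFS", "joint_sfs", "fold", "write_obs", "read_obs"]


@dataclass
class JointSFS:
    pops: tuple[str, ...]
    hap_sizes: tuple[int, ...]      # 2n per population
    counts: np.ndarray              # shape (h1+1, ...)
    folded: bool = False
    monomorphic_count: float | None = None
    callable_length: int | None = None

    def __post_init__(self) -> None:
        self.pops = tuple(self.pops)
        self.hap_sizes = tuple(int(h) for h in self.hap_sizes)
        self.counts = np.asarray(self.counts, dtype=float)
        expected = tuple(h + 1 for h in self.hap_sizes)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if not 1 <= len(self.pops) <= 3:
            raise ValueError("1-3 populations supported")

    @property
    def ndim(self) -> int:
        return len(self.pops)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def n_segregating(self) -> float:
        """Mass outside the two monomorphic corner cells."""
        corner0 = self.counts[(0,) * self.ndim]
        cornerf = self.counts[tuple(h for h in self.hap_sizes)]
        return float(self.counts.sum() - corner0 - cornerf)

    def marginal(self, pop: int | str) -> "JointSFS":
        """1-D spectrum of one population, summing over the others."""
        i = self.pops.index(pop) if isinstance(pop, str) else int(pop)
        axes = tuple(a for a in range(self.ndim) if a != i)
        counts = self.counts.sum(axis=axes) if axes else self.counts.copy()
        return JointSFS(pops=(self.pops[i],), hap_sizes=(self.hap_sizes[i],),
                        counts=counts, folded=self.folded)


def joint_sfs(geno: GenotypeMatrix, pop_labels=None, folded: bool = True,
              callable_length: int | None = None) -> JointSFS:
    """Build the joint SFS from complete biallelic genotypes.

    Each site increments the cell given by its per-population alternate
    allele counts; with ``folded`` the minor-allele (pooled count) fold is
    applied.  ``callable_length`` supplies the monomorphic mass
    (callable length minus the number of sites).
    """
    if pop_labels is None:
        pop_labels = tuple(dict.fromkeys(geno.populations))
    if not 1 <= len(pop_labels) <= 3:
        raise ValueError("1-3 populations supported")
    if np.any(geno.genotypes < 0):
        raise ValueError("missing genotypes present; run filters first")
    cols = [geno.pop_columns(p) for p in pop_labels]
    hap_sizes = tuple(2 * len(c) for c in cols)
    alt = np.stack([geno.genotypes[:, c].sum(axis=1) for c in cols], axis=1)
    counts = np.zeros(tuple(h + 1 for h in hap_sizes))
    np.add.at(counts, tuple(alt[:, i] for i in range(len(pop_labels))), 1.0)
    out = JointSFS(pops=tuple(pop_labels), hap_sizes=hap_sizes, counts=counts,
                   folded=False, callable_length=callable_length)
    if callable_length is not None:
        if callable_length < geno.n_sites:
            raise ValueError("callable_length smaller than the number of sites")
        out.monomorphic_count = float(callable_length - geno.n_sites)
    if folded:
        out = fold(out)
    return out


def _fold_cell(cell: tuple[int, ...], hap_sizes: tuple[int, ...]) -> tuple[int, ...]:
    total = sum(cell)
    htot = sum(hap_sizes)
    comp = tuple(h - c for c, h in zip(cell, hap_sizes))
    if 2 * total > htot:
        return comp
    if 2 * total == htot and cell > comp:
        return comp
    return cell


def fold(sfs: JointSFS) -> JointSFS:
    """Fold to the minor-allele spectrum (idempotent, mass-conserving).

    A cell whose pooled allele count exceeds half the pooled sample size is
    mapped onto its complement; exact-half cells are kept on the
    lexicographically smaller side of the fold line.
    """
    if sfs.folded:
        warnings.warn("spectrum already folded; returned unchanged", stacklevel=2)
        return replace(sfs, counts=sfs.counts.copy())
    folded = np.zeros_like(sfs.counts)
    for cell in product(*(range(h + 1) for h in sfs.hap_sizes)):
        folded[_fold_cell(cell, sfs.hap_sizes)] += sfs.counts[cell]
    return replace(sfs, counts=folded, folded=True)


# ---------------------------------------------------------------------------
# .obs dialect


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_obs(sfs: JointSFS, path) -> None:
    """Write the spectrum in the fastsimcoal2-compatible text dialect."""
    lines: list[str] = []
    if sfs.ndim == 1:
        lines.append("1 observations")
        lines.append("\t".join(f"d0_{i}" for i in range(sfs.hap_sizes[0] + 1)))
        lines.append("\t".join(_fmt(c) for c in sfs.counts))
    elif sfs.ndim == 2:
        # jointMAFpop1_0 layout: rows pop 1, columns pop 0
        lines.append("1 observations")
        lines.append("\t" + "\t".join(f"d0_{j}" for j in range(sfs.hap_sizes[0] + 1)))
        for i in range(sfs.hap_sizes[1] + 1):
            lines.append(f"d1_{i}\t" + "\t".join(_fmt(c) for c in sfs.counts[:, i]))
    else:
        lines.append("1 observations. No. of demes and sample sizes are on next line")
        lines.append("3\t" + "\t".join(str(h) for h in sfs.hap_sizes))
        lines.append("\t".join(_fmt(c) for c in sfs.counts.reshape(-1)))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_error(lineno: int, msg: str) -> ValueError:
    return ValueError(f"obs parse error at line {lineno}: {msg}")


def read_obs(path, pops: tuple[str, ...] | None = None, folded: bool = True) -> JointSFS:
    """Read a spectrum written by :func:`write_obs` (bit-exact round trip)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("1 observation"):
        raise _parse_error(1, "expected '1 observations' header")
    if "demes" in lines[0]:  # 3-D multiSFS layout
        if len(lines) < 3:
            raise _parse_error(2, "truncated multiSFS file")
        hdr = lines[1].split("\t")
        if len(hdr) != 4 or hdr[0] != "3":
            raise _parse_error(2, f"expected '3<TAB>n1 n2 n3', got {lines[1]!r}")
        hap_sizes = tuple(int(x) for x in hdr[1:])
        flat = lines[2].split("\t")
        ncells = int(np.prod([h + 1 for h in hap_sizes]))
        if len(flat) != ncells:
            raise _parse_error(3, f"expected {ncells} cells, got {len(flat)}")
        counts = np.array([float(x) for x in flat]).reshape([h + 1 for h in hap_sizes])
        pops = pops or ("pop0", "pop1", "pop2")
        return JointSFS(pops=pops, hap_sizes=hap_sizes, counts=counts, folded=folded)

    labels = lines[1].split("\t")
    if labels and labels[0] == "":  # 2-D: leading tab before column labels
        col_labels = labels[1:]
        for j, lab in enumerate(col_labels):
            if lab != f"d0_{j}":
                raise _parse_error(2, f"unexpected column label {lab!r}")
        h0 = len(col_labels) - 1
        rows = lines[2:]
        rows = [r for r in rows if r.strip()]
        h1 = len(rows) - 1
        counts = np.zeros((h0 + 1, h1 + 1))
        for i, row in enumerate(rows):
            parts = row.split("\t")
            if parts[0] != f"d1_{i}":
                raise _parse_error(3 + i, f"unexpected row label {parts[0]!r}")
            if len(parts) != h0 + 2:
                raise _parse_error(3 + i,
                                   f"expected {h0 + 1} counts, got {len(parts) - 1}")
            counts[:, i] = [float(x) for x in parts[1:]]
        pops = pops or ("pop0", "pop1")
        return JointSFS(pops=pops, hap_sizes=(h0, h1), counts=counts, folded=folded)

    # 1-D
    for j, lab in enumerate(labels):
        if lab != f"d0_{j}":
            raise _parse_error(2, f"unexpected label {lab!r}")
    h0 = len(labels) - 1
    parts = lines[2].split("\t")
    if len(parts) != h0 + 1:
        raise _parse_error(3, f"expected {h0 + 1} counts, got {len(parts)}")
    counts = np.array([float(x) for x in parts])
    pops = pops or ("pop0",)
    return JointSFS(pops=pops, hap_sizes=(h0,), counts=counts, folded=folded)
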