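"""Genomic relatedness matrices within and across generations.

The GRM entry for individuals ``j``, ``k`` is the average over SNPs of the
product of allele-frequency-standardized genotypes,

``A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``,

skipping missing genotypes pairwise (the per-pair SNP count replaces M).
The same estimator applied across generations (child rows x parent columns)
gives the cross-GRM, whose own-family entries concentrate near 0.5.  By
default a single allele-frequency reference -- pooled over everyone entering
the matrix set -- keeps within- and cross-generation matrices on one scale.

Relatedness pruning removes whole families greedily (most-connected first)
until no within-generation off-diagonal nor off-family cross entry exceeds
the cutoff (0.025 by default); a child's own parent is exempt, since that
relatedness is the signal the model uses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GRM",
    "CrossGRM",
    "GRMSet",
    "allele_frequencies",
    "compute_grm",
    "compute_cross_grm",
    "build_grm_set",
    "prune_relatedness",
    "read_gcta_grm",
    "write_gcta_grm",
]


@dataclass
class GRM:
    """Symmetric relatedness matrix with sample ids.

    ``n_pairs`` is the per-pair SNP count matrix, or None when genotypes
    were complete (every pair used all ``n_snps`` SNPs).
    """

    ids: pd.DataFrame  # columns fid, iid
    values: np.ndarray
    n_snps: int
    n_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM values must be n x n matching ids")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair_counts(self) -> np.ndarray:
        if self.n_pairs is not None:
            return self.n_pairs
        return np.full(self.values.shape, float(self.n_snps))

    def subset(self, idx: np.ndarray) -> "GRM":
        return GRM(
            self.ids.iloc[idx].reset_index(drop=True),
            self.values[np.ix_(idx, idx)],
            self.n_snps,
            None if self.n_pairs is None else self.n_pairs[np.ix_(idx, idx)],
        )


@dataclass
class CrossGRM:
    """Rectangular child-by-parent relatedness matrix."""

    row_ids: pd.DataFrame
    col_ids: pd.DataFrame
    values: np.ndarray
    n_snps: int
    n_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("cross-GRM shape must match row/col ids")
        if not np.isfinite(self.values).all():
            raise ValueError("cross-GRM contains non-finite values")

    def subset(self, idx: np.ndarray) -> "CrossGRM":
        return CrossGRM(
            self.row_ids.iloc[idx].reset_index(drop=True),
            self.col_ids.iloc[idx].reset_index(drop=True),
            self.values[np.ix_(idx, idx)],
            self.n_snps,
            None if self.n_pairs is None else self.n_pairs[np.ix_(idx, idx)],
        )


@dataclass
class GRMSet:
    """Aligned relatedness matrices for a parent-child pair dataset.

    Row ``i`` of every matrix refers to family ``family_ids[i]``: offspring
    GRM among children, parental GRM among the corresponding parents, and
    the child x parent cross matrix.  ``parental``/``cross`` may be None
    for an offspring-only analysis.
    """

    offspring: GRM
    parental: GRM | None
    cross: CrossGRM | None
    family_ids: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.family_ids)
        if self.offspring.n != n:
            raise ValueError("offspring GRM misaligned with family ids")
        if self.parental is not None and self.parental.n != n:
            raise ValueError("parental GRM misaligned with family ids")
        if self.cross is not None and self.cross.values.shape != (n, n):
            raise ValueError("cross GRM misaligned with family ids")

    @property
    def n(self) -> int:
        return len(self.family_ids)

    def subset(self, idx: np.ndarray) -> "GRMSet":
        return GRMSet(
            self.offspring.subset(idx),
            None if self.parental is None else self.parental.subset(idx),
            None if self.cross is None else self.cross.subset(idx),
            np.asarray(self.family_ids)[idx],
        )


def allele_frequencies(*genotype_matrices: np.ndarray) -> np.ndarray:
    """Pooled allele frequency of the counted allele across samples."""
    stacked = np.vstack([np.asarray(g, dtype=float) for g in genotype_matrices])
    obs = ~np.isnan(stacked)
    return np.nansum(stacked, axis=0) / (2 * obs.sum(axis=0))


def _standardized(X: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Standardize, zero-filling missing entries; returns (W, observed mask or None)."""
    X = np.asarray(X, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1); filter monomorphic SNPs first")
    W = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    nan = np.isnan(W)
    if nan.any():
        W[nan] = 0.0
        return W, ~nan
    return W, None


def compute_grm(
    genotypes: np.ndarray,
    freqs: np.ndarray | None = None,
    ids: pd.DataFrame | None = None,
) -> GRM:
    """Standardized-genotype relatedness among one set of individuals.

    ``freqs`` defaults to sample allele frequencies.  Missing genotypes are
    skipped pairwise, with the per-pair SNP count used as denominator.
    """
    X = np.asarray(genotypes, dtype=float)
    if freqs is None:
        freqs = allele_frequencies(X)
    W, obs = _standardized(X, freqs)
    m = X.shape[1]
    if obs is None:
        A = (W @ W.T) / m
        n_pairs = None
    else:
        counts = obs.astype(float) @ obs.astype(float).T
        if (counts == 0).any():
            raise ValueError("some pairs share no observed SNPs")
        A = (W @ W.T) / counts
        n_pairs = counts
    if ids is None:
        ids = pd.DataFrame({"fid": [f"I{i}" for i in range(len(A))],
                            "iid": [f"I{i}" for i in range(len(A))]})
    A = (A + A.T) / 2.0
    return GRM(ids.reset_index(drop=True), A, m, n_pairs)


def compute_cross_grm(
    child_genotypes: np.ndarray,
    parent_genotypes: np.ndarray,
    freqs: np.ndarray | None = None,
    row_ids: pd.DataFrame | None = None,
    col_ids: pd.DataFrame | None = None,
) -> CrossGRM:
    """Cross-generation relatedness (children in rows, parents in columns).

    Both matrices must cover the same SNP panel with the same counted
    allele.  ``freqs`` defaults to the pooled child+parent frequencies.
    """
    Xc = np.asarray(child_genotypes, dtype=float)
    Xp = np.asarray(parent_genotypes, dtype=float)
    if Xc.shape[1] != Xp.shape[1]:
        raise ValueError(
            f"SNP panel mismatch: children have {Xc.shape[1]} SNPs, parents {Xp.shape[1]}"
        )
    if freqs is None:
        freqs = allele_frequencies(Xc, Xp)
    Wc, obs_c = _standardized(Xc, freqs)
    Wp, obs_p = _standardized(Xp, freqs)
    m = Xc.shape[1]
    if obs_c is None and obs_p is None:
        A = (Wc @ Wp.T) / m
        n_pairs = None
    else:
        oc = obs_c.astype(float) if obs_c is not None else np.ones_like(Wc)
        op = obs_p.astype(float) if obs_p is not None else np.ones_like(Wp)
        counts = oc @ op.T
        if (counts == 0).any():
            raise ValueError("some cross pairs share no observed SNPs")
        A = (Wc @ Wp.T) / counts
        n_pairs = counts
    if row_ids is None:
        row_ids = pd.DataFrame({"fid": [f"F{i}" for i in range(len(Wc))],
                                "iid": [f"F{i}-C" for i in range(len(Wc))]})
    if col_ids is None:
        col_ids = pd.DataFrame({"fid": [f"F{i}" for i in range(len(Wp))],
                                "iid": [f"F{i}-P" for i in range(len(Wp))]})
    return CrossGRM(row_ids.reset_index(drop=True), col_ids.reset_index(drop=True), A, m, n_pairs)


def build_grm_set(
    family_ids: np.ndarray,
    child_genotypes: np.ndarray,
    parent_genotypes: np.ndarray | None = None,
    child_ids: pd.DataFrame | None = None,
    parent_ids: pd.DataFrame | None = None,
) -> GRMSet:
    """Build aligned offspring/parental/cross matrices for one pair dataset,
    standardizing everything with pooled parent+child allele frequencies."""
    family_ids = np.asarray(family_ids)
    if parent_genotypes is None:
        return GRMSet(compute_grm(child_genotypes, ids=child_ids), None, None, family_ids)
    freqs = allele_frequencies(child_genotypes, parent_genotypes)
    offspring = compute_grm(child_genotypes, freqs, ids=child_ids)
    parental = compute_grm(parent_genotypes, freqs, ids=parent_ids)
    cross = compute_cross_grm(
        child_genotypes, parent_genotypes, freqs, row_ids=child_ids, col_ids=parent_ids
    )
    return GRMSet(offspring, parental, cross, family_ids)


def _violation_matrix(grm_set: GRMSet, cutoff: float) -> np.ndarray:
    n = grm_set.n
    off = ~np.eye(n, dtype=bool)
    viol = (grm_set.offspring.values > cutoff) & off
    if grm_set.parental is not None:
        viol |= (grm_set.parental.values > cutoff) & off
    if grm_set.cross is not None:
        c = (grm_set.cross.values > cutoff) & off  # own child-parent pair exempt
        viol |= c | c.T
    return viol


def prune_relatedness(grm_set: GRMSet, cutoff: float = 0.025) -> np.ndarray:
    """Greedily drop families until no qualifying relatedness exceeds ``cutoff``.

    Qualifying entries are within-generation off-diagonals and off-family
    cross entries (a child's own parent is exempt).  The family involved in
    the most over-threshold pairs is removed first (ties broken toward the
    larger family index); both members of a removed family leave together.

    Returns the retained family ids, in the original order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    viol = _violation_matrix(grm_set, cutoff)
    alive = np.ones(grm_set.n, dtype=bool)
    degree = viol.sum(axis=1).astype(int)
    while degree.max(initial=0) > 0:
        worst = np.flatnonzero(degree == degree.max()).max()
        alive[worst] = False
        degree -= viol[:, worst].astype(int)
        degree[worst] = 0
        viol[worst, :] = False
        viol[:, worst] = False
    return np.asarray(grm_set.family_ids)[alive]


def write_gcta_grm(grm: GRM, prefix: str) -> None:
    """Write the GCTA binary GRM triplet: ``prefix.grm.bin`` (float32 lower
    triangle, row-major), ``prefix.grm.N.bin`` (per-pair SNP counts,
    float32), ``prefix.grm.id`` (FID IID, tab separated)."""
    n = grm.n
    tri = np.tril_indices(n)
    grm.values[tri].astype("<f4").tofile(prefix + ".grm.bin")
    grm.pair_counts()[tri].astype("<f4").tofile(prefix + ".grm.N.bin")
    grm.ids[["fid", "iid"]].to_csv(prefix + ".grm.id", sep="\t", header=False, index=False)


def read_gcta_grm(prefix: str) -> GRM:
    """Read a GCTA binary GRM triplet written by :func:`write_gcta_grm`."""
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"],
                      dtype=str)
    n = len(ids)
    expected = n * (n + 1) // 2
    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if len(vals) != expected:
        raise ValueError(
            f"{prefix}.grm.bin has {len(vals)} values, expected {expected} for {n} ids"
        )
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    if len(counts) not in (1, expected):
        raise ValueError(f"{prefix}.grm.N.bin length inconsistent with id count")
    A = np.zeros((n, n))
    N = np.zeros((n, n))
    tri = np.tril_indices(n)
    A[tri] = vals
    A = A + np.tril(A, -1).T
    if len(counts) == 1:
        N[:] = counts[0]
    else:
        N[tri] = counts
        N = N + np.tril(N, -1).T
    return GRM(ids, A, int(round(float(N.max()))), N)
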