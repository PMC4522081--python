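"""Pedigree numerator relationship matrix A and its inverse.

A is twice the kinship matrix: A_ij = 2 * P(two alleles sampled from i and j
are identical by descent), with diagonal 1 + F_i where F_i is the inbreeding
coefficient.  The polygenic effect of the prediction models is a ~ N(0, A
sigma_a^2), and the Gibbs sampler needs A^-1, assembled directly from the
pedigree by Henderson's rules with exact inbreeding (Mendelian-sampling
variances from the recursively computed F).

Dense matrices are used throughout; the pedigrees this package targets are
desk-scale (up to a few thousand animals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PedigreeTable

DENSE_LIMIT = 20_000


@dataclass
class PedigreeRelationship:
    """Numerator relationship matrix for a sorted pedigree."""

    ids: list[str]
    A: np.ndarray
    F: np.ndarray  # inbreeding coefficients, F_i = A_ii - 1

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        return np.array([lookup[str(i)] for i in ids], dtype=np.int64)


def build_A(pedigree: PedigreeTable) -> PedigreeRelationship:
    """Tabular (recursive) construction of A from a sorted pedigree.

    For animal j with parents s, d (unknown parents contribute 0):
    A_ij = (A_is + A_id) / 2 for all earlier i, and A_jj = 1 + A_sd / 2.
    """
    n = len(pedigree)
    if n > DENSE_LIMIT:
        raise ValueError(f"pedigree too large for dense A ({n} > {DENSE_LIMIT})")
    sire, dam = pedigree.parent_indices()
    if (sire >= np.arange(n)).any() or (dam >= np.arange(n)).any():
        raise ValueError("pedigree not sorted: parent after offspring")
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[:j, s]
        if d >= 0:
            row += 0.5 * A[:j, d]
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return PedigreeRelationship(ids=pedigree.ids, A=A, F=np.diag(A) - 1.0)


def inbreeding(pedigree: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients without forming A (Meuwissen–Luo style).

    For each animal the row of the Cholesky factor L of A is traced through
    the ancestors, giving A_ii = sum_j L_ij^2 D_j with D_j the
    Mendelian-sampling variance of j; F_i = A_ii - 1.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    F = np.zeros(n)
    Dvar = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            Dvar[i] = 1.0
            F[i] = 0.0
            continue
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        Dvar[i] = 0.5 - 0.25 * (fs + fd)
        v = np.zeros(i + 1)
        v[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            if v[j] == 0.0:
                continue
            aii += v[j] * v[j] * Dvar[j]
            if sire[j] >= 0:
                v[sire[j]] += 0.5 * v[j]
            if dam[j] >= 0:
                v[dam[j]] += 0.5 * v[j]
        F[i] = aii - 1.0
    return F


def build_A_inverse(pedigree: PedigreeTable) -> np.ndarray:
    """A^-1 by Henderson's rules with inbreeding.

    Each animal contributes 1/D_i to the inverse at (i,i), -1/(2 D_i) to the
    animal-parent entries and 1/(4 D_i) among its known parents, where
    D_i = 0.5 - 0.25 (F_s + F_d) is the Mendelian-sampling variance
    (an unknown parent enters with F = -1).
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_indices()
    F = inbreeding(pedigree)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        if s < 0 and d < 0:
            Di = 1.0
        else:
            Di = 0.5 - 0.25 * (fs + fd)
        alpha = 1.0 / Di
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2.0
                Ainv[p, i] -= alpha / 2.0
        for p in (s, d):
            for r in (s, d):
                if p >= 0 and r >= 0:
                    Ainv[p, r] += alpha / 4.0
    return Ainv


def export_nonzero(rel: PedigreeRelationship, path, atol: float = 1e-12) -> None:
    """TSV of (id_i, id_j, A_ij) for the upper triangle's nonzero entries."""
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tA\n")
        n = len(rel.ids)
        for i in range(n):
            for j in range(i, n):
                if abs(rel.A[i, j]) > atol:
                    fh.write(f"{rel.ids[i]}\t{rel.ids[j]}\t{rel.A[i, j]:.10g}\n")
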