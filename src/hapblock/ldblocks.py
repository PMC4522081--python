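"""Pairwise LD, D'-based haploblock construction, and the haploblock design matrix.

A haploblock is a run of adjacent SNPs on one chromosome such that *every*
pair of SNPs in the run has |D'| at or above a threshold (0.45 by default).
Each block is treated as a multi-allelic locus whose alleles are the distinct
haplotype strings observed in a set of reference (training) haplotypes; the
design matrix M then has one dosage column per (block, variant), so a sample
contributes 2 copies split across the block's columns.

LD and catalogues are computed on training haplotypes only; test animals are
encoded against the training catalogue, and a haplotype absent from the
catalogue contributes nothing (all of that block's columns stay 0 for that
copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PhasedGenotypes


@dataclass(frozen=True)
class LDResult:
    """Pairwise linkage disequilibrium between two biallelic markers."""

    D: float
    Dprime: float
    r2: float


def pairwise_dprime(hapA: np.ndarray, hapB: np.ndarray) -> LDResult:
    """Compute D, D' and r^2 between two markers from phased haplotypes.

    ``hapA`` and ``hapB`` are {0,1} vectors over the same 2n haplotypes.
    With allele-1 frequencies pA, pB and joint frequency pAB of the (1,1)
    haplotype: D = pAB - pA*pB; D' = D / Dmax where Dmax is the largest
    |D| attainable at those allele frequencies with the observed sign of D;
    r^2 = D^2 / (pA(1-pA) pB(1-pB)).

    Raises
    ------
    ValueError
        If either marker is monomorphic — callers must MAF-filter first.
    """
    hapA = np.asarray(hapA)
    hapB = np.asarray(hapB)
    pA = hapA.mean()
    pB = hapB.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic marker: LD undefined")
    pAB = np.logical_and(hapA == 1, hapB == 1).mean()
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 1.0  # D == 0 -> D' defined as 0
    dprime = D / dmax if D != 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(D=float(D), Dprime=float(dprime), r2=float(r2))


def _abs_dprime(hapA: np.ndarray, hapB: np.ndarray) -> float:
    """|D'| via counts, vector-free hot path used during block growth."""
    n = hapA.shape[0]
    cA = int(hapA.sum())
    cB = int(hapB.sum())
    cAB = int(np.count_nonzero(hapA & hapB))
    pA = cA / n
    pB = cB / n
    D = cAB / n - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return 0.0
    return abs(D / dmax)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


@dataclass
class Haploblock:
    """A contiguous run of markers forming one multi-allelic locus.

    ``variants`` is the ordered catalogue of distinct haplotype allele-tuples
    observed in the reference haplotypes (descending frequency, ties broken
    lexicographically); it is filled by :func:`catalogue_variants`.  Blocks
    whose catalogue has exactly one variant carry no information and are
    flagged ``excluded``.
    """

    block_id: str
    chrom: str
    marker_indices: np.ndarray  # contiguous indices into the genotype map
    variants: list[tuple] = field(default_factory=list)
    variant_freqs: np.ndarray | None = None
    excluded: bool = False

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def _reference_haplotypes(
    geno: PhasedGenotypes, reference_samples: list[str] | None
) -> np.ndarray:
    if reference_samples is None:
        return geno.haplotypes
    if len(reference_samples) == 0:
        raise ValueError("reference_samples must be nonempty")
    return geno.subset_samples(list(reference_samples)).haplotypes


def build_blocks(
    geno: PhasedGenotypes,
    threshold: float = 0.45,
    reference_samples: list[str] | None = None,
) -> list[Haploblock]:
    """Partition the markers of each chromosome into haploblocks.

    Greedy left-to-right construction: a block starts at the first unassigned
    marker and is extended by the next marker iff its |D'| with *every*
    marker already in the block is >= ``threshold``; otherwise the block is
    closed and a new one started.  Every marker ends up in exactly one block;
    single-marker blocks are allowed.  LD is computed on the reference
    (training) haplotypes only.
    """
    H = _reference_haplotypes(geno, reference_samples)
    chrom = geno.markers["chrom"].to_numpy()
    blocks: list[Haploblock] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            members = [idx[start]]
            j = start + 1
            while j < len(idx):
                cand = idx[j]
                if all(
                    _abs_dprime(H[:, m], H[:, cand]) >= threshold for m in members
                ):
                    members.append(cand)
                    j += 1
                else:
                    break
            blocks.append(
                Haploblock(
                    block_id=f"{c}_b{len(blocks)}",
                    chrom=str(c),
                    marker_indices=np.asarray(members, dtype=np.int64),
                )
            )
            start = j
    return blocks


def catalogue_variants(
    block: Haploblock,
    geno: PhasedGenotypes,
    reference_samples: list[str] | None = None,
) -> Haploblock:
    """Fill a block's variant catalogue from the reference haplotypes.

    Variants are the distinct haplotype allele-tuples over the block's
    markers, ordered by descending frequency then lexicographically.  A
    single-variant block (all reference haplotypes identical over the span)
    is flagged ``excluded``.
    """
    H = _reference_haplotypes(geno, reference_samples)[:, block.marker_indices]
    strings = [tuple(int(a) for a in row) for row in H]
    counts: dict[tuple, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    block.variants = [v for v, _ in ordered]
    freqs = np.array([c for _, c in ordered], dtype=float)
    block.variant_freqs = freqs / freqs.sum()
    block.excluded = len(block.variants) == 1
    return block


@dataclass
class HaploblockDesign:
    """Variant-dosage design matrix M with column metadata.

    ``M[i, c]`` counts how many of sample i's two haplotypes match variant
    ``columns[c]`` of block ``columns[c][0]``.  For reference samples the
    dosages of one block's columns always sum to 2; a test haplotype missing
    from the catalogue contributes nothing.
    """

    M: np.ndarray  # (n, q) int8
    columns: list[tuple[str, int]]  # (block_id, variant index)
    sample_ids: list[str]

    @property
    def q(self) -> int:
        return self.M.shape[1]


def design_matrix(
    blocks: list[Haploblock],
    geno: PhasedGenotypes,
    samples: list[str],
) -> HaploblockDesign:
    """Encode samples against the catalogues of the given (included) blocks."""
    for b in blocks:
        if not b.variants:
            raise ValueError(f"block {b.block_id} has no catalogue")
        if b.excluded:
            raise ValueError(f"excluded block {b.block_id} in design list")
    sub = geno.subset_samples(list(samples))
    H = sub.haplotypes
    n = len(samples)
    q = sum(b.n_variants for b in blocks)
    M = np.zeros((n, q), dtype=np.int8)
    columns: list[tuple[str, int]] = []
    col0 = 0
    for b in blocks:
        lookup = {v: k for k, v in enumerate(b.variants)}
        Hb = H[:, b.marker_indices]
        for i in range(n):
            for hap_row in (2 * i, 2 * i + 1):
                key = tuple(int(a) for a in Hb[hap_row])
                k = lookup.get(key)
                if k is not None:
                    M[i, col0 + k] += 1
        columns.extend((b.block_id, k) for k in range(b.n_variants))
        col0 += b.n_variants
    return HaploblockDesign(M=M, columns=columns, sample_ids=list(samples))


def block_stats(blocks: list[Haploblock]) -> dict:
    """Summary counts over a catalogued block list (excluded blocks reported
    separately; q counts included blocks only)."""
    included = [b for b in blocks if not b.excluded]
    snps = np.array([b.n_markers for b in blocks])
    nvars = np.array([b.n_variants for b in included]) if included else np.array([0])
    return {
        "n_blocks": len(blocks),
        "n_excluded": sum(b.excluded for b in blocks),
        "n_markers": int(snps.sum()),
        "mean_snps_per_block": float(snps.mean()),
        "max_snps_per_block": int(snps.max()),
        "multi_snp_blocks": int((snps > 1).sum()),
        "mean_variants_per_block": float(nvars.mean()),
        "max_variants_per_block": int(nvars.max()),
        "q": int(sum(b.n_variants for b in included)),
    }


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def blocks_to_table(blocks: list[Haploblock], geno: PhasedGenotypes) -> pd.DataFrame:
    """BED-like table: chrom, start_bp, end_bp, block_id, n_snps, n_variants,
    excluded flag."""
    pos = geno.markers["pos"].to_numpy()
    rows = [
        (
            b.chrom,
            int(pos[b.marker_indices[0]]),
            int(pos[b.marker_indices[-1]]),
            b.block_id,
            b.n_markers,
            b.n_variants,
            int(b.excluded),
        )
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "block_id",
            "n_snps", "n_variants", "excluded",
        ],
    )


def write_design(design: HaploblockDesign, mtx_path, columns_path) -> None:
    """Persist M as MatrixMarket sparse triplets plus a column-metadata TSV."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(design.M))
    pd.DataFrame(design.columns, columns=["block_id", "variant"]).to_csv(
        columns_path, sep="\t", index=False
    )
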