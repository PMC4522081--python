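"""Readers, writers and core domain types for phased genotypes, pedigrees and DRP.

All downstream stages (LD blocking, relationship matrices, samplers) consume
only the domain types defined here: :class:`PhasedGenotypes`,
:class:`PedigreeTable` and :class:`DRPTable`.

Phased genotypes are held as a ``(2n, m)`` int8 matrix of haplotypes; rows
``2i`` and ``2i+1`` are the two haplotypes of sample ``i``.  VCF 4.x with
phased diploid GT is the canonical on-disk format; a plain whitespace
haplotype-matrix format (one row per haplotype) is accepted for small
fixtures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hapblock")

#: Reliabilities are clamped to this interval before weights w = r2/(1-r2)
#: are formed, so that residual weights stay positive and finite.
RELIABILITY_CAP = (0.01, 0.99)

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "allele0", "allele1"]


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Phased genotypes
# ---------------------------------------------------------------------------


@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes for ``n`` samples at ``m`` markers.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, length ``n``.
    markers
        DataFrame with columns ``marker_id, chrom, pos, allele0, allele1``,
        grouped by chromosome with strictly increasing positions within each.
    haplotypes
        ``(2n, m)`` matrix with entries in {0, 1}; rows ``2i`` and ``2i+1``
        are the two haplotypes of sample ``i``.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.markers = self.markers.reset_index(drop=True)
        n, m = self.n_samples, self.n_markers
        if n < 1 or m < 1:
            raise FormatError("need at least one sample and one marker")
        if len(set(self.sample_ids)) != n:
            raise FormatError("sample ids are not unique")
        if self.haplotypes.shape != (2 * n, m):
            raise FormatError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"(2*{n}, {m})"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise FormatError("haplotype entries must be 0 or 1 (no missing data)")
        self._validate_map()

    def _validate_map(self) -> None:
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        seen: set = set()
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            if c in seen or not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise FormatError(f"markers of chromosome {c!r} are not contiguous")
            seen.add(c)
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosages(self) -> np.ndarray:
        """Allele-1 dosage matrix of shape ``(n, m)`` with entries {0, 1, 2}."""
        h = self.haplotypes
        return (h[0::2, :] + h[1::2, :]).astype(np.int8)

    def allele_freqs(self) -> np.ndarray:
        """Allele-1 frequency per marker, over all haplotypes."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "PhasedGenotypes":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return PhasedGenotypes(
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[keep],
            haplotypes=self.haplotypes[:, keep],
        )

    def subset_samples(self, sample_ids: list[str]) -> "PhasedGenotypes":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.empty(2 * len(sample_ids), dtype=np.intp)
        for k, s in enumerate(sample_ids):
            i = index[s]
            rows[2 * k] = 2 * i
            rows[2 * k + 1] = 2 * i + 1
        return PhasedGenotypes(
            sample_ids=list(sample_ids),
            markers=self.markers,
            haplotypes=self.haplotypes[rows, :],
        )


def read_phased_vcf(path, region: str | None = None) -> PhasedGenotypes:
    """Load phased diploid genotypes from a VCF file.

    Non-biallelic and non-SNP records are skipped (the count is logged).
    Unphased or missing genotypes are hard errors: phasing and imputation
    are upstream of this package.

    Parameters
    ----------
    path
        VCF path (plain or bgzipped).
    region
        Optional chromosome name; only records on that chromosome are kept.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for rec in vcf:
        if region is not None and rec.CHROM != region:
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(rec.genotype.array())
        if gt.shape[1] != 3:
            raise FormatError(f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
        if not gt[:, 2].all():
            raise FormatError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        alleles = gt[:, :2]
        if (alleles < 0).any():
            raise FormatError(f"missing genotype at {rec.CHROM}:{rec.POS}")
        rows.append(alleles.reshape(-1).astype(np.int8))
        meta.append((rec.ID or f"{rec.CHROM}_{rec.POS}", rec.CHROM, rec.POS,
                     rec.REF, rec.ALT[0]))
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)
    if not meta:
        raise FormatError(f"no biallelic SNP records loaded from {path}")
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    if markers.duplicated(["chrom", "pos"]).any():
        raise FormatError("duplicate (chromosome, position) marker keys")
    return PhasedGenotypes(sample_ids, markers, np.column_stack(rows))


def write_phased_vcf(geno: PhasedGenotypes, path) -> None:
    """Write genotypes as a minimal phased VCF 4.2 file."""
    h = geno.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for j, row in enumerate(geno.markers.itertuples(index=False)):
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(geno.n_samples)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{row.allele0}\t"
                     f"{row.allele1}\t.\t.\t.\tGT\t{gts}\n")


def read_haplotype_matrix(path) -> PhasedGenotypes:
    """Read the plain-text fixture format written by :func:`write_haplotype_matrix`.

    Line 1: whitespace-separated sample ids.  Line 2..: one marker per line as
    ``marker_id chrom pos allele0 allele1`` followed by the 2n haplotype
    alleles in sample order.
    """
    with open(path) as fh:
        sample_ids = fh.readline().split()
        meta, rows = [], []
        for line in fh:
            parts = line.split()
            meta.append((parts[0], parts[1], int(parts[2]), parts[3], parts[4]))
            rows.append(np.array(parts[5:], dtype=np.int8))
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    return PhasedGenotypes(sample_ids, markers, np.column_stack(rows))


def write_haplotype_matrix(geno: PhasedGenotypes, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(geno.sample_ids) + "\n")
        for j, row in enumerate(geno.markers.itertuples(index=False)):
            alleles = " ".join(map(str, geno.haplotypes[:, j]))
            fh.write(f"{row.marker_id} {row.chrom} {row.pos} {row.allele0} "
                     f"{row.allele1} {alleles}\n")


# ---------------------------------------------------------------------------
# Marker editing
# ---------------------------------------------------------------------------


def edit_markers(
    geno: PhasedGenotypes,
    maf_min: float = 0.01,
    prune_complete_ld: bool = True,
) -> PhasedGenotypes:
    """Apply the standard marker edits: MAF filter, then complete-LD pruning.

    Markers with minor allele frequency below ``maf_min`` are removed first.
    If ``prune_complete_ld`` is set, maximal runs of retained adjacent markers
    whose consecutive pairs are in complete LD (r^2 = 1, i.e. the haplotype
    columns are identical or exactly complementary) are collapsed to their
    first member.  Pruning chains consecutive pairs; it does not test all
    pairs in a window.  The operation is idempotent.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    idx = np.flatnonzero(geno.maf() >= maf_min)
    if idx.size == 0:
        raise FormatError("all markers removed by the MAF filter")
    if prune_complete_ld:
        h = geno.haplotypes
        chrom = geno.markers["chrom"].to_numpy()
        kept = [idx[0]]
        for j in idx[1:]:
            prev = kept[-1]
            if chrom[j] == chrom[prev] and _complete_ld(h[:, prev], h[:, j]):
                continue
            kept.append(j)
        idx = np.array(kept)
    return geno.subset_markers(idx)


def _complete_ld(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff r^2 = 1 exactly: columns identical or exactly complementary."""
    return bool(np.array_equal(a, b) or np.array_equal(a, 1 - b))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree: parents precede offspring.

    ``records`` holds ``(individual, sire, dam)`` with ``None`` for an
    unknown parent.  Construction sorts the input and rejects cycles and
    duplicate individuals.
    """

    records: list[tuple[str, str | None, str | None]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = _toposort_pedigree(self.records)
        self._index = {r[0]: i for i, r in enumerate(self.records)}

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam index arrays aligned to the sorted order; -1 = unknown."""
        sire = np.full(len(self.records), -1, dtype=np.int64)
        dam = np.full(len(self.records), -1, dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            if s is not None:
                sire[i] = self._index[s]
            if d is not None:
                dam[i] = self._index[d]
        return sire, dam


def _toposort_pedigree(records) -> list[tuple[str, str | None, str | None]]:
    by_id: dict[str, tuple] = {}
    for rec in records:
        ind, sire, dam = rec
        sire = None if sire in (None, "", "0", 0) else str(sire)
        dam = None if dam in (None, "", "0", 0) else str(dam)
        ind = str(ind)
        if ind in by_id:
            raise FormatError(f"duplicate individual {ind!r} in pedigree")
        by_id[ind] = (ind, sire, dam)
    # parents that never appear as individuals are treated as unknown founders
    for ind, sire, dam in list(by_id.values()):
        by_id[ind] = (
            ind,
            sire if sire in by_id else None,
            dam if dam in by_id else None,
        )
    out: list[tuple] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(ind: str) -> None:
        stack = [(ind, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                out.append(by_id[node])
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise FormatError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for parent in by_id[node][1:]:
                if parent is not None and state.get(parent) != 1:
                    if state.get(parent) == 0:
                        raise FormatError(f"pedigree cycle involving {parent!r}")
                    stack.append((parent, False))

    for ind in by_id:
        if state.get(ind) != 1:
            visit(ind)
    return out


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV/TSV with columns ``id,sire,dam`` (0/empty = unknown)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        records = list(
            zip(df[cols["id"]], df[cols["sire"]], df[cols["dam"]])
        )
    except KeyError as exc:
        raise FormatError(f"pedigree file missing column {exc}") from exc
    return PedigreeTable(records)


def write_pedigree(ped: PedigreeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("id,sire,dam\n")
        for ind, sire, dam in ped.records:
            fh.write(f"{ind},{sire or '0'},{dam or '0'}\n")


# ---------------------------------------------------------------------------
# Deregressed proofs
# ---------------------------------------------------------------------------


@dataclass
class DRPTable:
    """Deregressed proofs with per-animal reliabilities and residual weights.

    The weight ``w_i = r2_i / (1 - r2_i)`` enters the models through the
    residual covariance ``D sigma_e^2`` with ``d_ii = 1/w_i``: a high
    reliability means a small residual variance for that record.
    Reliabilities are clamped to :data:`RELIABILITY_CAP` (with a warning)
    before the weights are formed.
    """

    table: pd.DataFrame  # columns: id, drp, reliability, weight

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        rel = df["reliability"].to_numpy(dtype=float)
        lo, hi = RELIABILITY_CAP
        if (rel <= 0).any() or (rel >= 1).any():
            warnings.warn(
                "reliabilities outside (0,1) clamped to "
                f"[{lo}, {hi}] before weighting",
                stacklevel=2,
            )
        rel = np.clip(rel, lo, hi)
        df["reliability"] = rel
        df["weight"] = rel / (1.0 - rel)
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            raise FormatError("duplicate animal ids in DRP table")
        self.table = df

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def values(self) -> np.ndarray:
        return self.table["drp"].to_numpy(dtype=float)

    @property
    def reliabilities(self) -> np.ndarray:
        return self.table["reliability"].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    def subset(self, ids: list[str]) -> "DRPTable":
        sub = self.table.set_index("id").loc[[str(i) for i in ids]].reset_index()
        return DRPTable(sub)


def read_drp(path) -> DRPTable:
    """Read a DRP CSV/TSV with columns ``id,drp,reliability`` (extra cols kept)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.lower() for c in df.columns]
    missing = {"id", "drp", "reliability"} - set(df.columns)
    if missing:
        raise FormatError(f"DRP file missing columns {sorted(missing)}")
    return DRPTable(df)


def write_drp(drp: DRPTable, path) -> None:
    drp.table[["id", "drp", "reliability"]].to_csv(path, index=False)
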