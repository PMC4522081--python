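"""Selection of QTL-haploblocks from ranked SNP effects, and a random baseline.

A QTL-haploblock is a haploblock containing at least one of the top-k SNPs
ranked by absolute posterior-mean effect from an all-SNP model fit.  The
selection model must match the prediction model (BLUP-ranked blocks are fit
with BLUP, mixture-ranked with the mixture); that pairing is enforced by the
pipeline, not here.

The random baseline samples k markers uniformly without replacement and maps
them to their containing blocks, repeated over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ldblocks import Haploblock


@dataclass
class Selection:
    """One selected block set with its bookkeeping."""

    blocks: list[Haploblock]  # genome order, excluded blocks absent
    k: int
    mode: str  # "qtl" | "random"
    n_blocks: int
    q: int  # total variant columns

    @property
    def block_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks]


def marker_to_block(blocks: list[Haploblock], n_markers: int) -> np.ndarray:
    """Index of the containing block for every marker (blocks partition the map)."""
    owner = np.full(n_markers, -1, dtype=np.int64)
    for bi, b in enumerate(blocks):
        owner[b.marker_indices] = bi
    if (owner < 0).any():
        raise ValueError("blocks do not cover every marker")
    return owner


def _collect(blocks: list[Haploblock], owner: np.ndarray,
             markers: np.ndarray, k: int, mode: str) -> Selection:
    hit = np.zeros(len(blocks), dtype=bool)
    hit[owner[markers]] = True
    chosen = [b for bi, b in enumerate(blocks) if hit[bi] and not b.excluded]
    return Selection(
        blocks=chosen,
        k=k,
        mode=mode,
        n_blocks=len(chosen),
        q=sum(b.n_variants for b in chosen),
    )


def select_qtl_haploblocks(
    ranked_effects: pd.DataFrame,
    blocks: list[Haploblock],
    k: int,
) -> Selection:
    """Blocks containing at least one of the top-k ranked markers.

    ``ranked_effects`` is the table from
    :func:`hapblock.samplers.snp_effect_table` (must carry ``marker_index``
    and ``rank``).  Top-k markers whose block is excluded (single variant)
    are skipped without topping up k.  The result is deduplicated and in
    genome order.
    """
    if not 1 <= k <= len(ranked_effects):
        raise ValueError("k must lie in [1, number of ranked markers]")
    owner = marker_to_block(blocks, len(ranked_effects))
    top = ranked_effects.sort_values("rank")["marker_index"].to_numpy()[:k]
    return _collect(blocks, owner, top, k, "qtl")


def select_random_haploblocks(
    blocks: list[Haploblock],
    n_markers: int,
    k: int,
    seed: int,
    replicates: int = 10,
) -> list[Selection]:
    """Baseline: blocks containing k uniformly sampled markers, per replicate."""
    if not 1 <= k <= n_markers:
        raise ValueError("k must lie in [1, n_markers]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    owner = marker_to_block(blocks, n_markers)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        picked = rng.choice(n_markers, size=k, replace=False)
        out.append(_collect(blocks, owner, picked, k, "random"))
    return out


def selection_summary(selections: list[Selection]) -> pd.DataFrame:
    """Table of (k, mode, n_blocks, q) rows, one per selection."""
    return pd.DataFrame(
        [(s.k, s.mode, s.n_blocks, s.q) for s in selections],
        columns=["k", "mode", "n_blocks", "q"],
    )
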