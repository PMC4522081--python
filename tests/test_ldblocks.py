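import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hapblock.ldblocks import (
    block_stats,
    build_blocks,
    catalogue_variants,
    design_matrix,
    pairwise_dprime,
)

from conftest import make_genotypes


def ld_oracle(hapA, hapB):
    """Brute-force D, D', r2 from the 2x2 haplotype count table."""
    n = len(hapA)
    n11 = sum(1 for a, b in zip(hapA, hapB) if a == 1 and b == 1)
    pA = sum(1 for a in hapA if a == 1) / n
    pB = sum(1 for b in hapB if b == 1) / n
    D = n11 / n - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 1.0
    dprime = D / dmax if D else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, dprime, r2


def _from_counts(nAB, nAb, naB, nab):
    hapA = [1] * (nAB + nAb) + [0] * (naB + nab)
    hapB = [1] * nAB + [0] * nAb + [1] * naB + [0] * nab
    return np.array(hapA, dtype=np.int8), np.array(hapB, dtype=np.int8)


def test_complete_ld_gives_unit_dprime_and_r2():
    hapA, hapB = _from_counts(5, 0, 0, 5)
    res = pairwise_dprime(hapA, hapB)
    assert abs(res.Dprime) == pytest.approx(1.0)
    assert res.r2 == pytest.approx(1.0)


def test_independence_gives_zero():
    hapA, hapB = _from_counts(3, 3, 3, 3)
    res = pairwise_dprime(hapA, hapB)
    assert res.D == 0.0
    assert res.Dprime == 0.0
    assert res.r2 == 0.0


def test_count_table_matches_direct_count_oracle():
    hapA, hapB = _from_counts(4, 1, 1, 4)
    res = pairwise_dprime(hapA, hapB)
    D, dprime, r2 = ld_oracle(hapA, hapB)
    assert res.D == pytest.approx(D, abs=1e-15)
    assert res.Dprime == pytest.approx(dprime, abs=1e-15)
    assert res.r2 == pytest.approx(r2, abs=1e-15)


def test_monomorphic_marker_is_error():
    with pytest.raises(ValueError, match="monomorphic"):
        pairwise_dprime(np.zeros(10, dtype=np.int8),
                        np.arange(10, dtype=np.int8) % 2)


@given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
       st.integers(0, 6))
def test_ld_bounds_and_zero_equivalence(nAB, nAb, naB, nab):
    hapA, hapB = _from_counts(nAB, nAb, naB, nab)
    if len(hapA) == 0 or hapA.var() == 0 or hapB.var() == 0:
        return
    res = pairwise_dprime(hapA, hapB)
    assert abs(res.Dprime) <= 1 + 1e-12
    assert -1e-12 <= res.r2 <= 1 + 1e-12
    assert (res.D == 0) == (res.Dprime == 0)


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------


def greedy_blocks_oracle(h, chrom, threshold):
    """Independent greedy partition using the all-pairs rule."""
    m = h.shape[1]
    blocks, j = [], 0
    while j < m:
        members = [j]
        k = j + 1
        while (
            k < m
            and chrom[k] == chrom[j]
            and all(
                abs(ld_oracle(h[:, a], h[:, k])[1]) >= threshold
                for a in members
            )
        ):
            members.append(k)
            k += 1
        blocks.append(members)
        j = k
    return blocks


def test_duplicated_columns_give_one_block_per_chromosome():
    rng = np.random.default_rng(0)
    col1 = rng.integers(0, 2, size=20)
    col2 = rng.integers(0, 2, size=20)
    while col1.var() == 0 or col2.var() == 0:
        col1, col2 = rng.integers(0, 2, (2, 20))
    h = np.column_stack([col1] * 3 + [col2] * 4).astype(np.int8)
    geno = make_genotypes(h, chrom=["1"] * 3 + ["2"] * 4)
    blocks = build_blocks(geno, threshold=0.45)
    assert len(blocks) == 2
    assert [b.n_markers for b in blocks] == [3, 4]


def test_pairwise_independent_markers_give_singletons():
    # all 8 binary triples as haplotypes: any two columns are independent
    h = np.array(list(itertools.product([0, 1], repeat=3)), dtype=np.int8)
    geno = make_genotypes(h)
    blocks = build_blocks(geno, threshold=0.45)
    assert all(b.n_markers == 1 for b in blocks)
    assert len(blocks) == 3


def test_planted_clusters_match_brute_force_greedy_oracle():
    rng = np.random.default_rng(1)
    n_hap, m = 60, 30
    h = rng.integers(0, 2, size=(n_hap, m)).astype(np.int8)
    # plant three LD clusters by copying a base column with small noise
    for start, size in [(2, 4), (11, 5), (22, 3)]:
        base = rng.integers(0, 2, size=n_hap)
        for j in range(start, start + size):
            col = base.copy()
            flips = rng.choice(n_hap, size=3, replace=False)
            col[flips] = 1 - col[flips]
            h[:, j] = col
    h = h[:, np.minimum(h.mean(0), 1 - h.mean(0)) > 0.05]
    geno = make_genotypes(h)
    blocks = build_blocks(geno, threshold=0.45)
    oracle = greedy_blocks_oracle(h, ["1"] * h.shape[1], 0.45)
    assert [list(b.marker_indices) for b in blocks] == oracle
    # every emitted multi-marker block satisfies the all-pairs rule
    for b in blocks:
        for a, c in itertools.combinations(b.marker_indices, 2):
            assert abs(ld_oracle(h[:, a], h[:, c])[1]) >= 0.45


def test_blocks_partition_markers_and_threshold_monotonicity(small_sim):
    from hapblock.io_formats import edit_markers

    geno = edit_markers(small_sim.genotypes, 0.01, True)
    train, _ = small_sim.split()
    sizes = {}
    for thr in (0.3, 0.45, 0.6, 0.9):
        blocks = build_blocks(geno, thr, train)
        covered = np.concatenate([b.marker_indices for b in blocks])
        assert np.array_equal(np.sort(covered), np.arange(geno.n_markers))
        sizes[thr] = [b.n_markers for b in blocks]
    # raising the threshold never increases the first block's extent
    for lo, hi in [(0.3, 0.45), (0.45, 0.6), (0.6, 0.9)]:
        assert max(sizes[hi]) <= max(sizes[lo])
        assert len(sizes[hi]) >= len(sizes[lo])


# ---------------------------------------------------------------------------
# variant catalogues and the design matrix
# ---------------------------------------------------------------------------


def test_single_polymorphic_snp_block_has_two_variants():
    h = np.array([[0], [1], [0], [1]], dtype=np.int8)
    geno = make_genotypes(h)
    blocks = build_blocks(geno)
    b = catalogue_variants(blocks[0], geno)
    assert sorted(b.variants) == [(0,), (1,)]
    assert not b.excluded


def test_monomorphic_block_is_excluded():
    # monomorphic within the reference subset only
    h = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
    geno = make_genotypes(h)  # samples s0 (rows 0,1), s1 (rows 2,3)
    blocks = build_blocks(geno, reference_samples=["s0"])
    b = catalogue_variants(blocks[0], geno, reference_samples=["s0"])
    assert b.n_variants == 1
    assert b.excluded


def test_catalogue_equals_distinct_rows_with_frequency_order():
    rng = np.random.default_rng(2)
    h = rng.integers(0, 2, size=(40, 4)).astype(np.int8)
    geno = make_genotypes(h)
    b = build_blocks(geno, threshold=0.0)[0]
    assert b.n_markers == 4
    catalogue_variants(b, geno)
    expected = {tuple(int(x) for x in row) for row in h}
    assert set(b.variants) == expected
    counts = [sum(1 for row in h if tuple(row) == v) for v in b.variants]
    assert counts == sorted(counts, reverse=True)
    assert np.isclose(b.variant_freqs.sum(), 1.0)


def test_design_matrix_dosages_and_row_sums():
    # two samples; sample 0 homozygous for variant (0,0)
    h = np.array([[0, 0], [0, 0], [0, 0], [1, 1]], dtype=np.int8)
    geno = make_genotypes(h)
    b = build_blocks(geno, threshold=0.0)[0]
    catalogue_variants(b, geno)
    design = design_matrix([b], geno, ["s0", "s1"])
    col = {v: i for i, v in enumerate(b.variants)}
    assert design.M[0, col[(0, 0)]] == 2
    assert design.M[0].sum() == 2
    assert design.M[1, col[(0, 0)]] == 1
    assert design.M[1, col[(1, 1)]] == 1
    assert np.all(design.M.sum(axis=1) == 2)


def test_novel_test_haplotype_contributes_nothing():
    h = np.array(
        [[0, 0], [1, 1],   # s0 (reference)
         [0, 0], [0, 1]],  # s1: (0,1) never seen in reference
        dtype=np.int8,
    )
    geno = make_genotypes(h)
    blocks = build_blocks(geno, threshold=0.0, reference_samples=["s0"])
    b = catalogue_variants(blocks[0], geno, reference_samples=["s0"])
    design = design_matrix([b], geno, ["s1"])
    assert design.M[0].sum() == 1  # only the catalogued copy counts


def test_block_stats_recount_oracle(small_sim):
    from hapblock.io_formats import edit_markers

    geno = edit_markers(small_sim.genotypes, 0.01, True)
    train, _ = small_sim.split()
    blocks = build_blocks(geno, 0.45, train)
    for b in blocks:
        catalogue_variants(b, geno, train)
    stats = block_stats(blocks)
    sizes = [b.n_markers for b in blocks]
    assert stats["n_blocks"] == len(blocks)
    assert stats["mean_snps_per_block"] == pytest.approx(np.mean(sizes))
    assert stats["q"] == sum(
        b.n_variants for b in blocks if not b.excluded
    )
    assert stats["n_markers"] == geno.n_markers


def test_design_matrix_mtx_export_round_trips(tmp_path):
    import pandas as pd
    from scipy.io import mmread

    from hapblock.ldblocks import write_design

    rng = np.random.default_rng(5)
    h = rng.integers(0, 2, size=(20, 6)).astype(np.int8)
    geno = make_genotypes(h)
    blocks = build_blocks(geno, threshold=0.0)
    for b in blocks:
        catalogue_variants(b, geno)
    design = design_matrix([b for b in blocks if not b.excluded], geno,
                           geno.sample_ids)
    write_design(design, tmp_path / "M.mtx", tmp_path / "cols.tsv")
    back = mmread(tmp_path / "M.mtx").toarray()
    assert np.array_equal(back, design.M)
    cols = pd.read_csv(tmp_path / "cols.tsv", sep="\t")
    assert len(cols) == design.q


def test_block_stats_mean_of_mixed_sizes():
    blocks = []
    for size in (1, 2, 3):
        h = np.ones((4, size), dtype=np.int8)
        h[0] = 0
        geno = make_genotypes(h)
        b = build_blocks(geno, threshold=0.0)[0]
        catalogue_variants(b, geno)
        blocks.append(b)
    assert block_stats(blocks)["mean_snps_per_block"] == pytest.approx(2.0)
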