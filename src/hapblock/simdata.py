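"""Synthetic pedigreed populations with block-structured LD and DRP phenotypes.

The generator emulates the data a dairy-cattle genomic-prediction study works
with, at desk scale:

* founder haplotypes copied segment-wise from a small ancestral pool, giving
  strong local LD (multi-SNP |D'| blocks) whose extent is tuned by a
  per-marker pool-switch rate;
* discrete generations of random monogamous mating with Haldane (Poisson,
  no-interference) recombination, recorded in a pedigree;
* a trait controlled by a small number of QTL whose effects are drawn from a
  four-class normal mixture (most effects tiny, a few large), scaled to a
  target heritability;
* deregressed-proof (DRP) phenotypes: DRP_i = TBV_i + e_i with a per-animal
  reliability r2_i drawn uniformly in a configured range and
  Var(e_i) = Var(TBV) (1 - r2_i) / r2_i, so that Cor^2(DRP_i, TBV_i)
  matches r2_i in expectation.

Defaults give 3 chromosomes x 1000 markers and 1000 animals (200 founders,
4 discrete generations of 200, so the forward split leaves 800 training and
200 test animals), the scale every downstream stage is exercised at.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import DRPTable, PedigreeTable, PhasedGenotypes, MARKER_COLUMNS

#: Mixing proportions of the four-class effect mixture (shared with the
#: Bayesian mixture prediction model): most effects near zero, few large.
DEFAULT_MIXTURE_PROPORTIONS = (0.889, 0.1, 0.01, 0.001)
#: Relative variances of the four classes; the absolute scale is irrelevant
#: because effects are rescaled to the target heritability.
DEFAULT_MIXTURE_VARIANCES = (1e-5, 1e-4, 1e-3, 1e-2)


@dataclass
class SimConfig:
    """Parameters of the synthetic population; defaults are the desk-scale
    study conditions used throughout the tests."""

    n_founders: int = 200
    n_generations: int = 4
    offspring_per_mating: int = 2
    m_markers: int = 3000
    n_chromosomes: int = 3
    chromosome_length_morgans: float = 1.0
    founder_haplotype_pool_size: int = 8
    mutation_copy_rate: float = 0.06
    n_qtl: int = 40
    qtl_effect_mixture: tuple = (
        DEFAULT_MIXTURE_PROPORTIONS,
        DEFAULT_MIXTURE_VARIANCES,
    )
    h2: float = 0.3
    drp_reliability_range: tuple = (0.6, 0.95)
    seed: int = 1

    def __post_init__(self) -> None:
        props, variances = self.qtl_effect_mixture
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0,1)")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if any(v < 0 for v in variances):
            raise ValueError("mixture variances must be >= 0")
        if self.founder_haplotype_pool_size < 2:
            raise ValueError("founder haplotype pool needs >= 2 haplotypes")
        if self.n_qtl > self.m_markers:
            raise ValueError("n_qtl cannot exceed m_markers")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "qtl_effect_mixture" in raw:
            raw["qtl_effect_mixture"] = tuple(
                tuple(x) for x in raw["qtl_effect_mixture"]
            )
        if "drp_reliability_range" in raw:
            raw["drp_reliability_range"] = tuple(raw["drp_reliability_range"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth of a simulated trait, for parameter-recovery tests."""

    ids: list[str]
    tbv: np.ndarray  # aligned to ids
    marker_effects: np.ndarray  # length m, zero off-QTL
    qtl_indices: np.ndarray
    var_tbv: float
    var_env: float

    @property
    def realized_h2(self) -> float:
        return self.var_tbv / (self.var_tbv + self.var_env)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "tbv": self.tbv})


def _marker_map(config: SimConfig) -> pd.DataFrame:
    per_chrom = config.m_markers // config.n_chromosomes
    counts = [per_chrom] * config.n_chromosomes
    counts[-1] += config.m_markers - per_chrom * config.n_chromosomes
    rows = []
    for c, cnt in enumerate(counts, start=1):
        for j in range(cnt):
            rows.append((f"snp{c}_{j}", str(c), (j + 1) * 1000, "A", "C"))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def _chrom_slices(markers: pd.DataFrame) -> list[slice]:
    chrom = markers["chrom"].to_numpy()
    slices = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return slices


def simulate_founder_haplotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> PhasedGenotypes:
    """Draw founder haplotypes by segment-copying from an ancestral pool.

    Each founder haplotype walks along the markers copying one of
    ``founder_haplotype_pool_size`` ancestral haplotypes, switching to a
    random pool member with probability ``mutation_copy_rate`` per marker
    (always switching at chromosome starts).  A low switch rate gives long
    shared segments and hence strong adjacent |D'|.  Markers whose founder
    MAF falls below 0.01 have their pool column redrawn (the copying paths
    are kept), with a bounded number of retries.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.m_markers
    pool_n = config.founder_haplotype_pool_size
    n_hap = 2 * config.n_founders
    markers = _marker_map(config)

    freqs = rng.uniform(0.1, 0.9, size=m)
    pool = (rng.random((pool_n, m)) < freqs).astype(np.int8)

    switch = rng.random((n_hap, m)) < config.mutation_copy_rate
    switch[:, 0] = True
    for sl in _chrom_slices(markers):
        switch[:, sl.start] = True
    seg = np.cumsum(switch, axis=1) - 1
    max_seg = int(seg.max()) + 1
    seg_choice = rng.integers(0, pool_n, size=(n_hap, max_seg))
    path = np.take_along_axis(seg_choice, seg, axis=1)

    hap = pool[path, np.arange(m)[None, :]]
    for _ in range(100):
        maf = np.minimum(hap.mean(axis=0), 1 - hap.mean(axis=0))
        bad = np.flatnonzero(maf < 0.01)
        if bad.size == 0:
            break
        pool[:, bad] = rng.random((pool_n, bad.size)) < rng.uniform(
            0.3, 0.7, size=bad.size
        )
        hap[:, bad] = pool[path[:, bad], bad[None, :]]
    else:
        raise RuntimeError("could not satisfy the founder MAF >= 0.01 guard")

    sample_ids = [f"g0_{i:04d}" for i in range(config.n_founders)]
    return PhasedGenotypes(sample_ids, markers, hap.astype(np.int8))


def _make_gamete(
    hap0: np.ndarray,
    hap1: np.ndarray,
    chrom_slices: list[slice],
    length_morgans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete under the Haldane model: per chromosome, Poisson(L)
    crossovers at uniform positions, random starting phase."""
    gamete = np.empty_like(hap0)
    for sl in chrom_slices:
        n_mark = sl.stop - sl.start
        n_x = rng.poisson(length_morgans)
        phase = int(rng.integers(0, 2))
        if n_x == 0:
            src = hap0 if phase == 0 else hap1
            gamete[sl] = src[sl]
            continue
        # crossover points as marker-interval fractions
        cuts = np.sort(rng.random(n_x))
        boundaries = np.floor(cuts * n_mark).astype(np.int64)
        phase_vec = np.full(n_mark, phase, dtype=np.int8)
        for b in boundaries:
            phase_vec[b:] = 1 - phase_vec[b:]
        block0 = hap0[sl]
        block1 = hap1[sl]
        gamete[sl] = np.where(phase_vec == 0, block0, block1)
    return gamete


def drop_through_pedigree(
    founders: PhasedGenotypes,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhasedGenotypes, PedigreeTable]:
    """Random monogamous mating for ``n_generations`` discrete generations.

    Each generation the previous generation is shuffled and paired; each
    pair leaves ``offspring_per_mating`` offspring.  Gametes recombine under
    the Haldane model.  Sample ids encode the generation (``g<gen>_<i>``);
    the returned pedigree records every animal, founders first.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    slices = _chrom_slices(founders.markers)
    L = config.chromosome_length_morgans

    all_ids = list(founders.sample_ids)
    haps = [founders.haplotypes[i] for i in range(2 * founders.n_samples)]
    records: list[tuple] = [(s, None, None) for s in founders.sample_ids]
    prev_gen = list(range(founders.n_samples))  # indices into all_ids

    for gen in range(1, config.n_generations + 1):
        perm = rng.permutation(len(prev_gen))
        n_pairs = len(prev_gen) // 2
        child_no = 0
        new_gen = []
        for p in range(n_pairs):
            sire_i = prev_gen[perm[2 * p]]
            dam_i = prev_gen[perm[2 * p + 1]]
            for _ in range(config.offspring_per_mating):
                cid = f"g{gen}_{child_no:04d}"
                child_no += 1
                g_s = _make_gamete(haps[2 * sire_i], haps[2 * sire_i + 1],
                                   slices, L, rng)
                g_d = _make_gamete(haps[2 * dam_i], haps[2 * dam_i + 1],
                                   slices, L, rng)
                haps.append(g_s)
                haps.append(g_d)
                records.append((cid, all_ids[sire_i], all_ids[dam_i]))
                new_gen.append(len(all_ids))
                all_ids.append(cid)
        prev_gen = new_gen

    geno = PhasedGenotypes(all_ids, founders.markers, np.vstack(haps))
    return geno, PedigreeTable(records)


def generation_of(ids: list[str]) -> np.ndarray:
    """Generation index parsed from simulated sample ids (``g<gen>_<i>``)."""
    return np.array([int(str(s).split("_")[0][1:]) for s in ids])


def simulate_trait(
    geno: PhasedGenotypes,
    pedigree: PedigreeTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[DRPTable, SimTruth]:
    """Simulate QTL effects, true breeding values and DRP phenotypes.

    QTL positions are uniform over the markers; each QTL's effect class is
    drawn from the four-class mixture and its effect from the class normal.
    Effects are rescaled so that the realized variance of TBV over all
    animals equals ``h2`` against an environmental variance of ``1 - h2``.
    DRP_i = TBV_i + e_i with Var(e_i) = Var(TBV)(1 - r2_i)/r2_i.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    m = geno.n_markers
    X = geno.dosages().astype(np.float64)
    props, variances = config.qtl_effect_mixture
    for _ in range(20):
        qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
        classes = rng.choice(len(props), size=config.n_qtl, p=np.asarray(props))
        beta = rng.standard_normal(config.n_qtl) * np.sqrt(
            np.asarray(variances)[classes]
        )
        tbv = X[:, qtl] @ beta
        if np.var(tbv) > 0:
            break
    else:
        raise RuntimeError("degenerate trait: Var(TBV) = 0 after retries")

    scale = np.sqrt(config.h2 / np.var(tbv))
    beta *= scale
    tbv *= scale
    var_tbv = float(np.var(tbv))
    var_env = 1.0 - config.h2

    lo, hi = config.drp_reliability_range
    rel = rng.uniform(lo, hi, size=geno.n_samples)
    err_sd = np.sqrt(var_tbv * (1.0 - rel) / rel)
    drp_values = tbv + rng.standard_normal(geno.n_samples) * err_sd

    drp = DRPTable(
        pd.DataFrame(
            {"id": geno.sample_ids, "drp": drp_values, "reliability": rel}
        )
    )
    effects = np.zeros(m)
    effects[qtl] = beta
    truth = SimTruth(
        ids=list(geno.sample_ids),
        tbv=tbv,
        marker_effects=effects,
        qtl_indices=qtl,
        var_tbv=var_tbv,
        var_env=var_env,
    )
    return drp, truth


@dataclass
class SimData:
    """Bundle of one simulated study population."""

    config: SimConfig
    genotypes: PhasedGenotypes
    pedigree: PedigreeTable
    drp: DRPTable
    truth: SimTruth

    @property
    def generations(self) -> np.ndarray:
        return generation_of(self.genotypes.sample_ids)

    def split(self) -> tuple[list[str], list[str]]:
        """Forward-validation split: the last generation is the test set."""
        gens = self.generations
        test_gen = gens.max()
        ids = np.asarray(self.genotypes.sample_ids)
        return list(ids[gens < test_gen]), list(ids[gens == test_gen])


def simulate(config: SimConfig) -> SimData:
    """Run the full generator: founders -> pedigree drop -> trait."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_founder_haplotypes(config, rng)
    geno, ped = drop_through_pedigree(founders, config, rng)
    drp, truth = simulate_trait(geno, ped, config, rng)
    return SimData(config=config, genotypes=geno, pedigree=ped, drp=drp,
                   truth=truth)
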