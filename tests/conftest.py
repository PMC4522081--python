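import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hapblock.io_formats import DRPTable, PedigreeTable, PhasedGenotypes
from hapblock.io_formats import MARKER_COLUMNS
from hapblock.simdata import SimConfig, simulate


def make_genotypes(haplotypes, chrom=None, sample_ids=None):
    """PhasedGenotypes from a raw (2n, m) matrix with an auto map."""
    h = np.asarray(haplotypes, dtype=np.int8)
    m = h.shape[1]
    chrom = ["1"] * m if chrom is None else list(chrom)
    n = h.shape[0] // 2
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    pos, counter = [], {}
    for c in chrom:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c] * 100)
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele0": "A",
            "allele1": "C",
        }
    )[MARKER_COLUMNS]
    return PhasedGenotypes(sample_ids, markers, h)


def make_drp(values, reliabilities, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.size)]
    return DRPTable(
        pd.DataFrame({"id": ids, "drp": values, "reliability": reliabilities})
    )


def random_pedigree(n, n_founders, rng):
    """Random sorted pedigree: founders first, then random matings."""
    recs = [(f"a{i}", None, None) for i in range(n_founders)]
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        recs.append((f"a{i}", f"a{s}", f"a{d}"))
    return PedigreeTable(recs)


@pytest.fixture(scope="session")
def default_sim():
    """The desk-scale study population shared across the suite."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced population for fast sampler and pipeline tests."""
    return simulate(
        SimConfig(
            seed=7,
            n_founders=60,
            n_generations=2,
            m_markers=300,
            n_chromosomes=2,
            n_qtl=15,
        )
    )
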