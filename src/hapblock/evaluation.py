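"""Prediction-quality statistics: reliability, bias, Hotelling-Williams test.

Validation follows the standard dairy-cattle forward-prediction scheme: GEBV
of test animals are compared against their deregressed proofs (DRP).  The
reliability of genomic prediction is the squared Pearson correlation between
DRP and GEBV corrected for the mean DRP reliability of the test animals,

    r^2 = Cor^2(DRP, GEBV) / mean(r2_DRP),

and the bias is b - 1 with b the least-squares slope of DRP regressed on
GEBV (b < 1: GEBV over-dispersed).

Two models evaluated on the same test set yield dependent correlations with
DRP; their equality is tested with the Hotelling-Williams t-test, whose
statistic is t-distributed with n - 3 degrees of freedom under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EvaluationResult:
    reliability: float
    correlation: float
    bias: float  # b - 1
    slope: float
    n_test: int


@dataclass(frozen=True)
class HWTest:
    r_drp_i: float
    r_drp_j: float
    r_ij: float
    n: int
    detR: float
    T: float
    p_value: float


def reliability(
    drp: np.ndarray, gebv: np.ndarray, mean_r2_drp: float
) -> EvaluationResult:
    """Reliability and bias of one GEBV vector against test-set DRP."""
    drp = np.asarray(drp, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if drp.shape != gebv.shape or drp.size < 3:
        raise ValueError("drp and gebv must have equal length >= 3")
    if not 0 < mean_r2_drp <= 1:
        raise ValueError("mean_r2_drp must lie in (0, 1]")
    if np.var(gebv) == 0:
        raise ValueError("zero-variance GEBV: reliability undefined")
    cor = float(np.corrcoef(drp, gebv)[0, 1])
    slope = float(np.polyfit(gebv, drp, 1)[0])
    return EvaluationResult(
        reliability=cor * cor / mean_r2_drp,
        correlation=cor,
        bias=slope - 1.0,
        slope=slope,
        n_test=drp.size,
    )


def hotelling_williams(
    drp: np.ndarray, gebv_i: np.ndarray, gebv_j: np.ndarray
) -> HWTest:
    """Test H0: Cor(DRP, GEBV_i) = Cor(DRP, GEBV_j) on the same animals.

    T = (r_di - r_dj) sqrt((n-3)(1+r_ij) / (2|R|)) /
        sqrt(1 + (n-3)(r_di+r_dj)^2 (1-r_ij)^3 / (8(n-1)|R|)),

    with |R| the determinant of the 3x3 correlation matrix of
    (DRP, GEBV_i, GEBV_j).  Under H0, T ~ t_{n-3}; the p-value is two-tailed.
    """
    drp = np.asarray(drp, dtype=float)
    gi = np.asarray(gebv_i, dtype=float)
    gj = np.asarray(gebv_j, dtype=float)
    n = drp.size
    if gi.size != n or gj.size != n or n < 4:
        raise ValueError("need three equal-length vectors with n >= 4")
    for v in (drp, gi, gj):
        if np.var(v) == 0:
            raise ValueError("zero-variance vector: correlations undefined")
    R = np.corrcoef(np.vstack([drp, gi, gj]))
    r_di, r_dj, r_ij = R[0, 1], R[0, 2], R[1, 2]
    detR = float(np.linalg.det(R))
    if r_di == r_dj:
        return HWTest(r_di, r_dj, r_ij, n, detR, 0.0, 1.0)
    if detR <= 0:
        raise ValueError(
            "singular correlation matrix (|R| <= 0): predictions collinear"
        )
    num = (r_di - r_dj) * np.sqrt((n - 3) * (1.0 + r_ij) / (2.0 * detR))
    den = np.sqrt(
        1.0 + (n - 3) * (r_di + r_dj) ** 2 * (1.0 - r_ij) ** 3
        / (8.0 * (n - 1) * detR)
    )
    T = float(num / den)
    p = float(2.0 * stats.t.sf(abs(T), df=n - 3))
    return HWTest(float(r_di), float(r_dj), float(r_ij), n, detR, T, p)


def evaluate_grid(
    drp: np.ndarray,
    mean_r2_drp: float,
    grid_gebv: dict[int, np.ndarray],
    full_blocks_gebv: np.ndarray,
    snp_gebv: np.ndarray,
) -> pd.DataFrame:
    """Comparison table over a k-grid, against the full-haploblock model.

    One row per k (reliability, bias, HW p-value vs the full-blocks model)
    plus a row for the full-blocks model and one for the individual-SNP
    model.  All GEBV vectors must cover the same test animals, in order.
    """
    n = np.asarray(drp).size
    for name, v in {"full_blocks": full_blocks_gebv, "snp": snp_gebv,
                    **{f"k={k}": g for k, g in grid_gebv.items()}}.items():
        if np.asarray(v).size != n:
            raise ValueError(f"GEBV vector {name} does not match the test set")
    rows = []
    for k in sorted(grid_gebv):
        res = reliability(drp, grid_gebv[k], mean_r2_drp)
        if np.array_equal(grid_gebv[k], full_blocks_gebv):
            p = 1.0
        else:
            p = hotelling_williams(drp, grid_gebv[k], full_blocks_gebv).p_value
        rows.append(("qtl", k, res.reliability, res.bias, p))
    res = reliability(drp, full_blocks_gebv, mean_r2_drp)
    rows.append(("full_blocks", None, res.reliability, res.bias, None))
    res = reliability(drp, snp_gebv, mean_r2_drp)
    p = hotelling_williams(drp, snp_gebv, full_blocks_gebv).p_value
    rows.append(("snp", None, res.reliability, res.bias, p))
    return pd.DataFrame(
        rows, columns=["model", "k", "reliability", "bias", "hw_p_vs_full"]
    )


def format_report(table: pd.DataFrame) -> str:
    """Plain-text rendering of an :func:`evaluate_grid` comparison table."""
    lines = [f"{'model':<14}{'k':>8}{'reliability':>13}{'bias':>9}"
             f"{'HW p vs full':>14}"]
    for row in table.itertuples(index=False):
        k = "" if row.k is None or (isinstance(row.k, float) and np.isnan(row.k)) \
            else int(row.k)
        p = "" if row.hw_p_vs_full is None or (
            isinstance(row.hw_p_vs_full, float) and np.isnan(row.hw_p_vs_full)
        ) else f"{row.hw_p_vs_full:.3f}"
        lines.append(
            f"{row.model:<14}{k!s:>8}{row.reliability:>13.3f}"
            f"{row.bias:>+9.3f}{p:>14}"
        )
    return "\n".join(lines)
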