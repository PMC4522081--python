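"""Single-chain Gibbs samplers for the two genomic prediction models.

Both models share the linear structure

    y = 1 mu + M g + Z a + e,    e ~ N(0, D sigma_e^2),

where y holds deregressed proofs of the training animals, M is a design
matrix of either individual-SNP dosages or haploblock-variant dosages, a is
a polygenic effect with a ~ N(0, A sigma_a^2) over *all* animals (training
and prediction candidates, linked through the pedigree), and D = diag(1/w_i)
with w_i = r2_i/(1-r2_i) weighting residuals by DRP reliability.

Bayesian BLUP places one common variance on all effects,
g ~ N(0, I sigma_g^2).  The four-component mixture draws each effect from
one of four normal components with fixed mixing proportions
pi = (0.889, 0.1, 0.01, 0.001) and component variances estimated under the
ordering constraint s1 < s2 < s3 < s4 (all priors improper uniform).

Sampling scheme, per cycle: mu (weighted normal), each effect g_j by
single-site weighted normal (mixture: component label first, by the
pi-weighted marginal likelihood of the four components), each polygenic
value a_i by single-site normal using A^-1, then the variances from their
scaled inverse chi-square conditionals (nu = count - 2, floored at 1).
Hot loops are numba-compiled; all randomness flows from one numpy Generator
so a seed reproduces the chain bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import DRPTable

MIXTURE_PROPORTIONS = (0.889, 0.1, 0.01, 0.001)

_VAR_FLOOR = 1e-12


@dataclass
class ModelSpec:
    """Configuration of one MCMC fit."""

    model: str = "blup"  # "blup" | "mixture4"
    mixture_proportions: tuple = MIXTURE_PROPORTIONS
    chain_length: int = 5000
    burn_in: int = 2000
    thinning: int = 1
    seed: int = 1
    include_polygenic: bool = True
    #: optional dict fixing variances (no updates): keys among
    #: sigma_g2, sigma_a2, sigma_e2, mixture_variances
    fix_variances: dict | None = None
    #: disable the s1<s2<s3<s4 constraint (diagnostics only)
    enforce_ordering: bool = True
    collect_traces: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("blup", "mixture4"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if abs(sum(self.mixture_proportions) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means after burn-in (thinned), plus bookkeeping."""

    mu: float
    g: np.ndarray
    a: np.ndarray  # over all animals carried in the chain (may be empty)
    animal_ids: list[str]
    sigma_e2: float
    sigma_a2: float
    sigma_g2: float | None  # BLUP only
    mixture_variances: np.ndarray | None  # mixture only
    n_retained: int
    model: str
    ordering_violations: int = 0
    traces: dict = field(default_factory=dict)

    def a_for(self, ids: list[str]) -> np.ndarray:
        if self.a.size == 0:
            return np.zeros(len(ids))
        lookup = {s: i for i, s in enumerate(self.animal_ids)}
        return self.a[[lookup[str(i)] for i in ids]]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _sweep_blup(Mt, wMt, e, g, cwm2, sg2, se2, z):
    q, n = Mt.shape
    for j in range(q):
        gj = g[j]
        s = 0.0
        for i in range(n):
            s += wMt[j, i] * e[i]
        rhs = (s + gj * cwm2[j]) / se2
        prec = cwm2[j] / se2 + 1.0 / sg2
        new = rhs / prec + z[j] / np.sqrt(prec)
        diff = new - gj
        if diff != 0.0:
            for i in range(n):
                e[i] -= Mt[j, i] * diff
        g[j] = new


@njit(cache=True, fastmath=True)
def _sweep_mixture(Mt, wMt, e, g, labels, cwm2, v4, log_pi, se2, z, u):
    q, n = Mt.shape
    for j in range(q):
        gj = g[j]
        s = 0.0
        for i in range(n):
            s += wMt[j, i] * e[i]
        r = (s + gj * cwm2[j]) / se2
        c = cwm2[j] / se2
        # component log marginal likelihoods (g_j integrated out)
        m0 = -1e300
        lw = np.empty(4)
        for k in range(4):
            t = 1.0 + c * v4[k]
            lw[k] = log_pi[k] - 0.5 * np.log(t) + 0.5 * r * r * v4[k] / t
            if lw[k] > m0:
                m0 = lw[k]
        tot = 0.0
        for k in range(4):
            lw[k] = np.exp(lw[k] - m0)
            tot += lw[k]
        target = u[j] * tot
        acc = 0.0
        lab = 3
        for k in range(4):
            acc += lw[k]
            if target <= acc:
                lab = k
                break
        labels[j] = lab
        prec = c + 1.0 / v4[lab]
        new = r / prec + z[j] / np.sqrt(prec)
        diff = new - gj
        if diff != 0.0:
            for i in range(n):
                e[i] -= Mt[j, i] * diff
        g[j] = new


@njit(cache=True, fastmath=True)
def _sweep_polygenic(indptr, indices, values, a, e, obs_row, w, sa2, se2, z):
    # A^-1 in CSR form: pedigree inverses are extremely sparse
    n_all = a.shape[0]
    for i in range(n_all):
        t = 0.0
        dii = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j == i:
                dii = values[p]
            else:
                t += values[p] * a[j]
        prec = dii / sa2
        rhs = -t / sa2
        r = obs_row[i]
        if r >= 0:
            etil = e[r] + a[i]
            prec += w[r] / se2
            rhs += w[r] * etil / se2
        new = rhs / prec + z[i] / np.sqrt(prec)
        if r >= 0:
            e[r] -= new - a[i]
        a[i] = new


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


def _draw_scaled_invchi2(rng: np.random.Generator, ss: float, count: int) -> float:
    """Flat-prior conditional: sigma^2 = ss / chi2_{nu}, nu = count-2 (>=1)."""
    nu = max(count - 2, 1)
    return max(ss, _VAR_FLOOR) / rng.chisquare(nu)


def fit(
    y: DRPTable,
    M: np.ndarray,
    spec: ModelSpec,
    a_inverse: np.ndarray | None = None,
    animal_ids: list[str] | None = None,
) -> PosteriorSummary:
    """Run one Gibbs chain and return posterior means.

    Parameters
    ----------
    y
        DRP of the training animals; rows of ``M`` must align with
        ``y.ids``.
    M
        Design matrix (n_train x q): SNP dosages or haploblock-variant
        dosages.
    spec
        Chain configuration.
    a_inverse
        Inverse numerator relationship matrix over ``animal_ids`` (required
        when ``spec.include_polygenic``).  Animals without phenotypes are
        carried in the chain so their polygenic values are sampled from the
        pedigree.
    animal_ids
        Ids indexing ``a_inverse``; must contain every training id.
    """
    w = np.ascontiguousarray(y.weights, dtype=np.float64)
    yv = y.values.astype(np.float64)
    Mt = np.ascontiguousarray(np.asarray(M, dtype=np.float64).T)
    q, n = Mt.shape
    if n != len(y.ids):
        raise ValueError("M rows do not match the training animals")
    wMt = np.ascontiguousarray(Mt * w[None, :])

    if spec.include_polygenic:
        if a_inverse is None or animal_ids is None:
            raise ValueError("polygenic effect requires a_inverse and animal_ids")
        from scipy.sparse import csr_matrix

        Acsr = csr_matrix(np.asarray(a_inverse, dtype=np.float64))
        a_indptr = Acsr.indptr.astype(np.int64)
        a_indices = Acsr.indices.astype(np.int64)
        a_values = Acsr.data.astype(np.float64)
        animal_ids = [str(s) for s in animal_ids]
        lookup = {s: i for i, s in enumerate(animal_ids)}
        obs_row = np.full(len(animal_ids), -1, dtype=np.int64)
        for r, s in enumerate(y.ids):
            obs_row[lookup[s]] = r
    else:
        a_indptr = np.zeros(1, dtype=np.int64)
        a_indices = np.zeros(0, dtype=np.int64)
        a_values = np.zeros(0)
        animal_ids = []
        obs_row = np.zeros(0, dtype=np.int64)
    n_all = len(animal_ids)

    rng = np.random.default_rng(spec.seed)
    fix = spec.fix_variances or {}

    var_y = float(np.var(yv)) or 1.0
    mu = float(np.average(yv, weights=w))
    g = np.zeros(q)
    a = np.zeros(n_all)
    base = var_y / (2.0 * q)
    sg2 = float(fix.get("sigma_g2", base))
    v4 = np.asarray(
        fix.get("mixture_variances", base * np.array([0.1, 1.0, 10.0, 100.0]))
    , dtype=np.float64).copy()
    sa2 = float(fix.get("sigma_a2", var_y / 4.0))
    se2 = float(fix.get("sigma_e2", var_y / 2.0))
    labels = np.zeros(q, dtype=np.int64)
    log_pi = np.log(np.asarray(spec.mixture_proportions))

    cwm2 = np.ascontiguousarray((wMt * Mt).sum(axis=1))
    e = yv - mu  # residual: y - mu - Mg - Za (g = a = 0 at start)

    sums = {"mu": 0.0, "g": np.zeros(q), "a": np.zeros(n_all),
            "sg2": 0.0, "v4": np.zeros(4), "sa2": 0.0, "se2": 0.0}
    n_ret = 0
    ordering_violations = 0
    traces: dict[str, list] = (
        {"sigma_e2": [], "sigma_a2": [], "sigma_g2": [],
         "mixture_variances": [], "g": [], "a": []}
        if spec.collect_traces else {}
    )

    sw = float(w.sum())
    mixture = spec.model == "mixture4"

    for cycle in range(spec.chain_length):
        # mean
        etil = e + mu
        new_mu = float(np.dot(w, etil) / sw) + rng.standard_normal() * np.sqrt(
            se2 / sw
        )
        e = etil - new_mu
        mu = new_mu

        # effects
        z_g = rng.standard_normal(q)
        if mixture:
            u = rng.random(q)
            _sweep_mixture(Mt, wMt, e, g, labels, cwm2, v4, log_pi, se2, z_g, u)
        else:
            _sweep_blup(Mt, wMt, e, g, cwm2, sg2, se2, z_g)

        # polygenic
        if spec.include_polygenic:
            z_a = rng.standard_normal(n_all)
            _sweep_polygenic(a_indptr, a_indices, a_values, a, e, obs_row, w,
                             sa2, se2, z_a)

        # variances
        if mixture:
            if "mixture_variances" not in fix:
                v4 = _update_mixture_variances(
                    rng, g, labels, v4, spec.enforce_ordering
                )
        else:
            if "sigma_g2" not in fix:
                sg2 = _draw_scaled_invchi2(rng, float(g @ g), q)
        if spec.include_polygenic and "sigma_a2" not in fix:
            sa2 = _draw_scaled_invchi2(rng, float(a @ (Acsr @ a)), n_all)
        if "sigma_e2" not in fix:
            se2 = _draw_scaled_invchi2(rng, float(np.dot(w, e * e)), n)

        if not np.isfinite(e).all():
            raise FloatingPointError(f"non-finite residual at cycle {cycle}")

        if cycle >= spec.burn_in and (cycle - spec.burn_in) % spec.thinning == 0:
            n_ret += 1
            sums["mu"] += mu
            sums["g"] += g
            sums["a"] += a
            sums["sg2"] += sg2
            sums["v4"] += v4
            sums["sa2"] += sa2
            sums["se2"] += se2
            if mixture and spec.enforce_ordering and np.any(np.diff(v4) <= 0):
                ordering_violations += 1
            if spec.collect_traces:
                traces["g"].append(g.copy())
                traces["a"].append(a.copy())
        if spec.collect_traces:
            traces["sigma_e2"].append(se2)
            traces["sigma_a2"].append(sa2)
            if mixture:
                traces["mixture_variances"].append(v4.copy())
            else:
                traces["sigma_g2"].append(sg2)

    return PosteriorSummary(
        mu=sums["mu"] / n_ret,
        g=sums["g"] / n_ret,
        a=sums["a"] / n_ret,
        animal_ids=animal_ids,
        sigma_e2=sums["se2"] / n_ret,
        sigma_a2=sums["sa2"] / n_ret,
        sigma_g2=None if mixture else sums["sg2"] / n_ret,
        mixture_variances=sums["v4"] / n_ret if mixture else None,
        n_retained=n_ret,
        model=spec.model,
        ordering_violations=ordering_violations,
        traces={k: np.asarray(v) for k, v in traces.items() if len(v)},
    )


def _update_mixture_variances(
    rng: np.random.Generator,
    g: np.ndarray,
    labels: np.ndarray,
    current: np.ndarray,
    enforce_ordering: bool,
    max_retries: int = 10,
) -> np.ndarray:
    """Sample the four component variances under the ordering constraint.

    Each occupied component's conditional is scaled inverse chi-square on its
    members' sum of squares; empty components keep their current value.  The
    joint draw is accepted only if strictly ordered; after ``max_retries``
    rejections the draw is projected by sorting.
    """
    ss = np.zeros(4)
    cnt = np.zeros(4, dtype=np.int64)
    for k in range(4):
        mask = labels == k
        cnt[k] = int(mask.sum())
        ss[k] = float(g[mask] @ g[mask])
    for _ in range(max_retries):
        prop = current.copy()
        for k in range(4):
            if cnt[k] > 0:
                prop[k] = _draw_scaled_invchi2(rng, ss[k], int(cnt[k]))
        if not enforce_ordering or np.all(np.diff(prop) > 0):
            return prop
    return np.sort(prop)


# ---------------------------------------------------------------------------
# prediction and ranking
# ---------------------------------------------------------------------------


def predict_gebv(
    summary: PosteriorSummary,
    M_new: np.ndarray,
    sample_ids: list[str],
) -> np.ndarray:
    """GEBV_i = sum_j m_ij g_hat_j + a_hat_i from the posterior means.

    ``M_new`` columns must match the training design; polygenic values for
    the requested animals come from the chain (they were carried in ``a``
    without a phenotype link).
    """
    M_new = np.asarray(M_new, dtype=np.float64)
    if M_new.shape[1] != summary.g.shape[0]:
        raise ValueError(
            f"design has {M_new.shape[1]} columns, model has {summary.g.shape[0]}"
        )
    return M_new @ summary.g + summary.a_for(sample_ids)


def snp_effect_table(
    summary: PosteriorSummary, markers: pd.DataFrame
) -> pd.DataFrame:
    """Rank posterior-mean SNP effects by |effect|, descending.

    Ties are broken by genome order (the marker map order), making the
    ranking deterministic.  Requires a fit whose design was the SNP dosage
    matrix, one column per marker.
    """
    if len(markers) != summary.g.shape[0]:
        raise ValueError("effect vector does not match the marker map")
    df = markers[["marker_id", "chrom", "pos"]].copy()
    df["marker_index"] = np.arange(len(df))
    df["effect"] = summary.g
    df["abs_effect"] = np.abs(summary.g)
    order = np.lexsort((df["marker_index"].to_numpy(), -df["abs_effect"].to_numpy()))
    ranks = np.empty(len(df), dtype=np.int64)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return df.sort_values("rank").reset_index(drop=True)


def mme_solution(
    y: DRPTable,
    M: np.ndarray,
    sigma_g2: float,
    sigma_a2: float,
    sigma_e2: float,
    a_inverse: np.ndarray | None = None,
    animal_ids: list[str] | None = None,
) -> dict:
    """Direct solve of the weighted mixed-model equations at fixed variances.

    Returns the joint posterior mode/mean of (mu, g, a) given the variances —
    the reference the fixed-variance Gibbs chain must reproduce.
    """
    w = y.weights
    yv = y.values
    Mf = np.asarray(M, dtype=np.float64)
    n, q = Mf.shape
    ones = np.ones((n, 1))
    if a_inverse is not None:
        animal_ids = [str(s) for s in animal_ids]
        Z = np.zeros((n, len(animal_ids)))
        lookup = {s: i for i, s in enumerate(animal_ids)}
        for r, s in enumerate(y.ids):
            Z[r, lookup[s]] = 1.0
        X = np.hstack([ones, Mf, Z])
        penalty = np.zeros((X.shape[1], X.shape[1]))
        penalty[1 : 1 + q, 1 : 1 + q] = np.eye(q) / sigma_g2
        penalty[1 + q :, 1 + q :] = np.asarray(a_inverse) / sigma_a2
    else:
        X = np.hstack([ones, Mf])
        penalty = np.zeros((X.shape[1], X.shape[1]))
        penalty[1:, 1:] = np.eye(q) / sigma_g2
    Winv = w / sigma_e2
    lhs = (X * Winv[:, None]).T @ X + penalty
    rhs = (X * Winv[:, None]).T @ yv
    sol = np.linalg.solve(lhs, rhs)
    out = {"mu": sol[0], "g": sol[1 : 1 + q]}
    if a_inverse is not None:
        out["a"] = sol[1 + q :]
    return out
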