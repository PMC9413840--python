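"""Inferential layer: permutation tests, FDR, motion sensitivity, power.

All permutation tests are two-sided, seeded, and use the add-one
estimator p = (1 + #{permutation stat at least as extreme}) / (n_perm + 1),
so p >= 1/(n_perm + 1) and p = 0 is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as _ndimage
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "classify_response",
    "motion_summary_metrics",
    "remove_outliers_3iqr",
    "perm_test_two_group",
    "perm_test_two_group_many",
    "omnibus_group_by_metric",
    "fdr_bh",
    "kendall_tau",
    "kendall_tau_many",
    "motion_sensitivity_suite",
    "cluster_perm_test",
    "min_detectable_effect",
]


@dataclass
class PermutationResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    seed: int
    statistic_name: str


# ---------------------------------------------------------------------------
# Clinical classification and motion summaries
# ---------------------------------------------------------------------------


def classify_response(caps_pre: float, caps_post: float) -> bool:
    """Responder iff the CAPS total dropped by at least 30% (inclusive)."""
    if caps_pre <= 0:
        raise ValueError("caps_pre must be positive")
    return (caps_pre - caps_post) / caps_pre >= 0.30


def motion_summary_metrics(
    fd: np.ndarray, threshold: float = 0.2
) -> dict[str, float]:
    """Median FD, max FD, motion-outlier count (FD > threshold), FD IQR.

    Quantiles use linear interpolation between order statistics (the
    outlier count uses a strict exceedance, matching spike flagging).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    q1, q3 = np.percentile(fd, [25, 75], method="linear")
    return {
        "median_fd": float(np.median(fd)),
        "max_fd": float(fd.max()),
        "n_outliers": int(np.sum(fd > threshold)),
        "iqr_fd": float(q3 - q1),
    }


def remove_outliers_3iqr(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 3*IQR outlier removal.

    A value is removed iff it is strictly below Q1 - 3*IQR or strictly
    above Q3 + 3*IQR, with quartiles by linear interpolation.  Returns
    (retained values, indices of removed values).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for the 3*IQR rule")
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    removed = (values < q1 - 3 * iqr) | (values > q3 + 3 * iqr)
    return values[~removed], np.flatnonzero(removed)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

_STATS = {
    "mean_diff": lambda x, y: np.mean(x) - np.mean(y),
    "median_diff": lambda x, y: np.median(x) - np.median(y),
    "t": lambda x, y: _sps.ttest_ind(x, y, equal_var=True).statistic,
}


def perm_test_two_group(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> PermutationResult:
    """Two-sided label-permutation test for a two-group difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATS[statistic]
    observed = float(stat(x, y))
    pooled = np.concatenate([x, y])
    n1 = x.size
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(stat(perm[:n1], perm[n1:])) >= abs(observed) - 1e-12:
            count += 1
    return PermutationResult(
        observed_stat=observed,
        p_value=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
        statistic_name=statistic,
    )


def _perm_group_means(values: np.ndarray, n1: int, perm_idx: np.ndarray):
    """Group-mean differences for many permutations at once.

    values: (n,) or (n, m); perm_idx: (n_perm, n) permuted subject indices.
    Returns (n_perm,) or (n_perm, m) mean(group1) - mean(group2).
    """
    v = values[perm_idx]  # (n_perm, n[, m])
    n = values.shape[0]
    return v[:, :n1].mean(axis=1) - v[:, n1:].mean(axis=1)


def perm_test_two_group_many(
    X1: np.ndarray,
    X2: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mean-difference permutation tests across many variables.

    ``X1`` (n1, m) and ``X2`` (n2, m) hold the same m variables for the
    two groups.  Returns (observed differences, two-sided add-one
    p-values), sharing one permutation stream across variables.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    pooled = np.vstack([X1, X2])
    n1, n = X1.shape[0], pooled.shape[0]
    rng = np.random.default_rng(seed)
    observed = X1.mean(axis=0) - X2.mean(axis=0)
    count = np.zeros(pooled.shape[1], dtype=np.int64)
    chunk = max(1, int(20_000_000 / max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm_idx = np.array([rng.permutation(n) for _ in range(b)])
        null = _perm_group_means(pooled, n1, perm_idx)  # (b, m)
        count += (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
        done += b
    return observed, (1 + count) / (n_perm + 1)


def _rm_anova_F(long: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Repeated-measures two-way F statistics (group, metric, interaction).

    long: (n_subjects, n_metrics); groups: (n_subjects,) integer labels.
    Group is a between-subject factor, metric a within-subject factor.
    """
    n, m = long.shape
    glabels = np.unique(groups)
    grand = long.mean()
    subj_means = long.mean(axis=1)
    metric_means = long.mean(axis=0)

    ss_between_subj = m * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_inter = 0.0
    for g in glabels:
        sel = groups == g
        ng = sel.sum()
        gm = long[sel].mean()
        ss_group += m * ng * (gm - grand) ** 2
        cell = long[sel].mean(axis=0)
        ss_inter += ng * np.sum((cell - gm - metric_means + grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_metric = n * np.sum((metric_means - grand) ** 2)
    ss_total = np.sum((long - grand) ** 2)
    ss_resid = ss_total - ss_between_subj - ss_metric - ss_inter

    G = glabels.size
    df_group, df_sw = G - 1, n - G
    df_metric = m - 1
    df_inter = df_group * df_metric
    df_resid = df_sw * df_metric

    def _f(ss_num, df_num, ss_den, df_den):
        den = ss_den / df_den if df_den > 0 else 0.0
        if den <= 0:
            return 0.0
        return (ss_num / df_num) / den

    return (
        _f(ss_group, df_group, ss_subj_within, df_sw),
        _f(ss_metric, df_metric, ss_resid, df_resid),
        _f(ss_inter, df_inter, ss_resid, df_resid),
    )


def omnibus_group_by_metric(
    table: np.ndarray | pd.DataFrame,
    groups: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation omnibus test for group, metric and group-by-metric effects.

    Each metric column is z-standardized across subjects, the table is
    treated as a balanced two-way layout (between-subject group factor,
    within-subject metric factor) and F-type statistics are computed.
    Null distributions: the group and interaction effects permute subject
    group labels (whole subjects, preserving within-subject structure);
    the metric effect shuffles metric labels within each subject.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x metrics table with >= 2 metrics")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        name = table.columns[j] if isinstance(table, pd.DataFrame) else str(j)
        raise ValueError(f"constant metric column {name!r}")
    Z = (X - X.mean(axis=0)) / sd
    groups = np.asarray(groups)

    f_group, f_metric, f_inter = _rm_anova_F(Z, groups)
    rng = np.random.default_rng(seed)
    cg = cm = ci = 0
    for _ in range(n_perm):
        gperm = rng.permutation(groups)
        fg, _fm, fi = _rm_anova_F(Z, gperm)
        cg += fg >= f_group - 1e-12
        ci += fi >= f_inter - 1e-12
        Zp = np.take_along_axis(
            Z, np.argsort(rng.random(Z.shape), axis=1), axis=1
        )
        _fg2, fm, _fi2 = _rm_anova_F(Zp, groups)
        cm += fm >= f_metric - 1e-12
    return {
        "F_group": f_group,
        "F_metric": f_metric,
        "F_interaction": f_inter,
        "p_group": (1 + cg) / (n_perm + 1),
        "p_metric": (1 + cm) / (n_perm + 1),
        "p_interaction": (1 + ci) / (n_perm + 1),
    }


# ---------------------------------------------------------------------------
# Multiple testing and rank correlation
# ---------------------------------------------------------------------------


def fdr_bh(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b with exact p for small n, normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must share length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    has_ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    method = "exact" if (x.size <= 10 and not has_ties) else "asymptotic"
    res = _sps.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def kendall_tau_many(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """tau-b of one vector against many, vectorized over columns of Y.

    ``x`` has shape (n,), ``Y`` shape (n, m).  Returns (tau, p) arrays of
    length m with NaN where a column is constant (undefined correlation).
    P-values use the no-ties normal approximation
    z = 3(C - D) / sqrt(n(n-1)(2n+5)/2); continuous inputs are assumed
    effectively tie-free (any pair ties only shrink the tau-b numerator
    consistently with the denominator correction applied here).
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = x.size
    if Y.shape[0] != n:
        raise ValueError("Y rows must match x length")
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])  # (P,)
    n0 = n * (n - 1) / 2.0
    tx = np.sum(sx == 0)

    m = Y.shape[1]
    tau = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    # chunk to bound memory at ~P x chunk floats
    chunk = max(1, int(2_000_000 / max(iu.size, 1)))
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    for start in range(0, m, chunk):
        sub = Y[:, start : start + chunk]
        sy = np.sign(sub[iu] - sub[ju])  # (P, c)
        ty = (sy == 0).sum(axis=0)
        num = sx @ sy  # C - D per column
        denom = np.sqrt((n0 - tx) * (n0 - ty))
        ok = denom > 0
        t = np.full(sub.shape[1], np.nan)
        t[ok] = num[ok] / denom[ok]
        z = num / np.sqrt(var_s)
        p = 2 * _sps.norm.sf(np.abs(z))
        p[~ok] = np.nan
        tau[start : start + chunk] = t
        pval[start : start + chunk] = p
    return tau, pval


# ---------------------------------------------------------------------------
# Motion sensitivity suite
# ---------------------------------------------------------------------------


@dataclass
class MotionSensitivityReport:
    """Residual-motion diagnostics for the connectome analysis."""

    pct_significant_edges: float
    edge_tau: np.ndarray
    edge_tau_mean: float
    n_undefined_edges: int
    global_metric_results: pd.DataFrame  # metric, tau, p
    nodal_results: pd.DataFrame  # node, metric, tau, p, p_fdr, significant
    leaf_fraction_motion_confounded: bool = field(default=False)


def motion_sensitivity_suite(
    matrices: np.ndarray,
    nodal_degree: np.ndarray,
    nodal_bc: np.ndarray,
    global_table: pd.DataFrame,
    mean_fd: np.ndarray,
    alpha: float = 0.05,
) -> MotionSensitivityReport:
    """Kendall-tau screen of residual motion against connectome outcomes.

    Four checks: (1) per-edge tau(edge strength, mean FD) with BH-FDR
    across all edges -> percentage of significant edges; (2) the full
    distribution of those tau values and its mean; (3) tau + uncorrected p
    per global metric; (4) per-node tau for degree and betweenness with
    BH-FDR.  A significant leaf-fraction association flags that metric as
    motion-confounded (callers should drop it from group testing).

    Parameters
    ----------
    matrices
        (n_subjects, N, N) stack of connectivity matrices.
    nodal_degree, nodal_bc
        (n_subjects, N) nodal metric tables.
    global_table
        DataFrame (n_subjects x global metrics).
    mean_fd
        (n_subjects,) average FD per subject.
    """
    matrices = np.asarray(matrices, dtype=float)
    mean_fd = np.asarray(mean_fd, dtype=float)
    n_subj = mean_fd.size
    for name, arr in (
        ("matrices", matrices),
        ("nodal_degree", nodal_degree),
        ("nodal_bc", nodal_bc),
        ("global_table", global_table),
    ):
        if np.asarray(arr).shape[0] != n_subj:
            raise ValueError(f"{name} has wrong subject count")
    if n_subj < 10:
        raise ValueError("need at least 10 subjects")

    N = matrices.shape[1]
    iu, ju = np.triu_indices(N, k=1)
    edge_strength = matrices[:, iu, ju]  # (n_subj, n_edges)

    tau_e, p_e = kendall_tau_many(mean_fd, edge_strength)
    defined = ~np.isnan(tau_e)
    n_undef = int((~defined).sum())
    if defined.any():
        rej, _ = fdr_bh(p_e[defined], alpha=alpha)
        pct_sig = 100.0 * rej.sum() / defined.sum()
        tau_mean = float(tau_e[defined].mean())
    else:
        pct_sig, tau_mean = 0.0, float("nan")

    grows = []
    for col in global_table.columns:
        vals = np.asarray(global_table[col], dtype=float)
        try:
            t, p = kendall_tau(mean_fd, vals)
        except ValueError:
            t, p = float("nan"), float("nan")
        grows.append({"metric": col, "tau": t, "p": p})
    gdf = pd.DataFrame(grows)
    leaf_rows = gdf[gdf["metric"] == "leaf_fraction"]
    leaf_confounded = bool(
        len(leaf_rows) and np.nan_to_num(leaf_rows["p"].iloc[0], nan=1.0) < alpha
    )

    nrows = []
    for mname, table in (("degree", nodal_degree), ("betweenness", nodal_bc)):
        t, p = kendall_tau_many(mean_fd, np.asarray(table, dtype=float))
        ok = ~np.isnan(t)
        p_fdr = np.full_like(p, np.nan)
        sig = np.zeros(p.size, dtype=bool)
        if ok.any():
            rej, adj = fdr_bh(p[ok], alpha=alpha)
            p_fdr[ok] = adj
            sig[ok] = rej
        for node in range(t.size):
            nrows.append(
                {
                    "node": node,
                    "metric": mname,
                    "tau": t[node],
                    "p": p[node],
                    "p_fdr": p_fdr[node],
                    "significant": bool(sig[node]),
                }
            )
    return MotionSensitivityReport(
        pct_significant_edges=float(pct_sig),
        edge_tau=tau_e,
        edge_tau_mean=tau_mean,
        n_undefined_edges=n_undef,
        global_metric_results=gdf,
        nodal_results=pd.DataFrame(nrows),
        leaf_fraction_motion_confounded=leaf_confounded,
    )


# ---------------------------------------------------------------------------
# Cluster-based permutation test (voxel maps)
# ---------------------------------------------------------------------------


def _two_sample_t_many(X: np.ndarray, idx: np.ndarray, n1: int) -> np.ndarray:
    """Pooled-variance two-sample t maps for many label permutations.

    X: (n, V); idx: (n_perm, n) permuted subject orders (first n1 = group 1).
    Returns (n_perm, V).
    """
    n = X.shape[0]
    n2 = n - n1
    Xp = X[idx]  # (n_perm, n, V)
    g1, g2 = Xp[:, :n1], Xp[:, n1:]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.nan_to_num(t)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _cluster_masses(tmap: np.ndarray, t_crit: float, mask: np.ndarray):
    """26-connected suprathreshold clusters of |t|; returns labels + masses."""
    supra = (np.abs(tmap) > t_crit) & mask
    labels, n_clus = _ndimage.label(supra, structure=_STRUCT26)
    if n_clus == 0:
        return labels, np.zeros(0)
    masses = _ndimage.sum_labels(np.abs(tmap), labels, index=np.arange(1, n_clus + 1))
    return labels, masses


def cluster_perm_test(
    maps: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    cdt_p: float = 0.001,
    n_perm: int = 10000,
    alpha_fwe: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-mass permutation test on 3-D maps with FWE correction.

    Covariates of no interest are regressed out of every voxel first
    (Freedman-Lane residualization), a pooled-variance two-sample t is
    computed per voxel, voxels with |t| above the two-sided
    cluster-defining threshold are grouped by 26-connectivity, and each
    cluster's mass (sum of suprathreshold |t|) is compared with the
    permutation null of the maximum cluster mass.

    Returns a cluster table (cluster_id, n_voxels, mass, peak_t, p_fwe,
    significant) sorted by descending mass; empty if no cluster forms.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, X, Y, Z)")
    groups = np.asarray(groups)
    glabels = np.unique(groups)
    if glabels.size != 2:
        raise ValueError("exactly two groups required")
    sel1 = groups == glabels[0]
    n1, n2 = int(sel1.sum()), int((~sel1).sum())
    if min(n1, n2) < 3:
        raise ValueError("need at least 3 subjects per group")
    shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    elif mask.shape != shape:
        raise ValueError("mask grid does not match maps")

    order = np.concatenate([np.flatnonzero(sel1), np.flatnonzero(~sel1)])
    X = maps.reshape(maps.shape[0], -1)[order][:, mask.ravel()]
    n = X.shape[0]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != maps.shape[0]:
            C = C.T
        C = C[order]
        D = np.column_stack([np.ones(n), C])
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        X = X - D @ beta

    df = n1 + n2 - 2
    t_crit = _sps.t.isf(cdt_p / 2.0, df)

    def _tvol(tflat: np.ndarray) -> np.ndarray:
        vol = np.zeros(shape)
        vol[mask] = tflat
        return vol

    t_obs = _two_sample_t_many(X, np.arange(n)[None, :], n1)[0]
    tvol = _tvol(t_obs)
    labels, masses = _cluster_masses(tvol, t_crit, mask)

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    null_max = np.zeros(n_perm)
    chunk = max(1, int(5_000_000 / max(X.size, 1)))
    for start in range(0, n_perm, chunk):
        tnull = _two_sample_t_many(X, perm_idx[start : start + chunk], n1)
        for k in range(tnull.shape[0]):
            _lab, m = _cluster_masses(_tvol(tnull[k]), t_crit, mask)
            null_max[start + k] = m.max() if m.size else 0.0

    rows = []
    for cid in np.argsort(masses)[::-1]:
        mass = masses[cid]
        in_c = labels == cid + 1
        p_fwe = (1 + np.sum(null_max >= mass - 1e-12)) / (n_perm + 1)
        rows.append(
            {
                "cluster_id": int(cid + 1),
                "n_voxels": int(in_c.sum()),
                "mass": float(mass),
                "peak_t": float(tvol[in_c][np.argmax(np.abs(tvol[in_c]))]),
                "p_fwe": float(p_fwe),
                "significant": bool(p_fwe < alpha_fwe),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_voxels", "mass", "peak_t", "p_fwe", "significant"],
    )


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


def _t_power(d: float, n1: int, n2: int, alpha: float) -> float:
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = _sps.t.isf(alpha / 2.0, df)
    return float(_sps.nct.sf(t_crit, df, nc) + _sps.nct.cdf(-t_crit, df, nc))


def min_detectable_effect(
    n1: int, n2: int, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Smallest Cohen's d detectable by a two-sided two-sample t-test.

    Uses the noncentral-t distribution with df = n1 + n2 - 2 and
    noncentrality d*sqrt(n1*n2/(n1+n2)); solved by bisection to 1e-4.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    lo, hi = 1e-8, 1.0
    while _t_power(hi, n1, n2, alpha) < power:
        hi *= 2
        if hi > 1e4:
            raise ValueError("unattainable power for these group sizes")
    while hi - lo > 1e-4:
        mid = (lo + hi) / 2.0
        if _t_power(mid, n1, n2, alpha) < power:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
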