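"""Statistical analysis of Procrustes-aligned shape coordinates.

Procrustes ANOVA of a specimen x side design (Goodall-style F with degrees
of freedom scaled by the shape dimension 2k-4), pooled within-group
allometric regression of shape on centroid size, principal component
analysis, shape reconstruction along ordination axes, canonical variate
analysis on a priori groups, and Mahalanobis/Procrustes group distances
with permutation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProcrustesAnovaTable",
    "AllometryModel",
    "Ordination",
    "CvaResult",
    "procrustes_anova",
    "allometry_regress",
    "pca",
    "shape_along_axis",
    "cva",
    "group_distance_tests",
]


def _as_matrix(shapes) -> np.ndarray:
    """Accept (n, k, 2) or (n, 2k); return (n, 2k) float matrix."""
    arr = np.asarray(shapes, float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2:
        raise ValueError("shapes must be (n, 2k) or (n, k, 2)")
    return arr


# ---------------------------------------------------------------------------
# Procrustes ANOVA
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesAnovaTable:
    """Decomposition of Procrustes sums of squares over design factors.

    Rows carry (effect, SS, df, MS, F, P); SS over effects plus residual
    equals the total SS, and degrees of freedom are the univariate ones
    multiplied by the shape-space dimension 2k-4.
    """

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["effect", "SS", "df", "MS", "F", "P", "P_perm"]
        )

    def __getitem__(self, effect: str):
        for row in self.rows:
            if row[0] == effect:
                return row
        raise KeyError(effect)


def _factor_ss(data: np.ndarray, labels: np.ndarray, grand: np.ndarray) -> float:
    ss = 0.0
    for lev in np.unique(labels):
        sel = labels == lev
        m = data[sel].mean(axis=0)
        ss += sel.sum() * float(np.sum((m - grand) ** 2))
    return ss


def procrustes_anova(
    shapes,
    individual,
    side,
    *,
    shape_dim: int | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> ProcrustesAnovaTable:
    """Sequential Procrustes ANOVA of aligned shapes over specimen and side.

    SS(individual) and SS(side) come from factor-level means against the
    grand mean; the individual x side remainder is the residual. F is the
    Goodall-style ratio MS(effect)/MS(residual) with df scaled by the shape
    dimension (2k - 4 by default); parametric P from the F distribution,
    plus optional permutation P (residual permutation) when n_perm > 0.
    The design may be unbalanced (specimens with one or two sides).
    """
    data = _as_matrix(shapes)
    individual = np.asarray(individual)
    side = np.asarray(side)
    n_obs = data.shape[0]
    if len(individual) != n_obs or len(side) != n_obs:
        raise ValueError("factor lengths must match number of observations")
    if len(np.unique(individual)) < 2:
        raise ValueError("need at least 2 individuals")
    if shape_dim is None:
        shape_dim = data.shape[1] - 4  # 2k - 4 for 2D Procrustes shapes

    grand = data.mean(axis=0)
    ss_total = float(np.sum((data - grand) ** 2))

    table = ProcrustesAnovaTable()
    if ss_total == 0.0:
        for name, levels in (("between-specimen", individual), ("within-specimen", side)):
            df = (len(np.unique(levels)) - 1) * shape_dim
            table.rows.append([name, 0.0, df, 0.0, np.nan, np.nan, np.nan])
        table.rows.append(["residual", 0.0, 0, 0.0, np.nan, np.nan, np.nan])
        table.rows.append(["total", 0.0, (n_obs - 1) * shape_dim, 0.0, np.nan, np.nan, np.nan])
        return table

    effects = []
    ss_effects = 0.0
    df_effects = 0
    for name, labels in (("between-specimen", individual), ("within-specimen", side)):
        levels = np.unique(labels)
        if len(levels) < 2:
            warnings.warn(f"factor {name!r} has one level; row omitted", stacklevel=2)
            continue
        ss = _factor_ss(data, labels, grand)
        df = (len(levels) - 1) * shape_dim
        effects.append((name, labels, ss, df))
        ss_effects += ss
        df_effects += df

    df_total = (n_obs - 1) * shape_dim
    ss_resid = ss_total - ss_effects
    df_resid = df_total - df_effects
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rng = np.random.default_rng(seed)
    for name, labels, ss, df in effects:
        ms = ss / df
        F = ms / ms_resid if ms_resid and np.isfinite(ms_resid) else np.nan
        P = float(stats.f.sf(F, df, df_resid)) if np.isfinite(F) else np.nan
        p_perm = np.nan
        if n_perm > 0 and np.isfinite(F):
            count = 0
            for _ in range(n_perm - 1):
                perm = rng.permutation(n_obs)
                ss_p = _factor_ss(data, labels[perm], grand)
                other_ss = sum(s for nm, lb, s, d in effects if nm != name)
                ss_r = ss_total - ss_p - other_ss
                f_p = (ss_p / df) / (ss_r / df_resid) if ss_r > 0 else np.inf
                if f_p >= F:
                    count += 1
            p_perm = min(1.0, (count + 1) / n_perm)
        table.rows.append([name, ss, df, ms, F, P, p_perm])

    table.rows.append(["residual", ss_resid, df_resid, ms_resid, np.nan, np.nan, np.nan])
    table.rows.append(["total", ss_total, df_total, ss_total / df_total, np.nan, np.nan, np.nan])
    return table


# ---------------------------------------------------------------------------
# Allometry: pooled within-group regression of shape on size
# ---------------------------------------------------------------------------

@dataclass
class AllometryModel:
    """Pooled within-group regression of shape coordinates on centroid size.

    ``slope`` is the common 2k-vector of shape change per unit size;
    ``percent_predicted`` the share of pooled within-group shape variance
    the regression explains; ``residuals`` keep the group mean differences
    (observed minus common-slope prediction), since downstream ordinations
    must still separate species and habitats.
    """

    slope: np.ndarray
    percent_predicted: float
    residuals: np.ndarray
    size_transform: str = "identity"
    excluded_groups: list = field(default_factory=list)
    p_value: float = float("nan")


def allometry_regress(
    shapes,
    sizes,
    groups,
    *,
    size_transform: str = "identity",
    n_perm: int = 0,
    seed: int | None = None,
) -> AllometryModel:
    """Regress pooled within-group shape on centroid size (common slope).

    Shapes and sizes are centered within groups; the common slope is
    b = sum_i s_i y_i / sum_i s_i^2 over the within-centered values.
    Groups with fewer than 2 members or zero within-group size variance are
    centered but excluded from slope estimation. Optional permutation test
    shuffles sizes within groups, statistic = percent predicted.
    """
    data = _as_matrix(shapes)
    sizes = np.asarray(sizes, float)
    groups = np.asarray(groups)
    n = data.shape[0]
    if size_transform == "log":
        sizes = np.log(sizes)
    elif size_transform != "identity":
        raise ValueError("size_transform must be 'identity' or 'log'")

    s_cent = np.empty(n)
    y_cent = np.empty_like(data)
    contributes = np.zeros(n, dtype=bool)
    excluded = []
    group_index = {}
    for lev in np.unique(groups):
        sel = groups == lev
        group_index[lev] = sel
        s_cent[sel] = sizes[sel] - sizes[sel].mean()
        y_cent[sel] = data[sel] - data[sel].mean(axis=0)
        if sel.sum() >= 2 and np.var(sizes[sel]) > 0:
            contributes[sel] = True
        else:
            excluded.append(lev)
    if excluded and not contributes.any():
        raise ValueError("no group has within-group size variance; cannot regress")
    if excluded:
        warnings.warn(
            f"groups excluded from slope estimation: {excluded}", stacklevel=2
        )

    def _fit(s_vec):
        denom = float(np.sum(s_vec[contributes] ** 2))
        b = (s_vec[contributes] @ y_cent[contributes]) / denom
        predicted = np.outer(s_vec, b)
        predicted[~contributes] = 0.0
        ss_within = float(np.sum(y_cent[contributes] ** 2))
        ss_pred = float(np.sum(predicted[contributes] ** 2))
        pct = 100.0 * ss_pred / ss_within if ss_within > 0 else 0.0
        return b, predicted, pct

    slope, predicted, pct = _fit(s_cent)
    residuals = data - predicted

    p_value = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        s_perm = s_cent.copy()
        for _ in range(n_perm - 1):
            for sel in group_index.values():
                idx = np.flatnonzero(sel)
                s_perm[idx] = s_cent[idx][rng.permutation(idx.size)]
            _, _, pct_p = _fit(s_perm)
            if pct_p >= pct:
                count += 1
        p_value = min(1.0, (count + 1) / n_perm)

    return AllometryModel(
        slope=slope,
        percent_predicted=pct,
        residuals=residuals,
        size_transform=size_transform,
        excluded_groups=excluded,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Principal component analysis
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """Eigen-decomposition of the shape covariance matrix.

    ``axes`` rows are orthonormal 2k-vectors (descending eigenvalue);
    ``scores`` are mean-centered projections of the input data.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    axes: np.ndarray
    scores: np.ndarray


def pca(data, mean_override=None) -> Ordination:
    """PCA of shape coordinates via the sample covariance (divisor n-1).

    Axes with eigenvalue below 1e-12 of the largest are dropped. Axis signs
    are fixed so each axis's largest-magnitude loading is positive.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = X.mean(axis=0) if mean_override is None else np.asarray(mean_override, float)
    C = X - mean
    # SVD of centered data == eigen-decomposition of covariance
    _, sing, Vt = np.linalg.svd(C - C.mean(axis=0), full_matrices=False)
    eigvals = sing**2 / (n - 1)
    keep = eigvals > 1e-12 * (eigvals[0] if eigvals.size else 1.0)
    eigvals = eigvals[keep]
    axes = Vt[keep]
    # deterministic sign convention
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    scores = (X - X.mean(axis=0)) @ axes.T
    total = eigvals.sum()
    pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    return Ordination(
        mean=mean,
        eigenvalues=eigvals,
        percent_variance=pct,
        axes=axes,
        scores=scores,
    )


def shape_along_axis(ordination: Ordination, axis: int, scale: float) -> np.ndarray:
    """Reconstruct the shape at a signed Procrustes distance along one axis.

    Returns mean + scale * axis reshaped to (k, 2); since axes are unit
    vectors the Procrustes distance from the mean equals |scale|.
    """
    if not (0 <= axis < ordination.axes.shape[0]):
        raise IndexError(f"axis {axis} out of range")
    vec = ordination.mean + scale * ordination.axes[axis]
    return _unflatten(vec)


def _unflatten(vec: np.ndarray) -> np.ndarray:
    """2k-vector (x-block then y-block) back to (k, 2)."""
    k = vec.size // 2
    return np.column_stack([vec[:k], vec[k:]])


# ---------------------------------------------------------------------------
# Canonical variate analysis
# ---------------------------------------------------------------------------

@dataclass
class CvaResult:
    """CVA of a priori groups plus pairwise distances and permutation P.

    ``cv_axes`` live in the original data space and are scaled so the
    pooled within-group variance of each score column is 1; ``mahalanobis``
    and ``procrustes_dist`` are g x g symmetric matrices with matching
    permutation P matrices.
    """

    cv_axes: np.ndarray
    cv_eigenvalues: np.ndarray
    percent_between_variance: np.ndarray
    scores: np.ndarray
    group_names: list
    mahalanobis: np.ndarray | None = None
    procrustes_dist: np.ndarray | None = None
    p_mahalanobis: np.ndarray | None = None
    p_procrustes: np.ndarray | None = None


def _project_full_rank(X: np.ndarray, rel_tol: float = 1e-9):
    """Project data onto principal axes with nonzero variance."""
    Xc = X - X.mean(axis=0)
    _, sing, Vt = np.linalg.svd(Xc, full_matrices=False)
    if sing.size == 0 or sing[0] == 0.0:
        raise ValueError("data have no variance")
    keep = sing > np.sqrt(rel_tol) * sing[0]
    basis = Vt[keep]
    return X @ basis.T, basis


def _pooled_within(Xp: np.ndarray, labels: np.ndarray, levels) -> np.ndarray:
    n, g = Xp.shape[0], len(levels)
    W = np.zeros((Xp.shape[1], Xp.shape[1]))
    for lev in levels:
        sub = Xp[labels == lev]
        d = sub - sub.mean(axis=0)
        W += d.T @ d
    return W / (n - g)


def cva(data, labels, *, rel_tol: float = 1e-9) -> CvaResult:
    """Canonical variate analysis: axes maximizing between- relative to
    within-group variance.

    Data are first projected to a full-rank principal basis; the generalized
    eigenproblem B a = lambda W a is solved with W the pooled within-group
    covariance (divisor n-g) and B the weighted between-group covariance
    (divisor g-1). min(g-1, rank) axes are kept, scaled so a'Wa = 1.
    """
    from scipy.linalg import eigh

    X = _as_matrix(data)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    g = len(levels)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    counts = {lev: int((labels == lev).sum()) for lev in levels}
    singles = [lev for lev, c in counts.items() if c < 2]
    if singles:
        raise ValueError(f"groups of size 1 not allowed: {singles}")

    Xp, basis = _project_full_rank(X, rel_tol)
    n, p = Xp.shape
    if n - g < 1:
        raise ValueError("need n - g >= 1 for a within-group covariance")
    W = _pooled_within(Xp, labels, levels)

    grand = Xp.mean(axis=0)
    Bmat = np.zeros((p, p))
    for lev in levels:
        sel = labels == lev
        d = Xp[sel].mean(axis=0) - grand
        Bmat += sel.sum() * np.outer(d, d)
    Bmat /= (g - 1)

    # guard: W may be singular in the projected space
    w_eig = np.linalg.eigvalsh(W)
    if w_eig[0] <= rel_tol * w_eig[-1]:
        warnings.warn("singular pooled within-group covariance; reducing rank", stacklevel=2)
        wvals, wvecs = np.linalg.eigh(W)
        keep = wvals > rel_tol * wvals[-1]
        R = wvecs[:, keep]
        Xp = Xp @ R
        basis = R.T @ basis
        p = Xp.shape[1]
        W = _pooled_within(Xp, labels, levels)
        grand = Xp.mean(axis=0)
        Bmat = np.zeros((p, p))
        for lev in levels:
            sel = labels == lev
            d = Xp[sel].mean(axis=0) - grand
            Bmat += sel.sum() * np.outer(d, d)
        Bmat /= (g - 1)

    eigvals, eigvecs = eigh(Bmat, W)  # eigh normalizes a'Wa = 1
    order = np.argsort(eigvals)[::-1]
    n_cv = min(g - 1, p)
    eigvals = np.clip(eigvals[order][:n_cv], 0.0, None)
    A = eigvecs[:, order][:, :n_cv]  # columns: CV axes in projected space

    scores = (Xp - grand) @ A
    total = eigvals.sum()
    pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    cv_axes = (basis.T @ A).T  # rows: axes in the original data space
    return CvaResult(
        cv_axes=cv_axes,
        cv_eigenvalues=eigvals,
        percent_between_variance=pct,
        scores=scores,
        group_names=levels,
    )


# ---------------------------------------------------------------------------
# Group distances and permutation tests
# ---------------------------------------------------------------------------

def _mahalanobis_pairwise(Xp: np.ndarray, labels: np.ndarray, levels) -> np.ndarray:
    W = _pooled_within(Xp, labels, levels)
    Winv = np.linalg.pinv(W)
    g = len(levels)
    means = np.stack([Xp[labels == lev].mean(axis=0) for lev in levels])
    D = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = means[i] - means[j]
            D[i, j] = D[j, i] = np.sqrt(max(0.0, float(d @ Winv @ d)))
    return D


def group_distance_tests(
    data,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Pairwise Mahalanobis and Procrustes distances between group means,
    with pairwise label-permutation tests.

    Mahalanobis distances use the pooled within-group covariance in the
    full-rank projected space; Procrustes distances are Euclidean norms of
    group-mean differences in the original space. For each pair, the two
    groups' members are randomly reassigned (group sizes preserved) n_perm
    times; P = (#{permuted >= observed} + 1)/n_perm, clamped to 1.
    Returns (mahalanobis, procrustes_dist, p_mahalanobis, p_procrustes,
    group_names).
    """
    X = _as_matrix(data)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xp, _ = _project_full_rank(X)
    # Mahalanobis needs an invertible pooled W (n - g degrees of freedom):
    # cap the dimensionality at n - g - 1, keeping the leading principal
    # directions of the data. The cap is label-independent, so observed and
    # permuted statistics are computed in the same space.
    max_dim = X.shape[0] - g - 1
    if Xp.shape[1] > max_dim:
        warnings.warn(
            f"data rank {Xp.shape[1]} exceeds within-group degrees of "
            f"freedom; Mahalanobis distances computed in the leading "
            f"{max_dim} principal dimensions",
            stacklevel=2,
        )
        Xp = Xp[:, :max_dim]

    D_maha = _mahalanobis_pairwise(Xp, labels, levels)
    means = {lev: X[labels == lev].mean(axis=0) for lev in levels}
    D_proc = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            D_proc[i, j] = D_proc[j, i] = float(
                np.linalg.norm(means[levels[i]] - means[levels[j]])
            )

    rng = np.random.default_rng(seed)
    P_maha = np.zeros((g, g))
    P_proc = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            sel = (labels == levels[i]) | (labels == levels[j])
            idx = np.flatnonzero(sel)
            n_i = int((labels[idx] == levels[i]).sum())
            count_m = 0
            count_p = 0
            labels_perm = labels.copy()
            for _ in range(n_perm - 1):
                perm = rng.permutation(idx.size)
                labels_perm[idx[perm[:n_i]]] = levels[i]
                labels_perm[idx[perm[n_i:]]] = levels[j]
                # same statistic as observed: pooled W over ALL groups
                Wp = _pooled_within(Xp, labels_perm, levels)
                m_i = Xp[labels_perm == levels[i]].mean(axis=0)
                m_j = Xp[labels_perm == levels[j]].mean(axis=0)
                d = m_i - m_j
                dm = np.sqrt(max(0.0, float(d @ np.linalg.pinv(Wp) @ d)))
                dp = float(
                    np.linalg.norm(
                        X[labels_perm == levels[i]].mean(axis=0)
                        - X[labels_perm == levels[j]].mean(axis=0)
                    )
                )
                if dm >= D_maha[i, j]:
                    count_m += 1
                if dp >= D_proc[i, j]:
                    count_p += 1
            labels_perm[idx] = labels[idx]
            P_maha[i, j] = P_maha[j, i] = min(1.0, (count_m + 1) / n_perm)
            P_proc[i, j] = P_proc[j, i] = min(1.0, (count_p + 1) / n_perm)
    return D_maha, D_proc, P_maha, P_proc, levels
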