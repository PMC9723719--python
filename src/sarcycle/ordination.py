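"""Constrained and unconstrained ordination of community dissimilarities.

PCoA embeds a Bray-Curtis matrix in Euclidean space (Gower double-centering,
negative eigenvalues discarded). CAP / db-RDA then regresses the principal
coordinates on standardized environmental variables: the inertia of the
fitted values is the variance the environment explains, with a
permutation-adjusted R^2. PERMANOVA partitions the squared dissimilarities
by a grouping factor and assesses the pseudo-F by label permutation.
Hierarchical clustering (UPGMA by default) recovers the warm/cold two-state
structure of the community, with clusters annotated by the warm-window
(2 May - 21 September) share of their sample dates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage, to_tree

from .community import EnvMatrix
from .dissimilarity import DistanceMatrix
from .seasonality import WARM_WINDOW

logger = logging.getLogger("sarcycle")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10):
    """Principal coordinates of a dissimilarity matrix.

    Gower double-centering of -d^2/2 followed by eigendecomposition; axes
    are ordered by decreasing eigenvalue and scaled to principal
    coordinates. Axes with eigenvalues <= eig_tol * max_eig are discarded
    (negative eigenvalues are reported in the log).

    Returns (coordinates DataFrame indexed by sample id, eigenvalues array).
    """
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=0)
    b = a - row[None, :] - row[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_neg = int((eigval < -eig_tol * max(eigval.max(), 1e-300)).sum())
    if n_neg:
        logger.info("pcoa: discarding %d negative eigenvalues (min %.3g)",
                    n_neg, eigval.min())
    keep = eigval > eig_tol * max(eigval.max(), 1e-300)
    eigval_pos = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval_pos)[None, :]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dm.ids, columns=cols), eigval_pos


# ---------------------------------------------------------------------------
# CAP / db-RDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    eigenvalues_constrained: np.ndarray
    eigenvalues_residual: np.ndarray
    site_scores: pd.DataFrame          # samples x constrained axes
    biplot_scores: pd.DataFrame        # env variables x constrained axes
    constrained_proportion: float
    adjusted_R2: float
    dropped_variables: list[str] = field(default_factory=list)

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues_constrained.sum()
                     + self.eigenvalues_residual.sum())


def _standardize_env(env: EnvMatrix, ids) -> pd.DataFrame:
    vals = env.values.loc[list(ids)]
    if vals.isna().to_numpy().any():
        raise ValueError("env matrix has missing values; impute upstream")
    std = vals.std(axis=0, ddof=1)
    degenerate = std[std == 0].index.tolist()
    if degenerate:
        warnings.warn(f"dropping constant env variables: {degenerate}",
                      stacklevel=3)
        vals = vals.drop(columns=degenerate)
        std = std.drop(degenerate)
    return (vals - vals.mean(axis=0)) / std


def _drop_collinear(X: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Greedy removal of env columns in the span of the preceding ones."""
    keep: list[str] = []
    basis = np.empty((len(X), 0))
    for col in X.columns:
        v = X[col].to_numpy()[:, None]
        resid = v - basis @ np.linalg.lstsq(basis, v, rcond=None)[0] \
            if basis.shape[1] else v
        if np.linalg.norm(resid) > tol * max(np.linalg.norm(v), 1.0):
            keep.append(col)
            q, _ = np.linalg.qr(np.hstack([basis, v]))
            basis = q
        else:
            warnings.warn(f"dropping collinear env variable {col!r}",
                          stacklevel=3)
    cond = np.linalg.cond(X[keep].to_numpy()) if keep else np.nan
    logger.info("cap: env design condition number %.3g", cond)
    return X[keep]


def cap(dm: DistanceMatrix, env: EnvMatrix, n_perm: int = 999,
        seed: int = 0) -> OrdinationResult:
    """Distance-based RDA of a dissimilarity matrix on environment.

    Principal coordinates (non-negative eigenvalues) are regressed on the
    column-standardized environmental design; the fitted values' inertia is
    the constrained inertia. ``adjusted_R2`` subtracts the mean R^2 of
    ``n_perm`` row-permuted designs and rescales, which remains defined for
    non-Euclidean dissimilarities.
    """
    coords, eigvals = pcoa(dm)
    y = coords.to_numpy()                       # already centered by Gower
    X = _drop_collinear(_standardize_env(env, dm.ids))
    dropped = [c for c in env.variables if c not in X.columns]
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than environmental variables")
    q, _ = np.linalg.qr(X.to_numpy())
    fitted = q @ (q.T @ y)
    total_inertia = float(eigvals.sum())

    # PCA of the fitted values gives the constrained axes.
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    lam_c = s ** 2
    keep = lam_c > 1e-10 * max(lam_c.max(), 1e-300)
    lam_c = lam_c[keep]
    site = u[:, keep] * s[keep]
    cols = [f"CAP{i + 1}" for i in range(site.shape[1])]
    site_scores = pd.DataFrame(site, index=dm.ids, columns=cols)

    resid = y - fitted
    lam_r = np.linalg.svd(resid, compute_uv=False) ** 2
    lam_r = lam_r[lam_r > 1e-10 * max(total_inertia, 1e-300)]

    r2 = float(lam_c.sum() / total_inertia)

    rng = np.random.default_rng(seed)
    y_norm2 = (y ** 2).sum()
    perm_r2 = np.empty(n_perm)
    Xa = X.to_numpy()
    for b in range(n_perm):
        qp, _ = np.linalg.qr(Xa[rng.permutation(n)])
        perm_r2[b] = ((qp.T @ y) ** 2).sum() / y_norm2
    mean_perm = perm_r2.mean()
    adj_r2 = float((r2 - mean_perm) / (1.0 - mean_perm))

    with np.errstate(invalid="ignore"):
        bip = np.array([
            [np.corrcoef(X[c], site_scores[a])[0, 1] for a in cols]
            for c in X.columns
        ])
    biplot = pd.DataFrame(np.nan_to_num(bip), index=X.columns, columns=cols)

    return OrdinationResult(
        eigenvalues_constrained=lam_c,
        eigenvalues_residual=lam_r,
        site_scores=site_scores,
        biplot_scores=biplot,
        constrained_proportion=r2,
        adjusted_R2=adj_r2,
        dropped_variables=dropped,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (ADONIS) with seeded label permutations.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), so the smallest
    attainable p with 999 permutations is 0.001.
    """
    groups = pd.Series(groups)
    if not groups.index.equals(pd.Index(dm.ids)):
        groups = groups.reindex(dm.ids)
    codes, uniques = pd.factorize(groups)
    k = len(uniques)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [uniques[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = dm.data ** 2
    f_obs, r2 = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_b, _ = _pseudo_f(d2, rng.permutation(codes), k)
        if f_b >= f_obs:
            count += 1
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2),
        p_value=(1 + count) / (1 + n_perm), n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    labels: pd.Series           # sample_id -> warm | cold (k=2) or cluster tag
    linkage_method: str
    newick: str
    cluster_of: pd.Series       # sample_id -> integer cluster


def _to_newick(node, ids) -> str:
    if node.is_leaf():
        return ids[node.id]
    left = _to_newick(node.get_left(), ids)
    right = _to_newick(node.get_right(), ids)
    bl = node.dist / 2.0
    return f"({left}:{bl:.6g},{right}:{bl:.6g})"


def hierarchical_clusters(dm: DistanceMatrix, dates: pd.Series, k: int = 2,
                          linkage: str = "average") -> ClusterAssignment:
    """Agglomerative clustering cut at k, annotated warm/cold by date.

    Samples are processed in sample-id order so merge-height ties resolve
    identically regardless of input ordering. For k = 2 the cluster whose
    samples fall more often inside the warm window is labeled "warm" and the
    other "cold"; for k > 2 each cluster gets the majority label.
    """
    if len(dm) < k:
        raise ValueError("fewer samples than requested clusters")
    order = np.argsort(np.asarray(dm.ids, dtype=object), kind="stable")
    ids = [dm.ids[i] for i in order]
    sub = dm.data[np.ix_(order, order)]
    condensed = sub[np.triu_indices(len(ids), 1)]
    Z = scipy_linkage(condensed, method=linkage)
    clusters = fcluster(Z, t=k, criterion="maxclust")
    cluster_of = pd.Series(clusters, index=ids)

    doy = pd.to_datetime(dates.loc[ids]).dt.dayofyear - 1
    in_warm = (doy >= WARM_WINDOW[0]) & (doy <= WARM_WINDOW[1])
    warm_frac = in_warm.groupby(cluster_of).mean()

    if k == 2:
        warm_cluster = warm_frac.idxmax()
        labels = cluster_of.map(
            lambda c: "warm" if c == warm_cluster else "cold")
    else:
        labels = cluster_of.map(
            lambda c: "warm" if warm_frac[c] >= 0.5 else "cold")

    tree = to_tree(Z)
    newick = _to_newick(tree, ids) + ";"
    return ClusterAssignment(labels=labels, linkage_method=linkage,
                             newick=newick, cluster_of=cluster_of)


def plot_cap(result: OrdinationResult, groups: pd.Series, path) -> None:
    """CAP scatter on the first two constrained axes with env arrows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xy = result.site_scores.iloc[:, :2]
    for g, sub in xy.groupby(groups.reindex(xy.index)):
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=14, label=str(g))
    scale = 0.8 * np.abs(xy.to_numpy()).max()
    for var, row in result.biplot_scores.iterrows():
        ax.annotate("", xy=(row.iloc[0] * scale, row.iloc[1] * scale),
                    xytext=(0, 0), arrowprops=dict(arrowstyle="->", lw=0.8))
        ax.text(row.iloc[0] * scale * 1.05, row.iloc[1] * scale * 1.05, var,
                fontsize=7)
    tot = result.total_inertia
    lc = result.eigenvalues_constrained
    ax.set_xlabel(f"CAP1 ({lc[0] / tot:.1%})")
    if len(lc) > 1:
        ax.set_ylabel(f"CAP2 ({lc[1] / tot:.1%})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
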