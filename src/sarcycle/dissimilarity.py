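"""Bray-Curtis / Euclidean distances and lag-averaged time-decay curves.

A seasonal community revisits similar compositions every year, so the mean
Bray-Curtis dissimilarity between pairs of samples, viewed as a function of
the calendar-day lag separating them, oscillates with a one-year wavelength:
turnover is maximal at about half a period. The curve is summarised by an
exactly periodic cubic B-spline fit (df = 4, period = 366 days) and the lag
of its first interior maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.spatial.distance import pdist, squareform

from .community import EnvMatrix, RelAbundanceMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("negative dissimilarities")
        np.fill_diagonal(self.data, 0.0)
        self.data = np.clip(self.data, 0.0, None)

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles have different lengths")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(np.abs(x - y).sum() / denom)


def pairwise_distance(mat: RelAbundanceMatrix | EnvMatrix | pd.DataFrame,
                      metric: str = "bray_curtis") -> DistanceMatrix:
    """All pairwise distances between sample rows.

    ``metric`` is ``bray_curtis`` (community profiles) or ``euclidean``
    (standardized environmental variables). Missing values are rejected:
    impute upstream.
    """
    if isinstance(mat, RelAbundanceMatrix):
        df = mat.values
    elif isinstance(mat, EnvMatrix):
        df = mat.values
    else:
        df = mat
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError(f"missing values not allowed under {metric}")
    if metric == "bray_curtis":
        d = pdist(arr, metric="braycurtis")
    elif metric == "euclidean":
        d = pdist(arr, metric="euclidean")
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return DistanceMatrix(list(df.index), squareform(d))


# ---------------------------------------------------------------------------
# Time-decay curves
# ---------------------------------------------------------------------------

@dataclass
class LagDecayCurve:
    """Mean dissimilarity per calendar-day lag, with optional spline fit."""

    lags: np.ndarray            # strictly increasing whole-day lags
    mean_dissimilarity: np.ndarray
    n_pairs: np.ndarray
    fitted: np.ndarray | None = None
    coefficients: np.ndarray | None = None   # [intercept, basis...]
    df: int | None = None
    period: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "lag": self.lags,
            "mean_bc": self.mean_dissimilarity,
            "n_pairs": self.n_pairs,
        })
        if self.fitted is not None:
            out["fitted"] = self.fitted
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def time_decay(dm: DistanceMatrix, dates: pd.Series) -> LagDecayCurve:
    """Average pairwise dissimilarities over identical whole-day lags.

    Every unordered sample pair contributes once at lag |date_i - date_j|;
    same-day pairs (lag 0) are retained.
    """
    if len(dm) < 2:
        raise ValueError("time_decay requires at least 2 samples")
    dates = pd.to_datetime(dates.loc[dm.ids])
    days = dates.to_numpy().astype("datetime64[D]").astype(np.int64)
    i, j = np.triu_indices(len(dm), k=1)
    lag = np.abs(days[i] - days[j])
    dist = dm.data[i, j]
    grouped = pd.DataFrame({"lag": lag, "d": dist}).groupby("lag")["d"]
    mean = grouped.mean()
    n = grouped.size()
    return LagDecayCurve(
        lags=mean.index.to_numpy(),
        mean_dissimilarity=mean.to_numpy(),
        n_pairs=n.to_numpy(),
    )


def periodic_bspline_basis(x, df: int = 4, period: float = 366.0,
                           degree: int = 3) -> np.ndarray:
    """Design matrix of ``df`` exactly periodic cubic B-spline basis functions.

    Uniform knots with spacing period/df; the basis is made circular by
    folding the wrapped columns of the open design matrix, so each basis
    function B satisfies B(t) = B(t + period) to machine precision.
    """
    if df < degree:
        raise ValueError(f"df must be >= degree ({degree})")
    x = np.asarray(x, dtype=float)
    h = period / df
    knots = np.arange(-degree, df + degree + 1) * h
    xm = np.mod(x, period)
    D = BSpline.design_matrix(xm, knots, degree).toarray()
    for j in range(degree):
        D[:, j] += D[:, j + df]
    return D[:, :df]


def fit_periodic_spline(curve: LagDecayCurve, df: int = 4,
                        period: float = 366.0) -> LagDecayCurve:
    """Least-squares periodic spline fit of the mean dissimilarities.

    Returns a new curve carrying fitted values and coefficients
    (intercept first). The basis functions form a partition of unity, so
    the intercept column is absorbed by a minimum-norm least-squares solve.
    """
    lags = np.asarray(curve.lags, dtype=float)
    if len(np.unique(lags)) < df + 1:
        raise ValueError(f"need at least {df + 1} distinct lags to fit df={df}")
    X = np.column_stack([np.ones_like(lags),
                         periodic_bspline_basis(lags, df=df, period=period)])
    beta, *_ = np.linalg.lstsq(X, curve.mean_dissimilarity, rcond=None)
    fitted = X @ beta
    return LagDecayCurve(
        lags=curve.lags,
        mean_dissimilarity=curve.mean_dissimilarity,
        n_pairs=curve.n_pairs,
        fitted=fitted,
        coefficients=beta,
        df=df,
        period=period,
    )


def evaluate_spline(curve: LagDecayCurve, at) -> np.ndarray:
    """Evaluate a fitted curve's spline at arbitrary lags."""
    if curve.coefficients is None:
        raise ValueError("curve has no fitted spline")
    at = np.asarray(at, dtype=float)
    X = np.column_stack([np.ones_like(at),
                         periodic_bspline_basis(at, df=curve.df,
                                                period=curve.period)])
    return X @ curve.coefficients


def first_peak_lag(curve: LagDecayCurve) -> int | None:
    """Smallest positive lag at which the fitted spline has a local maximum.

    Evaluated on a 1-day grid over one period. Returns None when the fitted
    curve has no interior peak (monotone or flat over the period).
    """
    if curve.coefficients is None:
        raise ValueError("fit the spline before locating its peak")
    period = int(round(curve.period))
    grid = np.arange(0, period + 1)
    f = evaluate_spline(curve, grid)
    if np.ptp(f) < 1e-12:
        return None
    for t in range(1, period):
        if f[t] > f[t - 1] and f[t] >= f[t + 1]:
            return t
    return None


def plot_time_decay(curve: LagDecayCurve, path: str | Path) -> None:
    """Scatter of lag-averaged dissimilarities with the periodic spline fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(curve.lags, curve.mean_dissimilarity, s=8, alpha=0.5,
               color="grey", label="lag mean")
    if curve.coefficients is not None:
        grid = np.linspace(0, curve.lags.max(), 500)
        ax.plot(grid, evaluate_spline(curve, grid), color="tab:blue",
                label=f"periodic spline (df={curve.df})")
    ax.set_xlabel("time distance (days)")
    ax.set_ylabel("mean Bray-Curtis dissimilarity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
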