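"""Short-term coupling between community turnover and the environment.

Weekly community and environment series are aligned to a fixed Monday grid
(nearest-Monday snapping, linear interpolation of gaps). Week-to-week change
is summarised by consecutive-sample distances: Bray-Curtis between
successive community compositions and Euclidean between successive
min-max-standardized environmental states. Wavelet coherence between the
two change series then localises, in time and period, when the community
tracks the environment: cells that are both significant (against
white-noise surrogates) and in phase (|phase difference| < pi/4) mark
coupling, and contiguous runs of high coupling score are reported as
coupled/uncoupled intervals. Environmental variables are finally compared
between the two phases with Mann-Whitney U tests.

The continuous wavelet transform uses the analytic Morlet mother
psi(eta) = pi^(-1/4) exp(i w0 eta) exp(-eta^2 / 2) with w0 = 6, evaluated
in the Fourier domain; smoothing for coherence follows the standard
scheme of a scale-proportional Gaussian in time and a 0.6-octave boxcar
across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .community import EnvMatrix
from .dissimilarity import bray_curtis
from .seasonality import adjust_pvalues

#: Fourier period of a Morlet wavelet per unit scale, omega0 = 6.
def _fourier_factor(omega0: float) -> float:
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0 ** 2))


# ---------------------------------------------------------------------------
# Weekly grid
# ---------------------------------------------------------------------------

def minmax_standardize(x) -> np.ndarray:
    """X' = (x - min x) / (max x - min x); min -> 0, max -> 1."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if not hi > lo:
        raise ValueError("degenerate variable: max(x) == min(x)")
    return (x - lo) / (hi - lo)


def snap_to_monday(dates: pd.Series):
    """Reassign each date to its nearest Monday (never moved > 3 days).

    Offsets of 0-3 days from the preceding Monday snap backwards, 4-6
    forwards. When two samples land on the same Monday the one whose
    original date is nearer is kept (earlier date on ties); collisions are
    returned in the report.

    Returns (snapped dates Series, report DataFrame of dropped samples).
    """
    dates = pd.to_datetime(dates)
    wd = dates.dt.weekday
    shift = wd.where(wd <= 3, wd - 7)           # days back to nearest Monday
    snapped = dates - pd.to_timedelta(shift, unit="D")
    dist = shift.abs()
    keep: dict[pd.Timestamp, str] = {}
    dropped = []
    for sid in dates.index:
        m = snapped.loc[sid]
        if m not in keep:
            keep[m] = sid
        else:
            prev = keep[m]
            if dist.loc[sid] < dist.loc[prev]:
                dropped.append((prev, dates.loc[prev], m))
                keep[m] = sid
            else:
                dropped.append((sid, dates.loc[sid], m))
    kept_ids = list(keep.values())
    report = pd.DataFrame(dropped, columns=["sample_id", "date", "monday"])
    return snapped.loc[kept_ids], report


@dataclass
class WeeklySeries:
    """Values on a strictly consecutive 7-day Monday grid, gaps filled."""

    monday_dates: pd.DatetimeIndex
    values: pd.DataFrame            # weeks x columns (ASVs or variables)
    interpolated_mask: np.ndarray   # True where a week was filled

    def __post_init__(self) -> None:
        diffs = np.diff(self.monday_dates.to_numpy().astype("datetime64[D]")
                        .astype(np.int64))
        if len(diffs) and not (diffs == 7).all():
            raise ValueError("weekly grid spacing is not exactly 7 days")
        if self.values.isna().to_numpy().any():
            raise ValueError("weekly grid contains missing values")

    def __len__(self) -> int:
        return len(self.monday_dates)


def to_weekly_grid(dates: pd.Series, values: pd.DataFrame | pd.Series
                   ) -> WeeklySeries:
    """Interpolate snapped samples onto the full Monday grid they span."""
    dates = pd.to_datetime(dates)
    if len(dates) < 2:
        raise ValueError("need at least 2 dated samples")
    if isinstance(values, pd.Series):
        values = values.to_frame()
    values = values.loc[dates.index]
    order = dates.sort_values(kind="stable").index
    dates, values = dates.loc[order], values.loc[order]
    days = dates.dt.normalize()
    grid = pd.date_range(days.iloc[0], days.iloc[-1], freq="7D")
    t_obs = (days - days.iloc[0]).dt.days.to_numpy(dtype=float)
    t_grid = (grid - grid[0]).days.to_numpy(dtype=float)
    out = np.column_stack([
        np.interp(t_grid, t_obs, values[c].to_numpy(dtype=float))
        for c in values.columns
    ])
    mask = ~np.isin(t_grid, t_obs)
    return WeeklySeries(grid, pd.DataFrame(out, index=grid,
                                           columns=values.columns), mask)


def consecutive_distances(ws: WeeklySeries, metric: str = "euclidean"
                          ) -> pd.Series:
    """Distance between each pair of successive weekly samples.

    ``bray_curtis`` for community composition rows, ``euclidean`` for
    standardized environmental rows; length = grid length - 1, indexed by
    the earlier Monday of each pair.
    """
    arr = ws.values.to_numpy(dtype=float)
    if metric == "euclidean":
        d = np.sqrt(((arr[1:] - arr[:-1]) ** 2).sum(axis=1))
    elif metric == "bray_curtis":
        d = np.array([bray_curtis(arr[i], arr[i + 1])
                      for i in range(len(arr) - 1)])
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return pd.Series(d, index=ws.monday_dates[:-1])


# ---------------------------------------------------------------------------
# Morlet CWT and wavelet coherence
# ---------------------------------------------------------------------------

def dyadic_scales(n: int, dt: float = 1.0, dj: float = 1 / 20,
                  min_period: float = 2.0,
                  omega0: float = 6.0) -> np.ndarray:
    """Dyadic scale grid whose Fourier periods span [min_period, n*dt/2]."""
    ff = _fourier_factor(omega0)
    s0 = min_period * dt / ff
    smax = n * dt / 2.0 / ff
    j = np.arange(0, np.floor(np.log2(smax / s0) / dj) + 1)
    return s0 * 2.0 ** (j * dj)


def morlet_cwt(y, scales, dt: float = 1.0, omega0: float = 6.0) -> np.ndarray:
    """Continuous wavelet transform, FFT implementation.

    Returns complex coefficients of shape (n_scales, n_times). The series
    is mean-centered internally; requires at least 8 points.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("series shorter than 8 points")
    y = y - y.mean()
    npad = int(2 ** np.ceil(np.log2(n)))
    yhat = np.fft.fft(y, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    out = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi ** -0.25
    for i, s in enumerate(np.asarray(scales, dtype=float)):
        psi_hat = (norm_const * np.sqrt(2.0 * np.pi * s / dt)
                   * np.exp(-0.5 * (s * omega - omega0) ** 2)
                   * (omega > 0))
        out[i] = np.fft.ifft(yhat * psi_hat)[:n]
    return out


def _smooth(field_: np.ndarray, scales: np.ndarray, dt: float,
            dj: float) -> np.ndarray:
    """Torrence-Webster smoothing: Gaussian in time, 0.6-octave boxcar in scale."""
    ns, nt = field_.shape
    npad = int(2 ** np.ceil(np.log2(nt)))
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=1.0)
    smoothed = np.empty_like(field_)
    for i, s in enumerate(scales):
        # FT of a Gaussian window with sd = 2 scale: wide smoothing favours
        # sustained coherence and gives the null more degrees of freedom
        gauss_hat = np.exp(-0.5 * ((2.0 * s / dt) * omega) ** 2)
        smoothed[i] = np.fft.ifft(np.fft.fft(field_[i], npad)
                                  * gauss_hat)[:nt].real \
            if not np.iscomplexobj(field_) else \
            np.fft.ifft(np.fft.fft(field_[i], npad) * gauss_hat)[:nt]
    width = max(int(round(0.6 / dj)), 1)
    kernel = np.ones(width) / width
    out = np.empty_like(smoothed)
    for t in range(nt):
        col = smoothed[:, t]
        out[:, t] = np.convolve(
            np.pad(col, (width // 2, width - 1 - width // 2), mode="edge"),
            kernel, mode="valid")
    return out


@dataclass
class CoherenceMap:
    """Time x period grids of squared coherence, phase and significance."""

    periods: np.ndarray             # Fourier periods, weeks
    times: pd.DatetimeIndex | np.ndarray
    coherence: np.ndarray           # (n_periods, n_times) in [0, 1]
    phase_difference: np.ndarray    # (-pi, pi]
    significant: np.ndarray         # boolean mask, same shape
    coi_period: np.ndarray          # per time: largest reliable period
    alpha: float = 0.05
    in_coi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # in_coi marks reliable cells: period shorter than the COI boundary
        self.in_coi = self.periods[:, None] <= self.coi_period[None, :]

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path, periods=self.periods,
            times=np.asarray(self.times).astype("datetime64[D]").astype(str)
            if isinstance(self.times, pd.DatetimeIndex) else self.times,
            coherence=self.coherence, phase=self.phase_difference,
            significant=self.significant, coi_period=self.coi_period,
            alpha=self.alpha)


def _coherence_fields(x, y, scales, dt, dj, omega0):
    wx = morlet_cwt(x, scales, dt=dt, omega0=omega0)
    wy = morlet_cwt(y, scales, dt=dt, omega0=omega0)
    inv_s = 1.0 / scales[:, None]
    sxx = _smooth((np.abs(wx) ** 2) * inv_s, scales, dt, dj).real
    syy = _smooth((np.abs(wy) ** 2) * inv_s, scales, dt, dj).real
    sxy = _smooth(wx * np.conj(wy) * inv_s, scales, dt, dj)
    denom = np.clip(sxx * syy, 1e-300, None)
    coh = np.clip(np.abs(sxy) ** 2 / denom, 0.0, 1.0)
    phase = np.angle(sxy)
    return coh, phase


def wavelet_coherence(x, y, dt: float = 1.0, dj: float = 1 / 20,
                      omega0: float = 6.0, n_sim: int = 100,
                      alpha: float = 0.05, seed: int = 0,
                      times=None) -> CoherenceMap:
    """Squared wavelet coherence with Monte-Carlo white-noise significance.

    ``x`` and ``y`` share one grid (e.g. weekly consecutive-distance
    series). Significance is the cell-wise 1 - alpha quantile of coherence
    over ``n_sim`` independent white-noise surrogate pairs of the same
    length; the cone of influence (sqrt(2) * scale from each edge) is
    reported per time point as the largest reliable period.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share one grid")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) input series")
    n = len(x)
    scales = dyadic_scales(n, dt=dt, dj=dj, omega0=omega0)
    ff = _fourier_factor(omega0)
    periods = ff * scales

    coh, phase = _coherence_fields(x, y, scales, dt, dj, omega0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_sim,) + coh.shape, dtype=np.float32)
    for b in range(n_sim):
        cb, _ = _coherence_fields(rng.standard_normal(n),
                                  rng.standard_normal(n),
                                  scales, dt, dj, omega0)
        null[b] = cb
    threshold = np.quantile(null, 1.0 - alpha, axis=0)
    significant = coh > threshold

    edge = np.minimum(np.arange(n), n - 1 - np.arange(n)) * dt
    coi_period = ff * edge / np.sqrt(2.0)

    if times is None:
        times = np.arange(n)
    return CoherenceMap(periods=periods, times=times, coherence=coh,
                        phase_difference=phase, significant=significant,
                        coi_period=coi_period, alpha=alpha)


# ---------------------------------------------------------------------------
# Phase segmentation and comparison
# ---------------------------------------------------------------------------

def coupling_score(cm: CoherenceMap, phase_tol: float = np.pi / 4
                   ) -> np.ndarray:
    """Per time point: fraction of reliable scales significant AND in phase."""
    good = cm.significant & (np.abs(cm.phase_difference) < phase_tol)
    n_valid = cm.in_coi.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (good & cm.in_coi).sum(axis=0) / n_valid
    return np.where(n_valid > 0, score, 0.0)


def segment_phases(cm: CoherenceMap, window: int = 12,
                   threshold: float = 0.2,
                   phase_tol: float = np.pi / 4) -> pd.DataFrame:
    """Label contiguous coupled/uncoupled intervals.

    The per-week coupling score is averaged over a centered rolling window
    (``window`` weeks); weeks at or above ``threshold`` are coupled.
    Returns a DataFrame with columns start, end, label, n_weeks, plus the
    per-week boolean in attribute ``coupled`` (stored in ``.attrs``).
    """
    n = cm.coherence.shape[1]
    if window > n:
        raise ValueError("window longer than the series")
    score = coupling_score(cm, phase_tol=phase_tol)
    rolled = (pd.Series(score)
              .rolling(window, center=True, min_periods=max(window // 2, 1))
              .mean().to_numpy())
    coupled = rolled >= threshold
    times = np.asarray(cm.times)
    intervals = []
    start = 0
    for i in range(1, n + 1):
        if i == n or coupled[i] != coupled[start]:
            intervals.append({
                "start": times[start], "end": times[i - 1],
                "label": "coupled" if coupled[start] else "uncoupled",
                "n_weeks": i - start,
            })
            start = i
    out = pd.DataFrame(intervals)
    out.attrs["coupled"] = pd.Series(coupled, index=pd.Index(times))
    out.attrs["score"] = pd.Series(rolled, index=pd.Index(times))
    return out


def compare_phases(env_weekly: WeeklySeries | pd.DataFrame,
                   coupled: pd.Series) -> pd.DataFrame:
    """Mann-Whitney U of each variable between coupled and uncoupled weeks.

    ``coupled`` is the per-week boolean from segment_phases. Returns per
    variable U, two-sided p, and BH q.
    """
    values = env_weekly.values if isinstance(env_weekly, WeeklySeries) \
        else env_weekly
    idx = values.index.intersection(coupled.index)
    values = values.loc[idx]
    mask = coupled.loc[idx].to_numpy(dtype=bool)
    if mask.all() or (~mask).all():
        raise ValueError("both phases must be represented")
    rows = []
    for var in values.columns:
        a = values.loc[mask, var].dropna()
        b = values.loc[~mask, var].dropna()
        u, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"variable": var, "U": float(u), "p_value": float(p),
                     "n_coupled": len(a), "n_uncoupled": len(b)})
    out = pd.DataFrame(rows).set_index("variable")
    out["q_value"] = adjust_pvalues(out["p_value"].to_numpy(), method="BH")
    return out


def standardize_env_weekly(env: EnvMatrix) -> WeeklySeries:
    """Snap env samples to Mondays, interpolate, then min-max standardize.

    Constant variables are dropped with a warning rather than aborting the
    pipeline.
    """
    import warnings as _warnings

    snapped, _ = snap_to_monday(env.dates)
    ws = to_weekly_grid(snapped, env.values.loc[snapped.index])
    cols = {}
    for var in ws.values.columns:
        try:
            cols[var] = minmax_standardize(ws.values[var].to_numpy())
        except ValueError:
            _warnings.warn(f"dropping degenerate env variable {var!r}",
                           stacklevel=2)
    std = pd.DataFrame(cols, index=ws.monday_dates)
    return WeeklySeries(ws.monday_dates, std, ws.interpolated_mask)


def plot_coupling(env_weekly: WeeklySeries, bc_series: pd.Series,
                  eu_series: pd.Series, path) -> None:
    """Two-panel figure: standardized env variables and the two change series."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    for i, var in enumerate(env_weekly.values.columns):
        ax1.plot(env_weekly.monday_dates,
                 env_weekly.values[var] + i, lw=0.6)
    ax1.set_ylabel("normalized variables (offset)")
    ax2.plot(eu_series.index, eu_series / eu_series.max(), color="tab:red",
             ls="--", lw=0.8, label="env Euclidean")
    ax2.plot(bc_series.index, bc_series / bc_series.max(), color="tab:blue",
             ls="--", lw=0.8, label="Bray-Curtis")
    ax2.set_ylabel("scaled consecutive distance")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
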