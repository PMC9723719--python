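"""Per-ASV periodicity screening and summer/winter phase classification.

Two-stage procedure. First, each ASV's relative-abundance series is screened
for a hidden periodic component with Fisher's exact G-test on the
periodogram (the test statistic is the largest ordinate's share of total
spectral power; its null distribution under Gaussian white noise is known in
closed form). Because the test assumes even sampling, irregular series are
linearly interpolated onto a regular weekly or monthly grid first. Second,
significant ASVs are fitted with a harmonic linear model

    y ~ b0 + bc * Xc + bs * Xs

where Xc = cos(2*pi*t) with t = d/365 and d the days since the most recent
winter solstice (Dec 21), and Xs = sin(2*pi*t) with d the days since
1 January. The fitted annual curve's peak day places the ASV in the warm
window (2 May - 21 September) -> "summer", otherwise "winter". An ASV is
called seasonal only when both the (BH-adjusted) G-test and the harmonic
model F-test pass the significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .community import RelAbundanceMatrix

#: Warm-cluster window, 0-based day of year: May 2 .. Sep 21 inclusive.
WARM_WINDOW = (121, 263)


@dataclass
class SeasonalityRecord:
    asv_id: str
    g_statistic: float
    p_value: float
    q_value: float
    beta0: float
    beta_c: float
    beta_s: float
    model_p: float
    peak_day: float | None      # 0-based day of year; None when nonseasonal
    seasonal_class: str         # summer | winter | nonseasonal


# ---------------------------------------------------------------------------
# Spectral screening
# ---------------------------------------------------------------------------

def periodogram(y) -> np.ndarray:
    """Periodogram ordinates I(f_k) = |DFT(y - mean)|^2 / N at k = 1..m.

    m = floor((N-1)/2): the zero and Nyquist frequencies are excluded.
    Requires N >= 6. A constant series yields all-zero ordinates.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError("periodogram requires at least 6 observations")
    m = (n - 1) // 2
    spec = np.fft.rfft(y - y.mean())
    return (np.abs(spec[1:m + 1]) ** 2) / n


def fisher_g_pvalue(g: float, m: int) -> float:
    """Exact null probability that the maximum ordinate share exceeds g.

    P = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(m,j) (1 - j g)^(m-1),
    clipped to [0, 1]; terms are accumulated on the log scale.
    """
    if g <= 0.0:
        return 1.0
    if g >= 1.0:
        return 0.0
    jmax = min(m, int(math.floor(1.0 / g)))
    total = 0.0
    for j in range(1, jmax + 1):
        base = 1.0 - j * g
        if base <= 0.0:
            continue
        log_term = (
            math.lgamma(m + 1) - math.lgamma(j + 1) - math.lgamma(m - j + 1)
            + (m - 1) * math.log(base)
        )
        term = math.exp(log_term)
        total += term if j % 2 == 1 else -term
    return float(min(max(total, 0.0), 1.0))


def fisher_g_test(y) -> tuple[float, float]:
    """Fisher's exact test for a single hidden periodicity.

    Returns (g, p) with g = max_k I(f_k) / sum_k I(f_k). An all-zero
    periodogram (constant series) returns (0, 1) by convention.
    """
    ords = periodogram(y)
    total = ords.sum()
    if total <= 0.0:
        return 0.0, 1.0
    g = float(ords.max() / total)
    return g, fisher_g_pvalue(g, len(ords))


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment across ASVs: none, BH, or bonferroni."""
    p = np.asarray(p, dtype=float)
    if method in (None, "none"):
        return p.copy()
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# Harmonic design and classification
# ---------------------------------------------------------------------------

def _days_since_solstice(dates: pd.Series) -> np.ndarray:
    dates = pd.to_datetime(dates)
    out = np.empty(len(dates), dtype=float)
    for i, d in enumerate(dates):
        sol = pd.Timestamp(year=d.year, month=12, day=21)
        if d < sol:
            sol = pd.Timestamp(year=d.year - 1, month=12, day=21)
        out[i] = (d - sol).days
    return out


def build_harmonic_design(dates: pd.Series) -> pd.DataFrame:
    """Annual cosine/sine predictors Xc (solstice-anchored) and Xs (Jan 1)."""
    dates = pd.to_datetime(dates)
    d_c = _days_since_solstice(dates)
    d_s = dates.dt.dayofyear.to_numpy(dtype=float) - 1.0
    return pd.DataFrame(
        {
            "Xc": np.cos(2 * np.pi * d_c / 365.0),
            "Xs": np.sin(2 * np.pi * d_s / 365.0),
        },
        index=dates.index,
    )


def harmonic_curve(beta_c: float, beta_s: float,
                   days=None) -> np.ndarray:
    """Fitted seasonal component over 0-based days of year 0..364."""
    if days is None:
        days = np.arange(365)
    days = np.asarray(days, dtype=float)
    xc = np.cos(2 * np.pi * ((days + 11.0) % 365.0) / 365.0)  # Dec 21 = day 354
    xs = np.sin(2 * np.pi * days / 365.0)
    return beta_c * xc + beta_s * xs


def interpolate_regular(dates: pd.Series, y, cadence: str = "weekly"
                        ) -> np.ndarray:
    """Resample an irregular series to an even grid by linear interpolation.

    Spacing is 7 days (weekly) or 30.4375 days (monthly); the grid spans the
    observed dates so no extrapolation occurs.
    """
    step = {"weekly": 7.0, "monthly": 30.4375}[cadence]
    dates = pd.to_datetime(dates)
    t = (dates - dates.min()).dt.days.to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, y = t[order], np.asarray(y, dtype=float)[order]
    grid = np.arange(0.0, t.max() + step / 2, step)
    return np.interp(grid, t, y)


def classify_seasonal(y, design: pd.DataFrame, alpha: float = 0.05,
                      asv_id: str = "", g: float | None = None,
                      p_value: float | None = None,
                      q_value: float | None = None) -> SeasonalityRecord:
    """Harmonic OLS fit and summer/winter call for one ASV series.

    ``y`` is aligned to ``design`` (one row per sample). The G-test
    statistics may be supplied from a prior screening pass (so that the
    q-value reflects the whole ASV family); when omitted they are computed
    from ``y`` directly, with q = p.
    """
    y = np.asarray(y, dtype=float)
    X = design[["Xc", "Xs"]].to_numpy()
    if np.ptp(X[:, 0]) < 1e-12 and np.ptp(X[:, 1]) < 1e-12:
        raise ValueError("degenerate harmonic design: all samples on one date")
    if g is None or p_value is None:
        g, p_value = fisher_g_test(y)
    if q_value is None:
        q_value = p_value
    if np.ptp(y) == 0:          # constant series: no seasonal signal
        beta0, beta_c, beta_s = float(y[0]), 0.0, 0.0
        model_p = 1.0
    else:
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        beta0, beta_c, beta_s = fit.params
        model_p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    significant = (q_value < alpha) and (model_p < alpha)
    if significant:
        curve = harmonic_curve(beta_c, beta_s)
        peak_day = float(np.argmax(curve))
        cls = ("summer" if WARM_WINDOW[0] <= peak_day <= WARM_WINDOW[1]
               else "winter")
    else:
        peak_day = None
        cls = "nonseasonal"
    return SeasonalityRecord(
        asv_id=asv_id, g_statistic=g, p_value=p_value, q_value=q_value,
        beta0=float(beta0), beta_c=float(beta_c), beta_s=float(beta_s),
        model_p=model_p, peak_day=peak_day, seasonal_class=cls,
    )


def screen_seasonality(ra: RelAbundanceMatrix, alpha: float = 0.05,
                       cadence: str = "weekly",
                       adjust: str = "BH") -> pd.DataFrame:
    """Full screening of every ASV in a relative-abundance table.

    Each ASV series is interpolated to an even grid for the G-test, p-values
    are adjusted across ASVs, and the harmonic model is fitted on the
    observed (uninterpolated) samples. Returns one row per ASV.
    """
    dates = pd.to_datetime(ra.dates)
    order = dates.sort_values(kind="stable").index
    values = ra.values.loc[order]
    dates = dates.loc[order]
    design = build_harmonic_design(dates)

    gs, ps = [], []
    for asv in values.columns:
        grid_y = interpolate_regular(dates, values[asv].to_numpy(), cadence)
        g, p = fisher_g_test(grid_y)
        gs.append(g)
        ps.append(p)
    qs = adjust_pvalues(ps, method=adjust)

    records = []
    for asv, g, p, q in zip(values.columns, gs, ps, qs):
        rec = classify_seasonal(values[asv].to_numpy(), design, alpha=alpha,
                                asv_id=asv, g=g, p_value=p, q_value=q)
        records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records]).set_index("asv_id")


def plot_annual_trends(records: pd.DataFrame, ra: RelAbundanceMatrix,
                       path, tiers=(0.005, 0.05)) -> None:
    """Fitted annual curves of seasonal ASVs, panelled by abundance tier."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean_ab = ra.values.mean(axis=0)
    lo, hi = tiers
    panels = [
        (f"> {hi:.1%} mean abundance", mean_ab.index[mean_ab > hi]),
        (f"{lo:.1%} - {hi:.1%}", mean_ab.index[(mean_ab >= lo) & (mean_ab <= hi)]),
        (f"< {lo:.1%}", mean_ab.index[mean_ab < lo]),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    days = np.arange(365)
    for ax, (title, asvs) in zip(axes, panels):
        for asv in asvs:
            if asv not in records.index:
                continue
            rec = records.loc[asv]
            if rec["seasonal_class"] == "nonseasonal":
                continue
            curve = rec["beta0"] + harmonic_curve(rec["beta_c"], rec["beta_s"], days)
            color = "tab:red" if rec["seasonal_class"] == "summer" else "tab:blue"
            ax.plot(days, curve, color=color, alpha=0.6, lw=1)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("day of year")
    axes[0].set_ylabel("fitted relative abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
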