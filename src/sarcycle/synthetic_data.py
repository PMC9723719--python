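"""Synthetic multiannual community + environment datasets.

Emulates the statistical structure of temperate marine amplicon time
series: a monthly (BATS-like) or weekly (WEC-like) sampling grid with
gaps, an annual temperature sinusoid with autocorrelated weekly anomalies,
winter-peaking nutrients, a spring chlorophyll bloom, stochastic wind and
river-flow series whose level scales with a per-year storminess factor,
and a SAR11-like community of two antagonistic seasonal ASV guilds
(summer- and winter-peaking) plus aperiodic ASVs.

Seasonal ASV i has log-affinity

    log a_i(t) = A * cos(2*pi*(doy_t - peak_i)/365) + r_i(t) + base_i

where r_i(t) is a mean-reverting weather displacement: each week the
seasonal taxa take a random step whose magnitude scales with the same-week
environmental change |du(t)| (u is the standardized temperature anomaly,
the part of the environment not explained by the annual cycle). Mixing
events of larger magnitude displace the community further, in an
unpredictable direction. ``coupling_strength`` blends this same-week
signal against an 8-week moving average of it: at 1 the expected
composition responds to the same-week environment state, at 0 it follows
the smoothed seasonal signal only, so week-scale community change is
decoupled from week-scale environmental change while the annual cycle is
preserved. Weekly anomaly innovations are amplitude-modulated with a
16-week period (alternating calm and stormy spells), giving the
environmental and (when coupled) community change series a common
oscillation band.

Aperiodic ASVs hold a fixed expected share of the community and the
seasonal guilds trade off within the remainder, so compositional closure
cannot induce a spurious annual signal in truly aperiodic taxa.

Counts are Dirichlet-multinomial: proportions drawn around the expected
composition with a concentration parameter (overdispersion typical of
amplicon data), library sizes lognormal. All randomness flows from the
config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CountMatrix, EnvMatrix, TaxonomyMap


@dataclass
class SimConfig:
    n_years: int = 7
    cadence: str = "weekly"                  # weekly | monthly
    missing_fraction: float = 0.1
    n_summer_asvs: int = 8
    n_winter_asvs: int = 8
    n_aperiodic_asvs: int = 14
    seasonal_amplitude: float = 1.5          # A in the affinity model
    dispersion: float = 200.0                # Dirichlet concentration
    library_size_log_mu: float = 9.9         # median ~ 2e4 reads
    library_size_log_sigma: float = 0.3
    coupling_strength: float | list = 1.0    # scalar or per-year
    storminess: float | list = 0.3           # scalar or per-year
    coupling_response: float = 0.6           # step size per unit |du|
    aperiodic_share: float = 0.4             # fixed expected aperiodic mass
    summer_peak_day: float = 197.0           # mid-July (0-based doy)
    winter_peak_day: float = 15.0            # mid-January
    peak_scatter_days: float = 10.0
    jitter_days: int = 2                     # sampling-date jitter, weekly only
    start_date: str = "2015-01-05"           # a Monday
    taxonomy_preset: str = "wec"             # wec | bats winter labels
    # Environment parameters (temperate coastal surface water)
    temp_mean: float = 13.4                  # degC; observed range ~7.6-19.2
    temp_amplitude: float = 5.0
    temp_trough_doy: float = 45.0            # mid-February minimum
    temp_anom_sd: float = 0.6                # degC, weekly AR(1) anomalies
    anom_ar1: float = 0.3
    anom_modulation: float = 0.8             # 16-week amplitude modulation depth
    anom_modulation_period: float = 16.0     # weeks
    seed: int = 0

    def coupling_by_year(self) -> np.ndarray:
        return _per_year(self.coupling_strength, self.n_years)

    def storminess_by_year(self) -> np.ndarray:
        return _per_year(self.storminess, self.n_years)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("coupling_strength", "storminess"):
            if isinstance(d[key], np.ndarray):
                d[key] = d[key].tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


def _per_year(value, n_years: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.repeat(arr, n_years)
    if arr.size != n_years:
        raise ValueError("per-year parameter length must equal n_years")
    return arr


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring downstream calls."""

    asv_class: dict[str, str]            # summer | winter | aperiodic
    asv_peak_day: dict[str, float | None]
    year_coupled: dict[int, bool]        # calendar year -> driven?
    driver_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "asv_class": self.asv_class,
                "asv_peak_day": self.asv_peak_day,
                "year_coupled": {str(k): v for k, v in self.year_coupled.items()},
                "driver_params": self.driver_params,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            asv_class=d["asv_class"],
            asv_peak_day=d["asv_peak_day"],
            year_coupled={int(k): v for k, v in d["year_coupled"].items()},
            driver_params=d.get("driver_params", {}),
        )


# ---------------------------------------------------------------------------
# Sampling dates
# ---------------------------------------------------------------------------

def _sample_dates(cfg: SimConfig, rng: np.random.Generator) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start_date)
    if cfg.cadence == "weekly":
        n = cfg.n_years * 52
        dates = start + pd.to_timedelta(np.arange(n) * 7, unit="D")
        if cfg.jitter_days:
            jit = rng.integers(-cfg.jitter_days, cfg.jitter_days + 1, size=n)
            dates = dates + pd.to_timedelta(jit, unit="D")
    elif cfg.cadence == "monthly":
        n = cfg.n_years * 12
        dates = pd.DatetimeIndex([
            pd.Timestamp(year=start.year + i // 12,
                         month=1 + i % 12, day=15) for i in range(n)
        ])
    else:
        raise ValueError(f"unknown cadence: {cfg.cadence!r}")
    if cfg.missing_fraction > 0:
        keep = rng.random(len(dates)) >= cfg.missing_fraction
        keep[0] = keep[-1] = True          # preserve the span
        dates = dates[keep]
    return pd.DatetimeIndex(dates)


def _seasonal_temperature(doy: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return cfg.temp_mean - cfg.temp_amplitude * np.cos(
        2 * np.pi * (doy - cfg.temp_trough_doy) / 365.0)


def _ar1(n: int, rho: float, sd: np.ndarray | float,
         rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n) * sd
    out = np.empty(n)
    out[0] = innov[0] / np.sqrt(max(1 - rho ** 2, 1e-12))
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov[t]
    return out


def _anomaly(cfg: SimConfig, n: int, week_idx: np.ndarray,
             rng: np.random.Generator, sd: float) -> np.ndarray:
    mod = 1.0 + cfg.anom_modulation * np.cos(
        2 * np.pi * week_idx / cfg.anom_modulation_period)
    return _ar1(n, cfg.anom_ar1, sd * mod, rng)


def generate_environment(cfg: SimConfig) -> EnvMatrix:
    """17 named environmental variables on the configured sampling dates.

    Short-term variability is synoptic: a single amplitude-modulated AR(1)
    "weather anomaly" process loads on most variables (storms raise wind,
    river flow and turbidity, depress pressure and perturb temperature
    simultaneously), while each variable's idiosyncratic noise is a smooth
    AR(1) so that week-to-week environmental change is weather-driven, as
    at a coastal station, rather than independent white jitter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    dates = _sample_dates(cfg, rng)
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float) - 1.0
    start = pd.Timestamp(cfg.start_date)
    week = ((dates - start).days.to_numpy(dtype=float)) / 7.0
    year_idx = np.clip(((dates - start).days.to_numpy() // 365), 0,
                       cfg.n_years - 1)
    storm = cfg.storminess_by_year()[year_idx]

    w = _anomaly(cfg, n, week, rng, 1.0)       # shared weather anomaly
    # smooth idiosyncratic AR(1) with stationary sd equal to the argument
    smooth = lambda sd: _ar1(n, 0.85, sd * np.sqrt(1 - 0.85 ** 2), rng)  # noqa: E731

    temp = (_seasonal_temperature(doy, cfg) + cfg.temp_anom_sd * w
            + smooth(0.15))

    winter_cycle = 0.5 * (1 + np.cos(2 * np.pi * (doy - cfg.temp_trough_doy)
                                     / 365.0))
    nitrate = np.clip(8.0 * winter_cycle + smooth(0.8) + 0.3 * w, 0, None)
    silicate = np.clip(5.0 * winter_cycle + smooth(0.5) + 0.2 * w, 0, None)
    phosphate = np.clip(0.5 * winter_cycle + smooth(0.06) + 0.02 * w, 0, None)
    chlorophyll = np.clip(
        0.8 + 2.5 * np.exp(-0.5 * ((doy - 105.0) / 15.0) ** 2)
        + smooth(0.25) - 0.1 * w, 0.05, None)

    wind_mean = np.exp(np.log(5.0 * (1 + storm))
                       + 0.30 * (0.9 * w + 0.45 * _ar1(n, 0.5, 1.0, rng)))
    wind_max = wind_mean * np.exp(0.4 + 0.10 * _ar1(n, 0.5, 1.0, rng)
                                  + 0.05 * w)
    river_flow = np.exp(np.log(20.0 * (1 + 2 * storm))
                        + 0.45 * (0.6 * w + 0.7 * _ar1(n, 0.7, 0.7, rng)))

    temp_z = (temp - temp.mean()) / max(temp.std(), 1e-9)
    nuisance = {}
    # (name, mean, sd, loading on seasonal temp_z, loading on weather w)
    specs = [
        ("salinity", 35.1, 0.15, -0.3, -0.3), ("oxygen", 260.0, 12.0, -0.8, 0.2),
        ("pH", 8.1, 0.04, 0.2, -0.1), ("par", 25.0, 8.0, 0.7, -0.3),
        ("ammonium", 0.4, 0.15, -0.4, 0.2), ("doc", 70.0, 6.0, 0.3, 0.2),
        ("turbidity", 1.5, 0.5, 0.1, 0.6), ("pressure", 1013.0, 6.0, -0.1, -0.5),
        ("humidity", 82.0, 5.0, 0.0, 0.3),
    ]
    for name, mean, sd, a, b in specs:
        resid = max(1.0 - a ** 2 - b ** 2, 0.05)
        nuisance[name] = mean + sd * (a * temp_z + b * w
                                      + np.sqrt(resid) * smooth(1.0))

    values = pd.DataFrame({
        "temperature": temp, "nitrate": nitrate, "silicate": silicate,
        "phosphate": phosphate, "chlorophyll": chlorophyll,
        "wind_mean": wind_mean, "wind_max": wind_max,
        "river_flow": river_flow, **nuisance,
    }, index=[f"S{i:04d}" for i in range(n)])
    units = {"temperature": "degC", "nitrate": "uM", "silicate": "uM",
             "phosphate": "uM", "chlorophyll": "mg m-3",
             "wind_mean": "m s-1", "wind_max": "m s-1",
             "river_flow": "m3 s-1"}
    return EnvMatrix(values, pd.Series(dates, index=values.index),
                     units=units)


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

def _driver_from_env(cfg: SimConfig, env: EnvMatrix) -> np.ndarray:
    """Standardized weekly temperature anomaly (environment minus annual cycle)."""
    doy = pd.to_datetime(env.dates).dt.dayofyear.to_numpy(dtype=float) - 1.0
    anom = env.values["temperature"].to_numpy() - _seasonal_temperature(doy, cfg)
    sd = anom.std()
    return anom / max(sd, 1e-9)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, np.ones(w) / w, mode="valid")


def _taxonomy_labels(cfg: SimConfig, summer_ids, winter_ids, aperiodic_ids,
                     rng: np.random.Generator) -> dict[str, str]:
    labels = {}
    summer_pool = ["Ia.3"] * (len(summer_ids) - 1) + ["IV"]
    for asv, lab in zip(summer_ids, summer_pool):
        labels[asv] = lab
    winter_pool = (["Ia.1", "IIa.B", "Ib", "II"] if cfg.taxonomy_preset == "wec"
                   else ["Ib", "IIa.A", "Ib.2", "IV"])
    for i, asv in enumerate(winter_ids):
        labels[asv] = winter_pool[i % len(winter_pool)]
    mixed_pool = ["other", "IIb", "IIIa", "other", "Ia.4", "IIa", "other"]
    for i, asv in enumerate(aperiodic_ids):
        labels[asv] = mixed_pool[i % len(mixed_pool)]
    return labels


def generate_community(cfg: SimConfig, env: EnvMatrix
                       ) -> tuple[CountMatrix, TaxonomyMap, GroundTruth]:
    """Dirichlet-multinomial counts for seasonal guilds + aperiodic ASVs."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    dates = pd.to_datetime(env.dates)
    n = len(dates)
    doy = dates.dt.dayofyear.to_numpy(dtype=float) - 1.0
    start = pd.Timestamp(cfg.start_date)
    elapsed_years = np.clip((dates - start).dt.days.to_numpy() // 365, 0,
                            cfg.n_years - 1)
    coupling = cfg.coupling_by_year()[elapsed_years]

    ns, nw, na = cfg.n_summer_asvs, cfg.n_winter_asvs, cfg.n_aperiodic_asvs
    summer_ids = [f"ASV{i + 1:03d}" for i in range(ns)]
    winter_ids = [f"ASV{i + 1:03d}" for i in range(ns, ns + nw)]
    aperiodic_ids = [f"ASV{i + 1:03d}" for i in range(ns + nw, ns + nw + na)]

    peaks = np.concatenate([
        np.mod(cfg.summer_peak_day
               + rng.normal(0, cfg.peak_scatter_days, ns), 365.0),
        np.mod(cfg.winter_peak_day
               + rng.normal(0, cfg.peak_scatter_days, nw), 365.0),
    ])
    base = rng.normal(0.0, 1.0, size=ns + nw)     # uneven base abundances

    u = _driver_from_env(cfg, env)

    # Weather-driven displacement: each week the seasonal taxa take a
    # mean-reverting random step in log-affinity whose size scales with the
    # same-week environmental change |du| (mixing events of larger magnitude
    # displace the community further, in an unpredictable direction).
    du = np.abs(np.diff(u, prepend=u[0]))
    du[0] = du[1:].mean() if n > 1 else 0.0
    steps = (cfg.coupling_response * du[:, None]
             * rng.standard_normal((n, ns + nw)))
    displacement = np.empty((n, ns + nw))
    displacement[0] = steps[0]
    for t in range(1, n):
        displacement[t] = 0.7 * displacement[t - 1] + steps[t]

    # Coupling blends the same-week signal against its 8-week moving
    # average (week-scale change removed, annual cycle kept).
    log_a_raw = (cfg.seasonal_amplitude
                 * np.cos(2 * np.pi * (doy[:, None] - peaks[None, :]) / 365.0)
                 + displacement + base[None, :])
    smoothed = np.apply_along_axis(_moving_average, 0, log_a_raw, 8)
    log_a = (coupling[:, None] * log_a_raw
             + (1.0 - coupling[:, None]) * smoothed)
    aff = np.exp(log_a - log_a.max(axis=1, keepdims=True))
    seasonal_p = (1.0 - cfg.aperiodic_share) * aff / aff.sum(axis=1,
                                                             keepdims=True)

    weights = rng.dirichlet(np.full(na, 0.5)) if na else np.empty(0)
    aperiodic_p = np.tile(cfg.aperiodic_share * weights, (n, 1))

    expected = np.hstack([seasonal_p, aperiodic_p])
    conc = cfg.dispersion * expected
    lib = np.maximum(rng.lognormal(cfg.library_size_log_mu,
                                   cfg.library_size_log_sigma, n), 1.0)
    counts = np.empty((n, ns + nw + na), dtype=np.int64)
    for i in range(n):
        p = rng.gamma(np.clip(conc[i], 1e-8, None))
        p /= p.sum()
        counts[i] = rng.multinomial(int(lib[i]), p)

    asv_ids = summer_ids + winter_ids + aperiodic_ids
    sample_ids = list(env.values.index)
    cm = CountMatrix(
        pd.DataFrame(counts, index=sample_ids, columns=asv_ids),
        pd.Series(dates.to_numpy(), index=sample_ids),
    )
    tax = TaxonomyMap(_taxonomy_labels(cfg, summer_ids, winter_ids,
                                       aperiodic_ids, rng))

    classes = (["summer"] * ns + ["winter"] * nw + ["aperiodic"] * na)
    peak_map: dict[str, float | None] = {
        a: (float(peaks[i]) if i < ns + nw else None)
        for i, a in enumerate(asv_ids)
    }
    coupling_per_year = cfg.coupling_by_year()
    year_coupled = {
        start.year + i: bool(coupling_per_year[i] >= 0.5)
        for i in range(cfg.n_years)
    }
    gt = GroundTruth(
        asv_class=dict(zip(asv_ids, classes)),
        asv_peak_day=peak_map,
        year_coupled=year_coupled,
        driver_params={
            "coupling_by_year": coupling_per_year.tolist(),
            "storminess_by_year": cfg.storminess_by_year().tolist(),
            "anom_modulation_period": cfg.anom_modulation_period,
            "seasonal_amplitude": cfg.seasonal_amplitude,
        },
    )
    return cm, tax, gt


def generate_dataset(cfg: SimConfig):
    """Environment + community in one call; returns (env, counts, tax, truth)."""
    env = generate_environment(cfg)
    cm, tax, gt = generate_community(cfg, env)
    return env, cm, tax, gt


def presets() -> dict[str, SimConfig]:
    """Named study designs emulating the two observatories and the
    coupled/decoupled contrast years."""
    return {
        "bats_like": SimConfig(n_years=3, cadence="monthly",
                               missing_fraction=0.0, jitter_days=0,
                               taxonomy_preset="bats", seed=0),
        "wec_like": SimConfig(n_years=7, cadence="weekly",
                              missing_fraction=0.1, taxonomy_preset="wec",
                              seed=0),
        "coupled_year": SimConfig(n_years=2, cadence="weekly",
                                  missing_fraction=0.05,
                                  coupling_strength=1.0, storminess=0.1,
                                  seed=0),
        "decoupled_year": SimConfig(n_years=2, cadence="weekly",
                                    missing_fraction=0.05,
                                    coupling_strength=0.0, storminess=1.0,
                                    seed=0),
    }


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Emit the exact file formats the community module reads."""
    from .community import write_count_table, write_env_table, write_taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env, cm, tax, gt = generate_dataset(cfg)
    paths = {
        "counts": str(outdir / "counts.tsv"),
        "taxonomy": str(outdir / "taxonomy.tsv"),
        "env": str(outdir / "environment.csv"),
        "groundtruth": str(outdir / "groundtruth.json"),
        "config": str(outdir / "sim_config.json"),
    }
    write_count_table(cm, paths["counts"], format="tsv")
    write_taxonomy(tax, paths["taxonomy"])
    write_env_table(env, paths["env"])
    gt.to_json(paths["groundtruth"])
    with open(paths["config"], "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1)
    return paths
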