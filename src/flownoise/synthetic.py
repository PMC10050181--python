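"""Synthetic inputs with known spectral structure.

Everything downstream — QC, detrending, periodogram slopes, driver
attribution — is validated against series generated here, where the truth
is known by construction:

* ``gen_colored_noise`` builds 1/f^a noise by spectral synthesis: Fourier
  coefficients with amplitude (k/T)^(-a/2) and independent uniform phases,
  inverse-transformed to a real series. The amplitudes are deterministic,
  so the periodogram follows the target power law exactly on the discrete
  frequency grid and slope-recovery tests are sharp.
* ``gen_ar1`` provides a process with a closed-form spectrum
  (``theoretical_ar1_spectrum``) as an independent analytic oracle.
* ``gen_streamflow_like`` composes a strictly positive discharge-like
  series in log space: baseline + linear trend + annual sinusoid + colored
  noise. It is a test harness emulating the structure the pipeline removes
  (trend, seasonality), not a hydrologic model.
* ``gen_driver_table`` draws covariate tables with a known functional
  dependence of noise color on chosen drivers, for testing the
  random-forest attribution workflow.

All generators take an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ingest import FlowSeries

__all__ = [
    "ColoredNoiseSpec",
    "StreamflowSimSpec",
    "DriverTableSpec",
    "DEFAULT_COVARIATE_CATEGORIES",
    "gen_colored_noise",
    "gen_ar1",
    "theoretical_ar1_spectrum",
    "gen_streamflow_like",
    "inject_missing",
    "gen_driver_table",
    "write_gage_set",
]

MIN_LENGTH = 16

#: 13 covariates in 4 categories, mirroring a gage-scale driver table:
#: geography, hydroclimate, land use / land cover, and water management.
DEFAULT_COVARIATE_CATEGORIES: dict[str, str] = {
    "drainage_area": "Geo",
    "elevation": "Geo",
    "stream_order": "Geo",
    "precip_mean": "Hydro",
    "precip_cv": "Hydro",
    "temp_mean": "Hydro",
    "temp_cv": "Hydro",
    "forest_pct": "Land use",
    "wetland_pct": "Land use",
    "urban_pct": "Land use",
    "water_use": "Water use",
    "dor": "Water use",
    "dof": "Water use",
}

VALID_CATEGORIES = frozenset({"Geo", "Hydro", "Land use", "Water use"})


@dataclass(frozen=True)
class ColoredNoiseSpec:
    """Parameters for 1/f^a spectral-synthesis noise.

    ``exponent`` is the target spectral slope a (>= -2); ``scale`` the
    output standard deviation in arbitrary discharge-like units.
    """

    exponent: float
    length: int
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent):
            raise ValueError("exponent must be finite")
        if self.exponent < -2:
            raise ValueError("exponent must be >= -2")
        if self.length < MIN_LENGTH:
            raise ValueError(f"length must be >= {MIN_LENGTH}")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class StreamflowSimSpec:
    """Parameters for a streamflow-like composite daily series.

    The series is exp(baseline + trend_slope*d + seasonal + colored noise),
    with the seasonal term an annual sinusoid in log-discharge. The phase
    clock maps Feb 29 onto Feb 28, so once leap days are dropped by the
    pipeline the seasonal component is exactly 365-periodic.
    """

    start_date: str = "1980-01-01"
    n_years: int = 20
    baseline: float = 1.0
    trend_slope: float = 0.0
    seasonal_amplitude: float = 0.5
    seasonal_phase: float = 0.0
    noise_exponent: float = 1.0
    noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass(frozen=True)
class DriverTableSpec:
    """Parameters for a synthetic driver table with known effects.

    ``effect_functions`` maps covariate names to deterministic functions of
    that covariate's value on [0, 1]; the response (noise color) is the sum
    of effects plus Gaussian residual noise.
    """

    n_gages: int = 200
    effect_functions: Mapping[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    noise_sd: float = 0.1
    covariate_categories: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_CATEGORIES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gages < 30:
            raise ValueError("n_gages must be >= 30")
        if len(self.covariate_categories) != 13:
            raise ValueError("exactly 13 covariates required")
        bad = set(self.covariate_categories.values()) - VALID_CATEGORIES
        if bad:
            raise ValueError(f"unknown covariate categories: {bad}")
        unknown = set(self.effect_functions) - set(self.covariate_categories)
        if unknown:
            raise ValueError(f"effect functions for unknown covariates: {unknown}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# colored noise


def gen_colored_noise(spec: ColoredNoiseSpec) -> np.ndarray:
    """Generate 1/f^a noise by Fourier filtering.

    Coefficients for k = 1..floor(T/2) get amplitude (k/T)^(-a/2) and an
    independent uniform phase; the mean (DC) coefficient is zero and, for
    even T, the Nyquist coefficient is real (a random sign) as required for
    a real inverse transform. The output is standardized to zero mean and
    standard deviation ``scale``; standardization rescales all spectral
    power by one constant, so the log-log slope is untouched.
    """
    T, a = spec.length, spec.exponent
    rng = np.random.default_rng(spec.seed)
    k = np.arange(1, T // 2 + 1)
    amplitude = (k / T) ** (-a / 2.0)
    phase = rng.uniform(0.0, 2.0 * math.pi, size=k.size)
    coef = amplitude * np.exp(1j * phase)
    if T % 2 == 0:
        coef[-1] = amplitude[-1] * (1.0 if phase[-1] < math.pi else -1.0)
    spectrum = np.concatenate([[0.0 + 0.0j], coef])
    x = np.fft.irfft(spectrum, n=T)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise RuntimeError("degenerate synthesis: zero variance")
    return x / sd * spec.scale


def gen_ar1(phi: float, n: int, sigma: float = 1.0, seed: int = 0) -> np.ndarray:
    """Stationary AR(1): x_t = phi x_{t-1} + eps_t, eps ~ N(0, sigma^2).

    x_0 is drawn from the stationary distribution N(0, sigma^2/(1-phi^2)),
    so the whole series is stationary from the first sample.
    """
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1 for stationarity")
    if n < MIN_LENGTH:
        raise ValueError(f"n must be >= {MIN_LENGTH}")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, sigma / math.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sigma, size=n)
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def theoretical_ar1_spectrum(phi: float, f, sigma: float = 1.0):
    """Closed-form AR(1) power spectrum, sigma^2 / (1 + phi^2 - 2 phi cos 2 pi f).

    Normalization matches the T^(-1/2) periodogram convention: the expected
    periodogram ordinate E[P_k] converges to this value at f = k/T (for
    white noise, phi = 0, both equal sigma^2 at every frequency).
    ``f`` is in cycles per sample and must lie in (0, 0.5].
    """
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 0.5):
        raise ValueError("frequency must be in (0, 0.5]")
    out = sigma**2 / (1.0 + phi * phi - 2.0 * phi * np.cos(2.0 * math.pi * f))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# streamflow-like composite series


def _seasonal_day_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """0..364 position on a 365-day phase clock; Feb 29 shares Feb 28's phase."""
    doy = dates.dayofyear.values
    leap = dates.is_leap_year
    return np.where(leap & (doy >= 60), doy - 2, doy - 1)


def gen_streamflow_like(spec: StreamflowSimSpec, gage_id: str = "synthetic") -> FlowSeries:
    """Generate a strictly positive discharge-like daily series.

    log Q_d = baseline + trend_slope*d + seasonal_amplitude*sin(2 pi p_d/365
    + seasonal_phase) + eta_d, where eta is colored noise with the requested
    exponent and standard deviation (in log-discharge). Noise is added in
    log space to guarantee positivity; the slope estimator is
    scale-invariant, so the transform does not bias recovery at moderate
    noise scales.
    """
    start = pd.Timestamp(spec.start_date)
    end = start + pd.DateOffset(years=spec.n_years) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    d = np.arange(n, dtype=float)
    seasonal = spec.seasonal_amplitude * np.sin(
        2.0 * math.pi * _seasonal_day_index(dates) / 365.0 + spec.seasonal_phase
    )
    if spec.noise_scale > 0:
        eta = gen_colored_noise(
            ColoredNoiseSpec(spec.noise_exponent, n, spec.noise_scale, spec.seed)
        )
    else:
        eta = np.zeros(n)
    log_q = spec.baseline + spec.trend_slope * d + seasonal + eta
    return FlowSeries(gage_id=gage_id, dates=dates, values=np.exp(log_q), source="synthetic")


def inject_missing(series: FlowSeries, frac: float, seed: int = 0) -> FlowSeries:
    """Mark round(frac*T) interior positions missing, uniformly at random.

    The first and last observations are never removed (gap filling must be
    able to interpolate, not extrapolate).
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    T = len(series)
    n_remove = int(round(frac * T))
    if T - n_remove < 2:
        raise ValueError("would leave fewer than 2 observed values")
    if n_remove == 0:
        return FlowSeries(series.gage_id, series.dates, series.values.copy(), series.source)
    rng = np.random.default_rng(seed)
    interior = np.arange(1, T - 1)
    drop = rng.choice(interior, size=n_remove, replace=False)
    values = series.values.copy()
    values[drop] = np.nan
    return FlowSeries(series.gage_id, series.dates, values, series.source)


# ---------------------------------------------------------------------------
# driver tables


def gen_driver_table(spec: DriverTableSpec):
    """Generate a covariate table with a known response surface.

    Covariates are i.i.d. uniform on [0, 1]; the response (noise color) is
    the sum of the per-covariate effect functions plus Gaussian noise.
    Returns a :class:`flownoise.drivers.DriverTable`.
    """
    from .drivers import DriverTable

    rng = np.random.default_rng(spec.seed)
    names = list(spec.covariate_categories)
    X = rng.uniform(0.0, 1.0, size=(spec.n_gages, 13))
    data = pd.DataFrame(X, columns=names)
    response = np.zeros(spec.n_gages)
    for name, fn in spec.effect_functions.items():
        response = response + np.asarray(fn(data[name].values), dtype=float)
    if spec.noise_sd > 0:
        response = response + rng.normal(0.0, spec.noise_sd, size=spec.n_gages)
    data.insert(0, "gage_id", [f"synthetic-{i:05d}" for i in range(spec.n_gages)])
    data["noise_color"] = response
    return DriverTable(data=data, categories=dict(spec.covariate_categories))


# ---------------------------------------------------------------------------
# gage-set output


def write_gage_set(
    specs: list[StreamflowSimSpec], out_dir, seed_offset: int = 0
) -> pd.DataFrame:
    """Write a synthetic gage network as date,value CSVs plus a manifest.

    Each spec becomes ``gage-<i>.csv`` (columns date,value; missing token
    NA) and a row in ``manifest.csv`` recording the generating parameters,
    including the true noise exponent, for round-trip pipeline tests.
    Returns the manifest frame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        gid = f"synthetic-{i + seed_offset:05d}"
        series = gen_streamflow_like(spec, gage_id=gid)
        frame = series.to_frame()
        frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
        path = out / f"gage-{i + seed_offset:05d}.csv"
        frame.to_csv(path, index=False, na_rep="NA")
        rows.append(
            {
                "gage_id": gid,
                "file": path.name,
                "true_exponent": spec.noise_exponent,
                "start_date": spec.start_date,
                "n_years": spec.n_years,
                "baseline": spec.baseline,
                "trend_slope": spec.trend_slope,
                "seasonal_amplitude": spec.seasonal_amplitude,
                "seasonal_phase": spec.seasonal_phase,
                "noise_scale": spec.noise_scale,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
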