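"""Synthetic mooring and annual-anomaly series generators.

Emulates the statistical structure the analysis consumes: near-hourly
bottom-water records with a mean level, one annual harmonic and AR(1) noise,
and multidecadal annual series with a linear trend plus white noise. The
AR(1) innovations are scaled so the *stationary* standard deviation equals
the requested ``noise_sd`` (parameter-recovery tests depend on this).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tsstats import SiteSeries

__all__ = [
    "PodSimSpec",
    "AnnualSimSpec",
    "simulate_pod_series",
    "simulate_annual_series",
]


@dataclass(frozen=True)
class PodSimSpec:
    """Mooring-series recipe: mean + seasonal harmonic + AR(1) noise."""

    mean: float
    seasonal_amplitude: float = 0.0
    noise_sd: float = 0.0
    ar1_coefficient: float = 0.9
    sampling_interval: float = 1.0  # hours
    duration: float = 3.4  # years
    seed: int = 0
    site_id: str = "SYN001"
    depth: float = 150.0
    variable: str = "oxygen"
    unit: str = "mg/L"
    start: str = "2011-11-01"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be > 0")


@dataclass(frozen=True)
class AnnualSimSpec:
    """Annual-anomaly recipe: linear trend plus iid Gaussian noise."""

    start_year: int
    n_years: int
    intercept: float
    slope: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("need n_years >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_pod_series(spec: PodSimSpec) -> SiteSeries:
    """Generate a mooring-like series; reproducible for a fixed seed.

    value(t) = mean + A·cos(2π · doy / 365.25) + AR(1) noise whose
    stationary standard deviation equals ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * 365.25 * 24.0 / spec.sampling_interval))
    times = pd.date_range(
        spec.start, periods=n, freq=pd.Timedelta(hours=spec.sampling_interval)
    )
    doy = times.dayofyear.to_numpy(dtype=float)
    seasonal = spec.seasonal_amplitude * np.cos(2.0 * np.pi * doy / 365.25)
    noise = np.zeros(n)
    if spec.noise_sd > 0:
        phi = spec.ar1_coefficient
        innov_sd = spec.noise_sd * math.sqrt(1.0 - phi**2)
        noise[0] = rng.normal(0.0, spec.noise_sd)  # stationary start
        innov = rng.normal(0.0, innov_sd, size=n)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + innov[i]
    data = pd.Series(spec.mean + seasonal + noise, index=times)
    return SiteSeries(
        site_id=spec.site_id,
        depth=spec.depth,
        variable=spec.variable,
        unit=spec.unit,
        data=data,
    )


def simulate_annual_series(spec: AnnualSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (years, values) with a linear trend and white noise."""
    rng = np.random.default_rng(spec.seed)
    years = np.arange(spec.start_year, spec.start_year + spec.n_years, dtype=float)
    values = spec.intercept + spec.slope * (years - spec.start_year)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.n_years)
    return years, values
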