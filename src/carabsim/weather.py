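"""Synthetic multi-year daily weather with temperate-maritime structure.

Temperature is a sinusoidal annual cycle plus AR(1) daily noise;
precipitation follows a seeded two-state (wet/dry) Markov chain with
gamma-distributed wet-day amounts; wind is AR(1) around a seasonal mean.
Years are 365 days long (no leap days); day-of-year 59 is March 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DAYS_PER_YEAR = 365


@dataclass
class ClimatePreset:
    """Parameters of the annual weather cycle.

    The default emulates a temperate-maritime (Dutch lowland) climate:
    annual mean near 10 degC with a ~7 degC seasonal amplitude, coldest in
    mid-January, roughly half of days wet.
    """

    annual_mean_c: float = 10.0
    amplitude_c: float = 7.0
    coldest_doy: int = 15
    noise_sd_c: float = 2.5
    noise_ar1: float = 0.7
    p_wet_after_wet: float = 0.65
    p_wet_after_dry: float = 0.25
    rain_gamma_shape: float = 0.9
    rain_gamma_scale_mm: float = 5.0
    wind_mean_ms: float = 4.0
    wind_sd_ms: float = 1.5
    wind_ar1: float = 0.6


TEMPERATE_MARITIME = ClimatePreset()


@dataclass
class WeatherSeries:
    """Daily weather over ``n_years`` 365-day years (gap-free)."""

    tmean_c: np.ndarray
    wind_ms: np.ndarray
    precip_mm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.tmean_c)
        if n % DAYS_PER_YEAR or len(self.wind_ms) != n or len(self.precip_mm) != n:
            raise ValueError("series must cover whole 365-day years with equal lengths")

    @property
    def n_years(self) -> int:
        return len(self.tmean_c) // DAYS_PER_YEAR

    def day_index(self, year: int, doy: int) -> int:
        """Linear index of day-of-year ``doy`` (1-based) in ``year`` (0-based)."""
        if not 1 <= doy <= DAYS_PER_YEAR:
            raise ValueError("day-of-year out of range")
        return year * DAYS_PER_YEAR + doy - 1

    def year_slice(self, year: int) -> slice:
        return slice(year * DAYS_PER_YEAR, (year + 1) * DAYS_PER_YEAR)


def generate_weather(
    n_years: int,
    seed: int | np.random.Generator,
    preset: ClimatePreset = TEMPERATE_MARITIME,
) -> WeatherSeries:
    """Generate a seeded synthetic weather series of ``n_years`` years."""
    if n_years < 1:
        raise ValueError("need at least one year")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR
    doy = np.arange(n) % DAYS_PER_YEAR + 1

    seasonal = preset.annual_mean_c - preset.amplitude_c * np.cos(
        2 * np.pi * (doy - preset.coldest_doy) / DAYS_PER_YEAR
    )
    rho = preset.noise_ar1
    innov_sd = preset.noise_sd_c * np.sqrt(max(1e-12, 1 - rho**2))
    noise = np.empty(n)
    noise[0] = rng.normal(0, preset.noise_sd_c)
    eps = rng.normal(0, innov_sd, size=n)
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + eps[i]
    tmean = seasonal + noise

    wet = np.empty(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < 0.5
    for i in range(1, n):
        p = preset.p_wet_after_wet if wet[i - 1] else preset.p_wet_after_dry
        wet[i] = u[i] < p
    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        precip[wet] = rng.gamma(preset.rain_gamma_shape, preset.rain_gamma_scale_mm, n_wet)

    wrho = preset.wind_ar1
    wind_innov = preset.wind_sd_ms * np.sqrt(max(1e-12, 1 - wrho**2))
    wnoise = np.empty(n)
    wnoise[0] = rng.normal(0, preset.wind_sd_ms)
    weps = rng.normal(0, wind_innov, size=n)
    for i in range(1, n):
        wnoise[i] = wrho * wnoise[i - 1] + weps[i]
    wind = np.maximum(0.0, preset.wind_mean_ms + wnoise)

    return WeatherSeries(tmean_c=tmean, wind_ms=wind, precip_mm=precip)
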