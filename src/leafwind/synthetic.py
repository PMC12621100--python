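"""Synthetic forcing generators.

Every scenario in the package can run from generated inputs, so the whole
pipeline is testable without external weather or microclimate files.  Three
generators are provided:

* :func:`gen_diurnal` — a greenhouse-style diurnal forcing: a 16 h
  photoperiod with PPFD rising to a 1500 umol m-2 s-1 peak (half-sine by
  default) under constant air temperature (32 degC), vapour pressure
  (2.4 kPa, i.e. 50% relative humidity) and CO2;
* :func:`gen_profile` — a within-canopy vertical microclimate profile in
  the style of a dense June wheat crop: air CO2 rising from 366 umol mol-1
  at the canopy top to 380 at the bottom, PPFD decaying from
  1600 umol m-2 s-1 with cumulative leaf area (Beer-Lambert), wind from
  the exponential canopy attenuation law, and mild temperature/VPD
  gradients;
* :func:`gen_wind_series` — an anemometer-style wind time series with a
  Weibull marginal distribution and AR(1) temporal persistence (a Gaussian
  copula construction, so the marginal is exactly Weibull).

All generators are pure functions of their parameters (and seed).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .canopy_wind import CanopyDescription, attenuation_coefficient, u_within

__all__ = ["gen_diurnal", "gen_profile", "gen_wind_series"]


def gen_diurnal(
    photoperiod_h: float = 16.0,
    ppfd_max: float = 1500.0,
    Tair: float = 32.0,
    ea: float = 2.4,
    Ca: float = 425.0,
    dt: float = 60.0,
    shape: str = "half_sine",
    Trefl: float | None = None,
) -> pd.DataFrame:
    """Diurnal forcing table over one photoperiod.

    ``shape="half_sine"`` gives ``PPFD(t) = ppfd_max sin(pi t / T)``;
    ``"trapezoid"`` ramps linearly over the first and last quarter of the
    photoperiod with a plateau at ``ppfd_max`` in between.  Air state
    (Tair, ea, Ca) is constant; Trefl defaults to Tair.

    Returns a DataFrame with columns ``time`` (s), ``PPFD``, ``Tair``,
    ``ea``, ``Ca``, ``Trefl``.
    """
    if photoperiod_h <= 0 or dt <= 0:
        raise ValueError("photoperiod_h and dt must be positive")
    T = photoperiod_h * 3600.0
    t = np.arange(0.0, T + 0.5 * dt, dt)
    if shape == "half_sine":
        ppfd = ppfd_max * np.sin(np.pi * np.clip(t, 0, T) / T)
    elif shape == "trapezoid":
        ramp = T / 4.0
        ppfd = ppfd_max * np.clip(np.minimum(t / ramp, (T - t) / ramp), 0.0, 1.0)
    else:
        raise ValueError(f"unknown diurnal shape {shape!r}")
    ppfd = np.maximum(ppfd, 0.0)
    return pd.DataFrame({
        "time": t,
        "PPFD": ppfd,
        "Tair": Tair,
        "ea": ea,
        "Ca": Ca,
        "Trefl": Tair if Trefl is None else Trefl,
    })


def gen_profile(
    h: float = 0.8,
    n_levels: int = 9,
    Ca_top: float = 366.0,
    Ca_bottom: float = 380.0,
    ppfd_top: float = 1600.0,
    extinction_k: float = 0.5,
    T_top: float = 25.0,
    VPD_top: float = 1.5,
    dT_bottom: float = -1.0,
    dVPD_bottom: float = -0.3,
    u_top: float = 1.0,
    LAI: float = 5.3,
    leaf_width: float = 0.01,
    ca_curvature: float = 3.0,
) -> pd.DataFrame:
    """Synthetic within-canopy vertical microclimate profile.

    The height grid spans the canopy interior from 0.1 h to the canopy top
    ``h``.  PPFD follows Beer-Lambert decay with the leaf area above each
    level (uniform leaf area density): ``PPFD(z) = ppfd_top
    exp[-k LAI (1 - z/h)]``.  Air CO2 rises non-linearly (exponential
    approach with curvature ``ca_curvature``) from ``Ca_top`` to
    ``Ca_bottom``; temperature and VPD interpolate linearly to their
    bottom offsets; wind follows the canopy attenuation law.

    Returns a DataFrame with columns ``z`` (m, ascending), ``Ca``, ``VPD``
    (kPa), ``T`` (degC), ``PPFD``, ``u``.
    """
    if n_levels < 3:
        raise ValueError("n_levels must be >= 3")
    if Ca_bottom < Ca_top:
        warnings.warn("Ca_bottom < Ca_top is physically atypical within a canopy",
                      stacklevel=2)
    z = np.linspace(0.1 * h, h, n_levels)
    z_rel = z / h
    lai_above = LAI * (1.0 - z_rel)
    ppfd = ppfd_top * np.exp(-extinction_k * lai_above)
    # exponential approach from the bottom value toward the top value
    c = ca_curvature
    frac = (1.0 - np.exp(-c * z_rel)) / (1.0 - np.exp(-c))
    Ca = Ca_bottom + (Ca_top - Ca_bottom) * frac
    T = T_top + dT_bottom * (1.0 - z_rel)
    VPD = np.maximum(VPD_top + dVPD_bottom * (1.0 - z_rel), 0.05)
    canopy = CanopyDescription(h=h, LAI=LAI, w=leaf_width)
    a = attenuation_coefficient(canopy)
    u = u_within(u_top, np.clip(z_rel, 1e-9, 1.0), a)

    df = pd.DataFrame({"z": z, "Ca": Ca, "VPD": VPD, "T": T, "PPFD": ppfd, "u": u})
    # construction invariants
    assert np.all(np.diff(df["PPFD"]) >= -1e-9), "PPFD must increase with height"
    assert np.all(np.diff(df["Ca"]) <= 1e-9) or Ca_bottom < Ca_top, \
        "Ca must not increase with height"
    return df


def gen_wind_series(
    n: int = 10_000,
    weibull_shape: float = 2.0,
    weibull_scale: float = 3.0,
    ar1_rho: float = 0.8,
    seed: int | None = 0,
    start: str = "2022-01-01 00:00",
    freq: str = "1min",
    T_mean: float = 12.0,
    T_amp: float = 6.0,
    include_ppfd: bool = True,
) -> pd.DataFrame:
    """Anemometer-style synthetic wind record sequence.

    A standard-normal AR(1) process with lag-1 correlation ``ar1_rho`` is
    mapped through the Gaussian CDF and the Weibull quantile function, so
    the marginal wind-speed distribution is exactly
    Weibull(shape, scale) while retaining temporal persistence (the
    rank correlation survives the monotone transform; the linear lag-1
    autocorrelation is close to, slightly below, ``ar1_rho``).

    Air temperature follows a diurnal sine around ``T_mean`` with
    amplitude ``T_amp``; an optional synthetic PPFD column (daylight
    half-sine, 06:00-22:00) supports daytime filtering downstream.

    Returns a DataFrame with columns ``timestamp``, ``u`` (m s-1), ``T``
    (degC) and optionally ``ppfd``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 <= ar1_rho < 1.0):
        raise ValueError("ar1_rho must lie in [0, 1)")
    if weibull_shape <= 0 or weibull_scale <= 0:
        raise ValueError("Weibull parameters must be positive")
    rng = np.random.default_rng(seed)
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innovations = rng.standard_normal(n - 1) * np.sqrt(1.0 - ar1_rho**2)
    for i in range(1, n):
        z[i] = ar1_rho * z[i - 1] + innovations[i - 1]
    u = stats.weibull_min.ppf(stats.norm.cdf(z), c=weibull_shape,
                              scale=weibull_scale)

    idx = pd.date_range(start=start, periods=n, freq=freq)
    hour = idx.hour + idx.minute / 60.0
    T = T_mean + T_amp * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)
    df = pd.DataFrame({"timestamp": idx, "u": u, "T": T})
    if include_ppfd:
        frac = np.clip((hour - 6.0) / 16.0, 0.0, 1.0)
        df["ppfd"] = 1000.0 * np.sin(np.pi * frac)
        df.loc[(hour < 6.0) | (hour > 22.0), "ppfd"] = 0.0
    return df
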