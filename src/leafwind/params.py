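"""Leaf parameter sets: photosynthetic, stomatal and energy-balance traits.

A simulation is parameterised by three blocks:

* :class:`PhotoParams` — FvCB biochemistry (Vcmax, Jmax, Rd, mesophyll
  conductance, Michaelis constants, electron-transport curvature) plus the
  induction/relaxation time constants of net assimilation;
* :class:`StomatalParams` — the Leuning stomatal model (g0, g1, D0) plus
  stomatal time constants;
* :class:`EnergyParams` — optical/thermal leaf properties for the energy
  balance.

Two presets ship with the package as editable YAML files
(``presets/*.yaml``): ``tomato_greenhouse`` (a greenhouse tomato leaf) and
``wheat_field`` (a field-grown wheat flag leaf).  Temperature-response
constants (Arrhenius activation energies, peaked-function terms of the
tobacco-calibrated sets standard in the FvCB literature) live in the YAML
presets so they can be edited without touching code; the dataclass defaults
mirror the shipped values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Any

import numpy as np
import yaml

__all__ = [
    "PhotoParams",
    "StomatalParams",
    "EnergyParams",
    "ParameterSet",
    "load_preset",
    "available_presets",
    "arrhenius",
    "peaked_arrhenius",
]

T_REF_K = 298.15
R_GAS = 8.314462618


def arrhenius(k25, Ea, T_K):
    """Arrhenius temperature scaling of a rate constant from 25 degC.

    ``k(T) = k25 exp[Ea (T - 298.15) / (298.15 R T)]``; Ea in J mol-1.
    """
    return k25 * np.exp(Ea * (T_K - T_REF_K) / (T_REF_K * R_GAS * T_K))


def peaked_arrhenius(k25, Ea, Hd, dS, T_K):
    """Peaked (optimum-temperature) Arrhenius function.

    Arrhenius rise moderated by a high-temperature deactivation term with
    enthalpy ``Hd`` (J mol-1) and entropy ``dS`` (J mol-1 K-1).
    """
    num = 1.0 + np.exp((T_REF_K * dS - Hd) / (T_REF_K * R_GAS))
    den = 1.0 + np.exp((dS * T_K - Hd) / (R_GAS * T_K))
    return arrhenius(k25, Ea, T_K) * num / den


@dataclass(frozen=True)
class PhotoParams:
    """FvCB photosynthesis parameters (25 degC basis).

    Units: Vcmax25, Jmax25, Rd25 in umol m-2 s-1; gm25 in
    umol m-2 s-1 Pa-1 (converted to a mole-fraction basis internally by
    multiplying by ambient pressure); Kc25, GammaStar25 in umol mol-1;
    Ko25 and O in mmol mol-1; time constants in s.
    """

    Vcmax25: float = 100.0
    Jmax25: float = 180.0
    Rd25: float = 1.0
    gm25: float = 4.0
    AbsPAR: float = 0.85  # PAR absorptance feeding electron transport
    Curv: float = 0.7  # curvature of J vs absorbed PAR
    f_spectral: float = 0.15  # spectral quality loss factor for PSII
    Kc25: float = 404.9
    Ko25: float = 278.4
    GammaStar25: float = 42.75
    O: float = 210.0
    tauA_inc: float = 300.0
    tauA_dec: float = 1.0
    # temperature-response constants (J mol-1; dS in J mol-1 K-1).  The
    # in-vivo tobacco calibrations for Vcmax and Jmax are plain Arrhenius
    # over 10-40 degC; setting both Hd and dS switches on a peaked
    # (deactivating) response instead.
    Ea_Vcmax: float = 65330.0
    Hd_Vcmax: float | None = None
    dS_Vcmax: float | None = None
    Ea_Jmax: float = 43540.0
    Hd_Jmax: float | None = None
    dS_Jmax: float | None = None
    Ea_Rd: float = 46390.0
    Ea_Kc: float = 79430.0
    Ea_Ko: float = 36380.0
    Ea_GammaStar: float = 37830.0
    Ea_gm: float = 49600.0
    Hd_gm: float = 437400.0
    dS_gm: float = 1400.0

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "Rd25", "gm25", "Kc25", "Ko25",
                     "GammaStar25", "O", "tauA_inc", "tauA_dec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.Curv < 1.0):
            raise ValueError("Curv must lie in (0, 1)")
        if not (0.0 < self.AbsPAR <= 1.0):
            raise ValueError("AbsPAR must lie in (0, 1]")


@dataclass(frozen=True)
class StomatalParams:
    """Leuning stomatal-conductance parameters.

    ``gs = g0 + g1 A / [(Cs - Gamma)(1 + Ds/D0)]`` on a total (two-sided)
    water-vapour basis.  g0 is the nocturnal/minimum conductance
    (mol m-2 s-1), g1 a dimensionless slope, D0 the humidity-deficit
    sensitivity (kPa); stomatal opening/closing time constants in s.
    """

    g0: float = 0.02
    g1: float = 9.0
    D0: float = 1.5
    tauG_inc: float = 900.0
    tauG_dec: float = 450.0

    def __post_init__(self) -> None:
        for name in ("g0", "g1", "D0", "tauG_inc", "tauG_dec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EnergyParams:
    """Optical and thermal leaf properties for the energy balance.

    ksun converts incident PPFD (umol m-2 s-1) to shortwave irradiance
    (W m-2) assuming the PAR quantum-to-energy ratio 4.57 umol J-1 and a
    PAR fraction of 0.47 of total shortwave; k_heat is the areal heat
    capacity of the leaf (J m-2 K-1).
    """

    AbsShortwave: float = 0.5
    emissivity: float = 0.95
    k_heat: float = 280.0
    ksun: float = 1.0 / (4.57 * 0.47)

    def __post_init__(self) -> None:
        if not (0.0 < self.AbsShortwave <= 1.0):
            raise ValueError("AbsShortwave must lie in (0, 1]")
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError("emissivity must lie in (0, 1]")
        if self.k_heat <= 0 or self.ksun <= 0:
            raise ValueError("k_heat and ksun must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """Complete leaf parameterisation for a simulation."""

    photo: PhotoParams = field(default_factory=PhotoParams)
    stomatal: StomatalParams = field(default_factory=StomatalParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    name: str = "custom"

    def with_overrides(self, overrides: dict[str, Any]) -> "ParameterSet":
        """Return a copy with ``{"photo": {...}, "stomatal": {...}, ...}``
        style overrides applied; unknown keys raise."""
        blocks = {"photo": self.photo, "stomatal": self.stomatal, "energy": self.energy}
        new = {}
        for block_name, block_overrides in overrides.items():
            if block_name not in blocks:
                raise ValueError(f"unknown parameter block {block_name!r}")
            valid = {f.name for f in fields(blocks[block_name])}
            bad = set(block_overrides) - valid
            if bad:
                raise ValueError(f"unknown {block_name} parameter(s): {sorted(bad)}")
            new[block_name] = replace(blocks[block_name], **block_overrides)
        return replace(self, **new)


def _preset_dir():
    return resources.files("leafwind") / "presets"


def available_presets() -> list[str]:
    """Names of the parameter presets shipped with the package."""
    return sorted(
        p.name.removesuffix(".yaml")
        for p in _preset_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def load_preset(name: str) -> ParameterSet:
    """Load a shipped parameter preset (``tomato_greenhouse`` or
    ``wheat_field``) by name."""
    path = _preset_dir() / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ValueError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    valid_blocks = {"photo": PhotoParams, "stomatal": StomatalParams, "energy": EnergyParams}
    kwargs: dict[str, Any] = {}
    for block, cls in valid_blocks.items():
        block_raw = raw.get(block, {})
        valid = {f.name for f in fields(cls)}
        bad = set(block_raw) - valid
        if bad:
            raise ValueError(f"preset {name}: unknown {block} key(s) {sorted(bad)}")
        kwargs[block] = cls(**block_raw)
    extra = set(raw) - set(valid_blocks) - {"description"}
    if extra:
        raise ValueError(f"preset {name}: unknown top-level key(s) {sorted(extra)}")
    return ParameterSet(name=name, **kwargs)
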