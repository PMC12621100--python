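"""Coupled leaf gas-exchange core.

The model couples four sub-models at the scale of a single amphistomatous
leaf:

1. **FvCB photosynthesis** — net assimilation is the minimum of the
   Rubisco-limited rate Ac and the electron-transport-limited rate Aj (no
   smoothing between them, no triose-phosphate limitation); finite
   mesophyll conductance is included through the quadratic
   (non-rectangular-hyperbola) formulation, so each limitation-specific
   rate is the root of a quadratic consistent with the chloroplast CO2
   drawdown Cc = Ci - A/gm.
2. **Leuning stomatal conductance** — gs responds to assimilation, to the
   CO2 drawdown at the leaf surface (Cs - Gamma) and to the humidity
   deficit Ds *inside* the boundary layer.
3. **Transport** — Fick's-law drawdowns Ca -> Cs -> Ci -> Cc with the
   boundary-layer (1.37) and stomatal (1.6) water:CO2 factors;
   transpiration from the vapour mole-fraction gradient through the
   series stomatal + boundary-layer conductance; the leaf-surface deficit
   Ds = (ei - ea)(1 - gt/gb).
4. **Energy balance** — longwave exchange, shortwave absorption,
   convection and latent heat determine leaf temperature.

Assimilation, stomatal conductance and leaf temperature are state
variables: A and gs relax exponentially toward their instantaneous targets
with separate rise/fall time constants, and Tleaf integrates the net energy
flux divided by the leaf areal heat capacity.  Two solvers are provided:

* :func:`integrate_dynamic` — fixed-step time integration under arbitrary
  forcing, vectorised over a batch of (gbw, Ca) combinations;
* :func:`solve_steady_state` — nested Newton/bisection solution (outer
  scalar root on Tleaf closing the energy balance, inner damped fixed point
  on the A/gs/Ci algebraic loop), including an infinite-gb reference mode.

Conventions: gbw_one_sided is per leaf face; "total" conductances are
two-sided (x2, equal faces in parallel); gs is always total; CO2 mole
fractions in umol mol-1; vapour pressures in kPa; fluxes in W m-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .airphysics import (
    CP_MOLAR,
    F_HEAT_WATER,
    P_STANDARD_KPA,
    R_BL_CO2,
    R_ST_CO2,
    esat_kpa,
    latent_heat_molar,
)
from .params import ParameterSet, PhotoParams, arrhenius, peaked_arrhenius

__all__ = [
    "Forcing",
    "LeafState",
    "ConductanceSet",
    "FvcbResult",
    "fvcb_targets",
    "relax",
    "leuning_gs_target",
    "transport",
    "energy_fluxes",
    "conductance_set",
    "step_dynamic",
    "integrate_dynamic",
    "solve_steady_state",
]

SIGMA_SB = 5.670374419e-8  # Stefan-Boltzmann, W m-2 K-4


@dataclass(frozen=True)
class Forcing:
    """Ambient driver variables at one point/time.

    PPFD in umol m-2 s-1, temperatures in degC, ea (ambient vapour
    pressure) in kPa, Ca in umol mol-1, P in kPa.  Trefl is the radiative
    (reflected/background) temperature seen by the leaf; None means Tair.
    """

    PPFD: float
    Tair: float
    ea: float
    Ca: float
    Trefl: float | None = None
    P: float = P_STANDARD_KPA

    @property
    def trefl(self) -> float:
        return self.Tair if self.Trefl is None else self.Trefl


@dataclass
class LeafState:
    """Instantaneous leaf state plus derived algebraic variables."""

    A: float  # net assimilation, umol m-2 s-1 (dynamic state)
    gs: float  # total stomatal conductance to water, mol m-2 s-1 (state)
    Tleaf: float  # degC (state)
    A_star: float = np.nan  # steady-state assimilation target
    gs_star: float = np.nan
    Ac: float = np.nan
    Aj: float = np.nan
    Cs: float = np.nan  # leaf-surface CO2, umol mol-1
    Ci: float = np.nan  # intercellular CO2
    Cc: float = np.nan  # chloroplast CO2
    Gamma: float = np.nan  # CO2 compensation point incl. Rd
    E: float = np.nan  # transpiration, mol m-2 s-1
    Ds: float = np.nan  # leaf-surface vapour pressure deficit, kPa
    ei: float = np.nan  # intercellular (saturation) vapour pressure, kPa
    Hlw: float = np.nan
    Hsw: float = np.nan
    Hconv: float = np.nan
    Hlatent: float = np.nan
    net_flux: float = np.nan  # W m-2, energy-balance residual


@dataclass(frozen=True)
class ConductanceSet:
    """All conductances of one leaf, mole-fraction basis (mol m-2 s-1).

    ``gbw_total = 2 x gbw_one_sided`` (amphistomatous convention);
    ``gbc = gbw_total/1.37``; ``gsc = gsw/1.6``; ``gt_w`` is the series
    water conductance through stomata and boundary layer.
    """

    gbw_one_sided: float
    gsw: float
    gm: float
    P: float = P_STANDARD_KPA

    @property
    def gbw_total(self) -> float:
        return 2.0 * self.gbw_one_sided

    @property
    def gbh_total(self) -> float:
        return self.gbw_total / F_HEAT_WATER

    @property
    def gbc(self) -> float:
        return self.gbw_total / R_BL_CO2

    @property
    def gsc(self) -> float:
        return self.gsw / R_ST_CO2

    @property
    def gt_w(self) -> float:
        return 1.0 / (1.0 / self.gbw_total + 1.0 / self.gsw)


def conductance_set(gbw_one_sided: float, gsw: float, gm_mole_fraction: float,
                    P: float = P_STANDARD_KPA) -> ConductanceSet:
    """Assemble a :class:`ConductanceSet`; gm already on mole-fraction basis."""
    if gbw_one_sided <= 0 or gsw <= 0 or gm_mole_fraction <= 0:
        raise ValueError("conductances must be positive")
    return ConductanceSet(gbw_one_sided, gsw, gm_mole_fraction, P)


def gm_mole_fraction(photo: PhotoParams, Tleaf, P: float = P_STANDARD_KPA):
    """Mesophyll conductance at Tleaf on a mole-fraction basis
    (mol m-2 s-1), from the pressure-basis gm25 (umol m-2 s-1 Pa-1)."""
    T_K = np.asarray(Tleaf, dtype=float) + 273.15
    gm_pa = peaked_arrhenius(photo.gm25, photo.Ea_gm, photo.Hd_gm, photo.dS_gm, T_K)
    return gm_pa * P * 1000.0 * 1e-6


class FvcbResult(NamedTuple):
    A_star: np.ndarray | float
    Ac: np.ndarray | float
    Aj: np.ndarray | float
    Gamma: np.ndarray | float
    GammaStar: np.ndarray | float
    Rd: np.ndarray | float


def fvcb_targets(PPFD, Tleaf, Ci, photo: PhotoParams, P: float = P_STANDARD_KPA,
                 gm_infinite: bool = False) -> FvcbResult:
    """Steady-state FvCB assimilation target at given intercellular CO2.

    Temperature adjustment is internal: Kc, Ko, GammaStar, Rd follow
    Arrhenius and Vcmax, Jmax, gm peaked Arrhenius functions of Tleaf.  The
    potential electron-transport rate J is the lower root of the
    non-rectangular hyperbola in absorbed PAR with curvature ``Curv``; Ac
    and Aj are each the lower root of the quadratic coupling the
    biochemical demand to the mesophyll drawdown Cc = Ci - A/gm.  The
    target is min(Ac, Aj), unsmoothed; at PPFD = 0 it equals -Rd(Tleaf).

    All arguments broadcast; returns a NamedTuple of arrays/scalars.
    """
    PPFD = np.asarray(PPFD, dtype=float)
    Ci = np.asarray(Ci, dtype=float)
    if np.any(PPFD < 0):
        raise ValueError("PPFD must be non-negative")
    if np.any(Ci <= 0):
        raise ValueError("Ci must be positive")
    T_K = np.asarray(Tleaf, dtype=float) + 273.15

    if photo.Hd_Vcmax is not None and photo.dS_Vcmax is not None:
        Vcmax = peaked_arrhenius(photo.Vcmax25, photo.Ea_Vcmax,
                                 photo.Hd_Vcmax, photo.dS_Vcmax, T_K)
    else:
        Vcmax = arrhenius(photo.Vcmax25, photo.Ea_Vcmax, T_K)
    if photo.Hd_Jmax is not None and photo.dS_Jmax is not None:
        Jmax = peaked_arrhenius(photo.Jmax25, photo.Ea_Jmax,
                                photo.Hd_Jmax, photo.dS_Jmax, T_K)
    else:
        Jmax = arrhenius(photo.Jmax25, photo.Ea_Jmax, T_K)
    Rd = arrhenius(photo.Rd25, photo.Ea_Rd, T_K)
    Kc = arrhenius(photo.Kc25, photo.Ea_Kc, T_K)
    Ko = arrhenius(photo.Ko25, photo.Ea_Ko, T_K)
    Gs = arrhenius(photo.GammaStar25, photo.Ea_GammaStar, T_K)
    Km = Kc * (1.0 + photo.O / Ko)

    # potential electron transport (lower root of the light NRH)
    I2 = PPFD * photo.AbsPAR * (1.0 - photo.f_spectral) / 2.0
    s = I2 + Jmax
    J = (s - np.sqrt(s * s - 4.0 * photo.Curv * I2 * Jmax)) / (2.0 * photo.Curv)

    def limited(Vm, K):
        if gm_infinite:
            return Vm * (Ci - Gs) / (Ci + K) - Rd
        gm = gm_mole_fraction(photo, np.asarray(Tleaf, dtype=float), P)
        a = -1.0 / gm
        b = (Vm - Rd) / gm + Ci + K
        c = Rd * (Ci + K) - Vm * (Ci - Gs)
        disc = np.maximum(b * b - 4.0 * a * c, 0.0)
        return (-b + np.sqrt(disc)) / (2.0 * a)

    Ac = limited(Vcmax, Km)
    Aj = limited(J / 4.0, 2.0 * Gs)
    A_star = np.minimum(Ac, Aj)
    Gamma = (Gs * Vcmax + Rd * Km) / (Vcmax - Rd)

    if A_star.ndim == 0:
        return FvcbResult(float(A_star), float(Ac), float(Aj), float(Gamma),
                          float(Gs), float(Rd))
    return FvcbResult(A_star, Ac, Aj, Gamma, np.broadcast_to(Gs, A_star.shape),
                      np.broadcast_to(Rd, A_star.shape))


def relax(value, target, tau_inc: float, tau_dec: float, dt: float):
    """Exponential relaxation of a state toward its target over one step.

    The time constant is chosen by the sign of (target - value): ``tau_inc``
    for a rise, ``tau_dec`` for a fall.  The update is the exact solution of
    ``dx/dt = (x* - x)/tau`` against a frozen target:
    ``x + (x* - x)(1 - exp(-dt/tau))``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau_inc <= 0 or tau_dec <= 0:
        raise ValueError("time constants must be positive")
    value = np.asarray(value, dtype=float)
    target = np.asarray(target, dtype=float)
    tau = np.where(target >= value, tau_inc, tau_dec)
    out = value + (target - value) * (1.0 - np.exp(-dt / tau))
    return float(out) if out.ndim == 0 else out


def leuning_gs_target(A, Cs, Ds, Gamma, stomatal, warn_degenerate: bool = True):
    """Steady-state Leuning stomatal conductance target (total water basis).

    ``gs* = g0 + g1 A / [(Cs - Gamma)(1 + Ds/D0)]``, clamped at g0 when
    A <= 0 and when the surface CO2 falls to the compensation point
    (a degenerate state the model flags rather than extrapolates).
    """
    A = np.asarray(A, dtype=float)
    Cs = np.asarray(Cs, dtype=float)
    Ds = np.asarray(Ds, dtype=float)
    if np.any(np.asarray(Ds) < 0):
        raise ValueError("Ds must be non-negative")
    degenerate = Cs <= np.asarray(Gamma)
    if warn_degenerate and np.any(degenerate):
        warnings.warn("Cs <= Gamma: stomatal target pinned at g0", stacklevel=2)
    denom = np.where(degenerate, 1.0, (Cs - Gamma) * (1.0 + Ds / stomatal.D0))
    gs = stomatal.g0 + stomatal.g1 * A / denom
    out = np.where(degenerate | (A < 0), stomatal.g0, np.maximum(gs, stomatal.g0))
    return float(out) if out.ndim == 0 else out


def transport(A, gsw, gbw_total, gm, Ca, Tleaf, ea, P: float = P_STANDARD_KPA):
    """Fick's-law CO2 drawdowns and water-vapour fluxes.

    CO2 path (umol mol-1): ``Cs = Ca - 1.37 A/gbw_total``,
    ``Ci = Cs - 1.6 A/gsw``, ``Cc = Ci - A/gm`` (gm on mole-fraction
    basis; pass ``np.inf`` to skip the mesophyll drawdown).  Water path:
    ``ei = esat(Tleaf)``, ``E = gt (ei - ea)/P`` with the series water
    conductance gt, and the leaf-surface deficit
    ``Ds = (ei - ea)(1 - gt/gbw_total)`` (>= 0).

    Returns ``(Cs, Ci, Cc, E, Ds)``.
    """
    gsw = np.asarray(gsw, dtype=float)
    gbw_total = np.asarray(gbw_total, dtype=float)
    if np.any(gsw <= 0) or np.any(gbw_total <= 0):
        raise ValueError("conductances must be positive")
    A = np.asarray(A, dtype=float)
    Cs = np.asarray(Ca, dtype=float) - R_BL_CO2 * A / gbw_total
    Ci = Cs - R_ST_CO2 * A / gsw
    Cc = Ci - A / np.asarray(gm, dtype=float)
    ei = esat_kpa(Tleaf)
    gt = 1.0 / (1.0 / gbw_total + 1.0 / gsw)
    E = gt * (ei - ea) / P
    Ds = np.maximum((ei - ea) * (1.0 - gt / gbw_total), 0.0)
    return Cs, Ci, Cc, E, Ds


def energy_fluxes(Tleaf, forcing: Forcing, energy, gbh_total, E):
    """Component energy fluxes (W m-2) of a flat leaf.

    ``Hsw = AbsShortwave ksun PPFD`` (incident on the upper face);
    ``Hlw = 2 emissivity sigma (Trefl_K^4 - Tleaf_K^4)`` (both faces
    exchange with a background at the reflected temperature);
    ``Hconv = cp gbh_total (Tleaf - Tair)``; ``Hlatent = lambda E``.
    Returns ``(Hlw, Hsw, Hconv, Hlatent, net)`` with
    ``net = Hlw + Hsw - Hconv - Hlatent``.
    """
    Tleaf = np.asarray(Tleaf, dtype=float)
    Tl_K = Tleaf + 273.15
    Tr_K = np.asarray(forcing.trefl, dtype=float) + 273.15
    Hsw = energy.AbsShortwave * energy.ksun * np.asarray(forcing.PPFD, dtype=float)
    Hlw = 2.0 * energy.emissivity * SIGMA_SB * (Tr_K**4 - Tl_K**4)
    Hconv = CP_MOLAR * np.asarray(gbh_total, dtype=float) * (Tleaf - forcing.Tair)
    Hlat = latent_heat_molar(Tleaf) * np.asarray(E, dtype=float)
    net = Hlw + Hsw - Hconv - Hlat
    return Hlw, Hsw, Hconv, Hlat, net


# ---------------------------------------------------------------------------
# dynamic solver
# ---------------------------------------------------------------------------

def _targets_and_fluxes(A, gs, Tleaf, PPFD, Tair, ea, Ca, Trefl, P,
                        gbw_total, gbh_total, params: ParameterSet):
    """Algebraic closure at the instantaneous state (vectorised)."""
    photo, stomatal, energy = params.photo, params.stomatal, params.energy
    gm = gm_mole_fraction(photo, Tleaf, P)
    Cs = Ca - R_BL_CO2 * A / gbw_total
    Ci = np.maximum(Cs - R_ST_CO2 * A / gs, 1.0)
    ei = esat_kpa(Tleaf)
    gt = 1.0 / (1.0 / gbw_total + 1.0 / gs)
    E = gt * (ei - ea) / P
    Ds = np.maximum((ei - ea) * (1.0 - gt / gbw_total), 0.0)

    fv = fvcb_targets(PPFD, Tleaf, Ci, photo, P)
    gs_star = leuning_gs_target(A, Cs, Ds, fv.Gamma, stomatal, warn_degenerate=False)

    Tl_K = Tleaf + 273.15
    Tr_K = Trefl + 273.15
    Hsw = energy.AbsShortwave * energy.ksun * PPFD
    Hlw = 2.0 * energy.emissivity * SIGMA_SB * (Tr_K**4 - Tl_K**4)
    Hconv = CP_MOLAR * gbh_total * (Tleaf - Tair)
    Hlat = latent_heat_molar(Tleaf) * E
    net = Hlw + Hsw - Hconv - Hlat
    return fv, gs_star, Cs, Ci, E, Ds, ei, (Hlw, Hsw, Hconv, Hlat, net)


def step_dynamic(state: LeafState, forcing: Forcing, params: ParameterSet,
                 gbw_one_sided: float, dt: float) -> LeafState:
    """Advance a single leaf state by one time step ``dt`` (s).

    A and gs relax exponentially toward their instantaneous targets (exact
    update for a frozen target); Tleaf integrates the net energy flux with
    an explicit Euler step (stable for dt well below the leaf thermal time
    constant k_heat / (d net/d Tleaf), a few tens of seconds here).
    """
    gbw_total = 2.0 * gbw_one_sided
    gbh_total = gbw_total / F_HEAT_WATER
    fv, gs_star, Cs, Ci, E, Ds, ei, fluxes = _targets_and_fluxes(
        state.A, state.gs, state.Tleaf, forcing.PPFD, forcing.Tair, forcing.ea,
        forcing.Ca, forcing.trefl, forcing.P, gbw_total, gbh_total, params)
    Hlw, Hsw, Hconv, Hlat, net = fluxes
    photo, stomatal = params.photo, params.stomatal
    A_new = relax(state.A, fv.A_star, photo.tauA_inc, photo.tauA_dec, dt)
    gs_new = relax(state.gs, gs_star, stomatal.tauG_inc, stomatal.tauG_dec, dt)
    T_new = state.Tleaf + net / params.energy.k_heat * dt
    gm = gm_mole_fraction(photo, state.Tleaf, forcing.P)
    return LeafState(
        A=float(A_new), gs=float(gs_new), Tleaf=float(T_new),
        A_star=float(fv.A_star), gs_star=float(gs_star), Ac=float(fv.Ac),
        Aj=float(fv.Aj), Cs=float(Cs), Ci=float(Ci),
        Cc=float(Ci - state.A / gm), Gamma=float(fv.Gamma), E=float(E),
        Ds=float(Ds), ei=float(ei), Hlw=float(Hlw), Hsw=float(Hsw),
        Hconv=float(Hconv), Hlatent=float(Hlat), net_flux=float(net))


def integrate_dynamic(
    forcing: pd.DataFrame,
    params: ParameterSet,
    gbw_one_sided,
    Ca=None,
    dt: float = 2.0,
    record_every: float = 60.0,
    initial: tuple[float, float, float] | None = None,
    P: float = P_STANDARD_KPA,
) -> pd.DataFrame:
    """Integrate the coupled leaf model over a forcing time series.

    Parameters
    ----------
    forcing : DataFrame with columns ``time`` (s), ``PPFD``, ``Tair``,
        ``ea``, ``Ca`` and optionally ``Trefl``; values are linearly
        interpolated onto the integration grid.
    gbw_one_sided : scalar or 1-D array of one-sided boundary-layer water
        conductances; an array runs the whole batch simultaneously.
    Ca : optional scalar or array overriding the forcing CO2 column
        (broadcast against ``gbw_one_sided`` to define the batch).
    dt : integration step, s.
    record_every : sampling interval of the output table, s.
    initial : optional (A, gs, Tleaf) start state; defaults to the dark
        state (A = -Rd, gs = g0, Tleaf = Tair) at t = 0.

    Returns
    -------
    Long-format DataFrame with one row per recorded time per batch member:
    columns ``time, gbw, Ca_air, PPFD, A, gs, Tleaf, Cs, Ci, Ds, E,
    A_star, gs_star, net_flux``.
    """
    if dt <= 0 or record_every <= 0:
        raise ValueError("dt and record_every must be positive")
    required = {"time", "PPFD", "Tair", "ea", "Ca"}
    missing = required - set(forcing.columns)
    if missing:
        raise ValueError(f"forcing is missing column(s): {sorted(missing)}")

    gbw = np.atleast_1d(np.asarray(gbw_one_sided, dtype=float))
    if Ca is None:
        Ca_batch = None
    else:
        gbw, Ca_batch = np.broadcast_arrays(gbw, np.atleast_1d(np.asarray(Ca, dtype=float)))
        gbw, Ca_batch = gbw.astype(float).ravel(), Ca_batch.astype(float).ravel()
    if np.any(gbw <= 0):
        raise ValueError("gbw_one_sided must be positive")
    B = gbw.size
    gbw_total = 2.0 * gbw
    gbh_total = gbw_total / F_HEAT_WATER

    t_f = forcing["time"].to_numpy(dtype=float)
    t = np.arange(t_f[0], t_f[-1] + 0.5 * dt, dt)
    n = t.size
    cols = {c: np.interp(t, t_f, forcing[c].to_numpy(dtype=float))
            for c in ("PPFD", "Tair", "ea", "Ca")}
    if "Trefl" in forcing.columns:
        cols["Trefl"] = np.interp(t, t_f, forcing["Trefl"].to_numpy(dtype=float))
    else:
        cols["Trefl"] = cols["Tair"]
    if Ca_batch is not None:
        Ca_t = np.broadcast_to(Ca_batch, (n, B))
    else:
        Ca_t = np.broadcast_to(cols["Ca"][:, None], (n, B))

    photo, stomatal, energy = params.photo, params.stomatal, params.energy
    if initial is None:
        Rd0 = arrhenius(photo.Rd25, photo.Ea_Rd, cols["Tair"][0] + 273.15)
        A = np.full(B, -float(Rd0))
        gs = np.full(B, stomatal.g0)
        Tleaf = np.full(B, cols["Tair"][0])
    else:
        A = np.full(B, float(initial[0]))
        gs = np.full(B, float(initial[1]))
        Tleaf = np.full(B, float(initial[2]))

    rec_stride = max(int(round(record_every / dt)), 1)
    records = []
    for i in range(n):
        fv, gs_star, Cs, Ci, E, Ds, ei, fluxes = _targets_and_fluxes(
            A, gs, Tleaf, cols["PPFD"][i], cols["Tair"][i], cols["ea"][i],
            Ca_t[i], cols["Trefl"][i], P, gbw_total, gbh_total, params)
        net = fluxes[4]
        if i % rec_stride == 0 or i == n - 1:
            records.append((t[i], cols["PPFD"][i], A.copy(), gs.copy(),
                            Tleaf.copy(), np.asarray(Cs).copy(),
                            np.asarray(Ci).copy(), np.asarray(Ds).copy(),
                            np.asarray(E).copy(), np.asarray(fv.A_star).copy(),
                            np.asarray(gs_star).copy(), np.asarray(net).copy(),
                            Ca_t[i]))
        if i == n - 1:
            break
        tau_A = np.where(fv.A_star >= A, photo.tauA_inc, photo.tauA_dec)
        tau_g = np.where(gs_star >= gs, stomatal.tauG_inc, stomatal.tauG_dec)
        A = A + (fv.A_star - A) * (1.0 - np.exp(-dt / tau_A))
        gs = gs + (gs_star - gs) * (1.0 - np.exp(-dt / tau_g))
        Tleaf = Tleaf + net / energy.k_heat * dt
        if not np.all(np.isfinite(Tleaf)):
            raise RuntimeError(f"dynamic solver diverged at t={t[i]:.0f} s")

    batch_idx = np.arange(B)
    frames = []
    for (ti, ppfd, A_r, gs_r, Tl, Cs_r, Ci_r, Ds_r, E_r, Ast, gst, net_r, Ca_r) in records:
        frames.append(pd.DataFrame({
            "time": ti, "batch": batch_idx, "gbw": gbw,
            "Ca_air": np.broadcast_to(Ca_r, (B,)),
            "PPFD": ppfd, "A": A_r, "gs": gs_r, "Tleaf": Tl,
            "Cs": np.broadcast_to(Cs_r, (B,)), "Ci": np.broadcast_to(Ci_r, (B,)),
            "Ds": np.broadcast_to(Ds_r, (B,)), "E": np.broadcast_to(E_r, (B,)),
            "A_star": np.broadcast_to(Ast, (B,)),
            "gs_star": np.broadcast_to(gst, (B,)),
            "net_flux": np.broadcast_to(net_r, (B,)),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# steady-state solver
# ---------------------------------------------------------------------------

def _inner_algebraic(Tleaf: float, forcing: Forcing, params: ParameterSet,
                     gbw_one_sided: float | None, tol_ci: float = 1e-6,
                     max_iter: int = 400, damping: float = 0.5):
    """Damped fixed point on the (A, gs, Ci) loop at fixed leaf temperature.

    ``gbw_one_sided=None`` selects the infinite-gb mode: Cs = Ca,
    Ds = ei - ea, and no boundary-layer drawdowns (explicit code path, no
    infinities in the arithmetic).
    """
    photo, stomatal = params.photo, params.stomatal
    P, Ca, ea = forcing.P, forcing.Ca, forcing.ea
    infinite = gbw_one_sided is None
    if not infinite:
        gbw_total = 2.0 * gbw_one_sided
    gm = float(gm_mole_fraction(photo, Tleaf, P))
    ei = esat_kpa(Tleaf)

    A = 10.0
    gs = max(stomatal.g0, 0.15)
    Ci_prev = np.inf
    for _ in range(max_iter):
        if infinite:
            Cs = Ca
            gt = gs
            Ds = max(ei - ea, 0.0)
        else:
            Cs = Ca - R_BL_CO2 * A / gbw_total
            gt = 1.0 / (1.0 / gbw_total + 1.0 / gs)
            Ds = max((ei - ea) * (1.0 - gt / gbw_total), 0.0)
        Ci = max(Cs - R_ST_CO2 * A / gs, 1.0)
        fv = fvcb_targets(forcing.PPFD, Tleaf, Ci, photo, P)
        gs_new = leuning_gs_target(fv.A_star, Cs, Ds, fv.Gamma, stomatal,
                                   warn_degenerate=False)
        A = A + damping * (fv.A_star - A)
        gs = gs + damping * (gs_new - gs)
        if abs(Ci - Ci_prev) < tol_ci and abs(fv.A_star - A) < 1e-8:
            break
        Ci_prev = Ci
    else:
        raise RuntimeError(
            f"algebraic loop did not converge at Tleaf={Tleaf:.2f} "
            f"(PPFD={forcing.PPFD}, Ca={Ca})")
    E = gt * (ei - ea) / P
    return fv, gs, Cs, Ci, E, Ds, ei, gm


def solve_steady_state(
    forcing: Forcing,
    params: ParameterSet,
    gbw_one_sided: float | None,
    tol_tleaf: float = 1e-4,
    tleaf_bracket: tuple[float, float] = (-20.0, 30.0),
) -> LeafState:
    """Steady-state leaf solution by a nested iterative procedure.

    Outer level: scalar Newton/Brent root on Tleaf closing the energy
    balance (|net flux| -> 0); inner level: damped fixed point on the
    (A, gs, Ci) algebraic loop at the trial temperature.  With
    ``gbw_one_sided=None`` the boundary layer is removed (infinite-gb
    reference): convection then pins Tleaf at Tair analytically and the
    leaf-surface state equals the canopy air state.

    Returns a fully populated :class:`LeafState`; at convergence the energy
    residual is below ~1e-3 W m-2 and Fick consistency holds to the inner
    tolerance.
    """
    infinite = gbw_one_sided is None
    if not infinite and gbw_one_sided <= 0:
        raise ValueError("gbw_one_sided must be positive (or None for infinite)")

    energy = params.energy

    if infinite:
        Tleaf = forcing.Tair
        fv, gs, Cs, Ci, E, Ds, ei, gm = _inner_algebraic(Tleaf, forcing, params, None)
        Hsw = energy.AbsShortwave * energy.ksun * forcing.PPFD
        Hlw = 2.0 * energy.emissivity * SIGMA_SB * (
            (forcing.trefl + 273.15) ** 4 - (Tleaf + 273.15) ** 4)
        Hlat = latent_heat_molar(Tleaf) * E
        # convection absorbs whatever closes the balance in the infinite limit
        Hconv = Hlw + Hsw - Hlat
        A = fv.A_star
        return LeafState(
            A=A, gs=gs, Tleaf=Tleaf, A_star=fv.A_star, gs_star=gs, Ac=fv.Ac,
            Aj=fv.Aj, Cs=Cs, Ci=Ci, Cc=Ci - A / gm, Gamma=fv.Gamma, E=E,
            Ds=Ds, ei=ei, Hlw=Hlw, Hsw=Hsw, Hconv=Hconv, Hlatent=Hlat,
            net_flux=0.0)

    gbh_total = 2.0 * gbw_one_sided / F_HEAT_WATER

    def residual(Tleaf: float) -> float:
        fv, gs, Cs, Ci, E, Ds, ei, gm = _inner_algebraic(
            Tleaf, forcing, params, gbw_one_sided)
        _, _, _, _, net = energy_fluxes(Tleaf, forcing, energy, gbh_total, E)
        return float(net)

    lo = forcing.Tair + tleaf_bracket[0]
    hi = forcing.Tair + tleaf_bracket[1]
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            f"no energy-balance root in Tleaf bracket [{lo}, {hi}] "
            f"(residuals {r_lo:.1f}, {r_hi:.1f} W m-2)")
    Tleaf = brentq(residual, lo, hi, xtol=tol_tleaf)

    fv, gs, Cs, Ci, E, Ds, ei, gm = _inner_algebraic(Tleaf, forcing, params, gbw_one_sided)
    Hlw, Hsw, Hconv, Hlat, net = energy_fluxes(Tleaf, forcing, energy, gbh_total, E)
    A = fv.A_star
    return LeafState(
        A=A, gs=gs, Tleaf=Tleaf, A_star=fv.A_star, gs_star=gs, Ac=fv.Ac,
        Aj=fv.Aj, Cs=Cs, Ci=Ci, Cc=Ci - A / gm, Gamma=fv.Gamma, E=E, Ds=Ds,
        ei=ei, Hlw=float(Hlw), Hsw=float(Hsw), Hconv=float(Hconv),
        Hlatent=float(Hlat), net_flux=float(net))
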