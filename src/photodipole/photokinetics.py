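"""Light protocol, cis-isomer kinetics, and the circuit coefficient builder.

The photoswitch population is modelled as a two-state (trans/cis) system with
first-order kinetics: a photo-driven forward rate during illumination and a
thermal back rate at all times,

    dx/dt = (1 - x)/tau_on - x/tau_off    (light on)
    dx/dt = -x/tau_off                    (light off)

where ``x`` is the cis fraction.  This is the minimal model producing
step-like waveforms whose rise and fall track the cis-isomer concentration.
Both branches have piecewise single-exponential closed forms, so the
occupancy and its exact derivative are returned analytically — the circuit
ODE explicitly contains dC_m/dt and dV_s/dt and must never rely on numeric
differentiation.

The membrane perturbations ride on the cis fraction:

    C_m(t) = cm0 * (1 + dcm_rel * x_C(t))
    V_s(t) = vs0 + dvs * vs_scale * x_S(t)

with independent (tau_on, tau_off) pairs for the capacitive (``x_C``) and
dipolar (``x_S``) pathways, and ``vs_scale`` the field-strength multiplier
supplied by :mod:`photodipole.dipole_mapping`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .membrane_model import CircuitCoefficients, MembraneParams

__all__ = [
    "LightProtocol",
    "PhotoswitchParams",
    "CisOccupancy",
    "cis_occupancy",
    "build_coefficients",
]


@dataclass(frozen=True)
class LightProtocol:
    """A single rectangular light pulse.

    ``wavelength`` and ``irradiance`` are carried as metadata only; the
    kinetic rates are not coupled to intensity (a single intensity is
    simulated).
    """

    t_on: float  # ms
    duration: float  # ms
    wavelength: float = 470.0  # nm
    irradiance: float = 50.0  # mW/mm²

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_on) and math.isfinite(self.duration)):
            raise ValueError("LightProtocol times must be finite")
        if self.duration <= 0:
            raise ValueError(f"LightProtocol.duration must be > 0 ms, got {self.duration}")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration

    def require_baseline(self, window_start: float, baseline: float = 50.0) -> None:
        """Raise unless at least ``baseline`` ms of pre-pulse time is covered."""
        if self.t_on - window_start < baseline:
            raise ValueError(
                f"pulse onset {self.t_on} ms leaves less than {baseline} ms of "
                f"baseline after window start {window_start} ms"
            )


@dataclass(frozen=True)
class PhotoswitchParams:
    """Light-coupled perturbation amplitudes and kinetics.

    Parameters
    ----------
    dcm_rel : float
        Signed fractional capacitance change at full cis occupancy
        (dimensionless; -0.15 means a 15 % drop).
    dvs : float
        Signed surface-potential step at full cis occupancy, mV.
    tau_on_c, tau_off_c : float
        Rise/decay time constants of the capacitive pathway, ms.
    tau_on_s, tau_off_s : float
        Rise/decay time constants of the dipolar (surface-potential) pathway, ms.
    """

    dcm_rel: float
    dvs: float
    tau_on_c: float
    tau_off_c: float
    tau_on_s: float
    tau_off_s: float

    def __post_init__(self) -> None:
        for name in ("tau_on_c", "tau_off_c", "tau_on_s", "tau_off_s"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"PhotoswitchParams.{name} must be > 0 ms, got {val!r}")
        if not math.isfinite(self.dcm_rel) or 1.0 + self.dcm_rel <= 0:
            raise ValueError(
                f"PhotoswitchParams.dcm_rel must satisfy 1 + dcm_rel > 0, got {self.dcm_rel!r}"
            )
        if not math.isfinite(self.dvs):
            raise ValueError("PhotoswitchParams.dvs must be finite")


@dataclass(frozen=True)
class CisOccupancy:
    """Cis fraction ``x(t)`` in [0, 1] and its exact analytic derivative."""

    x_of_t: Callable[[np.ndarray | float], np.ndarray | float]
    dx_dt: Callable[[np.ndarray | float], np.ndarray | float]


def cis_occupancy(protocol: LightProtocol, tau_on: float, tau_off: float) -> CisOccupancy:
    """Closed-form cis fraction for a rectangular pulse.

    During the pulse the occupancy relaxes toward the photo-stationary value
    ``x* = tau_off / (tau_on + tau_off)`` with effective time constant
    ``tau_eff = tau_on*tau_off / (tau_on + tau_off)``; after the pulse it
    decays thermally with ``tau_off``.  The dark state before the pulse is
    pure trans (x = 0).
    """
    if tau_on <= 0 or tau_off <= 0:
        raise ValueError("time constants must be > 0 ms")
    t_on, t_off = protocol.t_on, protocol.t_off
    x_star = tau_off / (tau_on + tau_off)
    tau_eff = tau_on * tau_off / (tau_on + tau_off)
    x_end = x_star * (1.0 - math.exp(-protocol.duration / tau_eff))

    def x_of_t(t):
        if np.ndim(t) == 0:  # scalar fast path for the ODE right-hand side
            t = float(t)
            if t < t_on:
                return 0.0
            if t < t_off:
                return x_star * (1.0 - math.exp(-(t - t_on) / tau_eff))
            return x_end * math.exp(-(t - t_off) / tau_off)
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        during = (t >= t_on) & (t < t_off)
        after = t >= t_off
        out[during] = x_star * (1.0 - np.exp(-(t[during] - t_on) / tau_eff))
        out[after] = x_end * np.exp(-(t[after] - t_off) / tau_off)
        return out

    def dx_dt(t):
        if np.ndim(t) == 0:
            t = float(t)
            if t < t_on:
                return 0.0
            if t < t_off:
                return (x_star / tau_eff) * math.exp(-(t - t_on) / tau_eff)
            return -(x_end / tau_off) * math.exp(-(t - t_off) / tau_off)
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        during = (t >= t_on) & (t < t_off)
        after = t >= t_off
        out[during] = (x_star / tau_eff) * np.exp(-(t[during] - t_on) / tau_eff)
        out[after] = -(x_end / tau_off) * np.exp(-(t[after] - t_off) / tau_off)
        return out

    return CisOccupancy(x_of_t=x_of_t, dx_dt=dx_dt)


def build_coefficients(
    mem: MembraneParams,
    ps: PhotoswitchParams,
    protocol: LightProtocol,
    vs_scale: float = 1.0,
) -> CircuitCoefficients:
    """Assemble ``C_m(t)``, ``V_s(t)`` and their derivatives from the kinetics.

    ``vs_scale`` is the dimensionless field-strength multiplier applied to the
    surface-potential amplitude (1 disables scaling); it must be >= 0.
    """
    if not (math.isfinite(vs_scale) and vs_scale >= 0):
        raise ValueError(f"vs_scale must be >= 0, got {vs_scale!r}")
    occ_c = cis_occupancy(protocol, ps.tau_on_c, ps.tau_off_c)
    occ_s = cis_occupancy(protocol, ps.tau_on_s, ps.tau_off_s)
    # x in [0, 1] and 1 + dcm_rel > 0 together keep C_m(t) positive
    cm_min = mem.cm0 * min(1.0, 1.0 + ps.dcm_rel)
    if cm_min <= 0:
        raise ValueError("C_m(t) would become non-positive with these parameters")
    dvs_eff = ps.dvs * vs_scale

    def cm_of_t(t):
        return mem.cm0 * (1.0 + ps.dcm_rel * occ_c.x_of_t(t))

    def dcm_dt(t):
        return mem.cm0 * ps.dcm_rel * occ_c.dx_dt(t)

    def vs_of_t(t):
        return mem.vs0 + dvs_eff * occ_s.x_of_t(t)

    def dvs_dt(t):
        return dvs_eff * occ_s.dx_dt(t)

    return CircuitCoefficients(
        cm_of_t=cm_of_t,
        dcm_dt=dcm_dt,
        vs_of_t=vs_of_t,
        dvs_dt=dvs_dt,
        breakpoints=(protocol.t_on, protocol.t_off),
        min_timescale=min(ps.tau_on_c, ps.tau_off_c, ps.tau_on_s, ps.tau_off_s),
    )
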