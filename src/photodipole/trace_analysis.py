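"""Current-clamp trace metrics, amplitude-vs-V_r regression, and model fitting.

Metric conventions (all baseline-relative, so metrics are invariant to adding
a constant to the whole trace):

* baseline — mean V_m over the 50 ms immediately before pulse onset;
* peak_deflection — signed extremum of V_m − baseline of largest magnitude in
  the peak window [t_on, t_off + 5 ms]; hyperpolarization is negative.  The
  window extends 5 ms past pulse offset because the rise kinetics can delay
  the extremum slightly beyond the pulse;
* rebound_peak — signed maximum of V_m − baseline in (t_off, t_off + 200 ms],
  capturing the depolarization rebound after the pulse;
* plateau — mean of V_m − baseline over the last 50 ms of the rebound window.

The inverse problem (recovering photoswitch parameters from a recorded trace)
is solved by bounded nonlinear least squares on the simulated membrane
potential, with a small multi-start to reduce the risk of local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .membrane_model import MembraneParams, Trace, integrate_rk4
from .photokinetics import LightProtocol, PhotoswitchParams, build_coefficients

__all__ = [
    "TraceMetrics",
    "RegressionResult",
    "FitDiagnostics",
    "compute_metrics",
    "amplitude_vs_vr_regression",
    "fit_model",
    "FIT_PARAMETER_NAMES",
]

#: photoswitch parameters that fit_model may treat as free
FIT_PARAMETER_NAMES = (
    "dcm_rel",
    "dvs",
    "tau_on_c",
    "tau_off_c",
    "tau_on_s",
    "tau_off_s",
)

_FIT_BOUNDS = {
    "dcm_rel": (-0.95, 5.0),
    "dvs": (-100.0, 100.0),
    "tau_on_c": (0.05, 1e4),
    "tau_off_c": (0.05, 1e4),
    "tau_on_s": (0.05, 1e4),
    "tau_off_s": (0.05, 1e4),
}


@dataclass(frozen=True)
class TraceMetrics:
    """Baseline-relative summary metrics of a light-stimulation trace (mV / ms)."""

    baseline: float
    peak_deflection: float
    time_to_peak: float
    rebound_peak: float
    plateau: float

    def __post_init__(self) -> None:
        for name in ("baseline", "peak_deflection", "time_to_peak", "rebound_peak", "plateau"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"TraceMetrics.{name} is non-finite")


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares of peak deflection on resting potential."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class FitDiagnostics:
    """Convergence report of :func:`fit_model`."""

    converged: bool
    residual_norm: float  # sqrt(sum of squared residuals), mV
    n_starts: int
    message: str


def compute_metrics(
    trace: Trace,
    protocol: LightProtocol,
    peak_pad: float = 5.0,
    baseline_window: float = 50.0,
    rebound_window: float = 200.0,
    plateau_window: float = 50.0,
) -> TraceMetrics:
    """Quantify a light-stimulation trace (see module docstring for windows)."""
    t, v = trace.t, trace.v
    t_on, t_off = protocol.t_on, protocol.t_off
    if t[0] > t_on - baseline_window + 1e-9:
        raise ValueError(
            f"trace must cover {baseline_window} ms before pulse onset "
            f"(starts at {t[0]} ms, onset {t_on} ms)"
        )
    if t[-1] < t_off + rebound_window - 1e-9:
        raise ValueError(
            f"trace must cover {rebound_window} ms after pulse offset "
            f"(ends at {t[-1]} ms, offset {t_off} ms)"
        )

    base_mask = (t >= t_on - baseline_window) & (t < t_on)
    baseline = float(np.mean(v[base_mask]))
    dv = v - baseline

    peak_mask = (t >= t_on) & (t <= t_off + peak_pad)
    i_peak_rel = int(np.argmax(np.abs(dv[peak_mask])))
    i_peak = np.flatnonzero(peak_mask)[i_peak_rel]
    peak_deflection = float(dv[i_peak])
    time_to_peak = float(t[i_peak] - t_on)

    rebound_mask = (t > t_off) & (t <= t_off + rebound_window)
    rebound_peak = float(np.max(dv[rebound_mask]))

    plat_mask = (t > t_off + rebound_window - plateau_window) & (t <= t_off + rebound_window)
    plateau = float(np.mean(dv[plat_mask]))

    return TraceMetrics(
        baseline=baseline,
        peak_deflection=peak_deflection,
        time_to_peak=time_to_peak,
        rebound_peak=rebound_peak,
        plateau=plateau,
    )


def amplitude_vs_vr_regression(
    points: Iterable[tuple[float, float]],
) -> RegressionResult:
    """OLS of peak light-evoked deflection (mV) on resting potential (mV)."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (vr, peak_deflection) points")
    vr, amp = pts[:, 0], pts[:, 1]
    if np.ptp(vr) == 0:
        raise ValueError("degenerate design: all vr values are equal")
    res = stats.linregress(vr, amp)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def _simulate_on_grid(
    trace: Trace,
    protocol: LightProtocol,
    mem: MembraneParams,
    ps: PhotoswitchParams,
    vs_scale: float,
) -> np.ndarray:
    coeffs = build_coefficients(mem, ps, protocol, vs_scale=vs_scale)
    sim = integrate_rk4(coeffs, mem, (trace.t[0], trace.t[-1]), trace.rate)
    return sim.v


def fit_model(
    trace: Trace,
    protocol: LightProtocol,
    mem: MembraneParams,
    init: PhotoswitchParams,
    free: Sequence[str] = ("dcm_rel", "dvs"),
    vs_scale: float = 1.0,
    n_starts: int = 3,
    jitter: float = 0.3,
    seed: int = 0,
) -> tuple[PhotoswitchParams, FitDiagnostics]:
    """Recover photoswitch parameters from a membrane-potential trace.

    Bounded nonlinear least squares (trust-region reflective) minimizing the
    residual between ``trace`` and the simulated V_m on the same grid.  Free
    parameters are named in ``free`` (a subset of the photoswitch amplitudes
    and time constants); the remaining parameters stay at ``init``.  A small
    multi-start — ``init`` plus ``n_starts - 1`` multiplicatively jittered
    copies, seeded by ``seed`` — guards against local minima.

    Non-convergence is reported through :class:`FitDiagnostics`, never raised.
    """
    free = tuple(free)
    unknown = set(free) - set(FIT_PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if not free:
        raise ValueError("free parameter set is empty")

    lo = np.array([_FIT_BOUNDS[name][0] for name in free])
    hi = np.array([_FIT_BOUNDS[name][1] for name in free])
    x0 = np.array([getattr(init, name) for name in free], dtype=float)

    def make_params(x: np.ndarray) -> PhotoswitchParams:
        return replace(init, **{name: float(val) for name, val in zip(free, x)})

    def residuals(x: np.ndarray) -> np.ndarray:
        return _simulate_on_grid(trace, protocol, mem, make_params(x), vs_scale) - trace.v

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=x0.shape)
        # additive jitter where the initial guess is at zero
        shift = rng.uniform(-jitter, jitter, size=x0.shape) * (x0 == 0)
        starts.append(np.clip(x0 * factors + shift, lo, hi))

    best = None
    messages = []
    for start in starts:
        try:
            sol = optimize.least_squares(
                residuals, start, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
            )
        except Exception as exc:  # solver blow-up on a bad start is not fatal
            messages.append(str(exc))
            continue
        messages.append(sol.message)
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return init, FitDiagnostics(
            converged=False,
            residual_norm=float(np.linalg.norm(residuals(x0))),
            n_starts=len(starts),
            message="; ".join(messages) or "all starts failed",
        )

    fitted = make_params(best.x)
    return fitted, FitDiagnostics(
        converged=bool(best.success),
        residual_norm=float(math.sqrt(2.0 * best.cost)),
        n_starts=len(starts),
        message=str(best.message),
    )
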