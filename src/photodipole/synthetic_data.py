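"""Synthetic whole-cell current-clamp recordings with known ground truth.

Emulates patch-clamp traces of passive HEK-293T-like cells responding to a
light pulse: the clean dual-pathway simulation plus slow linear baseline
drift and additive Gaussian recording noise.  The noise is shaped by a
first-order low-pass at 10 kHz (the acquisition chain's filter bandwidth) and
rescaled so that its standard deviation *after* filtering equals ``sigma``;
the simulated signal itself is already band-limited and is not filtered.

Everything is seeded: the same :class:`NoiseModel` seed reproduces a trace
bitwise, and a cohort draws per-cell resting potentials and per-cell noise
streams from one seeded generator.

What this generator does not emulate: electrode/series-resistance artefacts,
amplifier capacitive transients, ionic-channel noise, or cell-to-cell
variability in passive parameters beyond the resting potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .dipole_mapping import field_scale
from .interface import RunConfig
from .membrane_model import Trace
from .photokinetics import PhotoswitchParams
from .experiments import simulate_trace

__all__ = ["NoiseModel", "generate_trace", "generate_cohort"]

#: low-pass corner frequency of the recording chain, kHz
FILTER_CUTOFF_KHZ = 10.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive recording-noise model.

    ``sigma`` is the Gaussian standard deviation in mV *after* the 10 kHz
    low-pass; ``drift_rate`` is a linear baseline drift in mV/s; ``seed``
    makes the stream reproducible.
    """

    sigma: float = 0.3
    drift_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"NoiseModel.sigma must be >= 0 mV, got {self.sigma!r}")
        if not math.isfinite(self.drift_rate):
            raise ValueError("NoiseModel.drift_rate must be finite")


def _filtered_noise(n: int, rate: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise shaped by a single-pole low-pass, unit-calibrated to sd=sigma."""
    if sigma == 0:
        return np.zeros(n)
    dt = 1.0 / rate  # ms
    tau_f = 1.0 / (2.0 * math.pi * FILTER_CUTOFF_KHZ)  # ms
    alpha = dt / (tau_f + dt)
    white = rng.standard_normal(n)
    shaped = lfilter([alpha], [1.0, -(1.0 - alpha)], white)
    # stationary gain of y[n] = (1-a) y[n-1] + a x[n] on white noise
    gain = math.sqrt(alpha / (2.0 - alpha))
    return sigma * shaped / gain


def generate_trace(cfg: RunConfig, noise: NoiseModel) -> tuple[Trace, PhotoswitchParams]:
    """One noisy dual-pathway trace plus the exact generating parameters."""
    clean = simulate_trace(cfg, dipole_on=True)
    rng = np.random.default_rng(noise.seed)
    drift = noise.drift_rate * (clean.t - clean.t[0]) / 1000.0  # mV/s on ms grid
    v = clean.v + drift + _filtered_noise(len(clean.t), clean.rate, noise.sigma, rng)
    meta = dict(clean.meta, synthetic=True, sigma_mV=noise.sigma,
                drift_mV_per_s=noise.drift_rate, seed=noise.seed)
    return Trace(t=clean.t, v=v, rate=clean.rate, meta=meta), cfg.photoswitch


def generate_cohort(
    cfg: RunConfig,
    n_cells: int,
    vr_range: tuple[float, float],
    noise: NoiseModel,
) -> list[tuple[Trace, float, PhotoswitchParams]]:
    """Synthetic cell population across a resting-potential range.

    Per-cell resting potentials are drawn uniformly in ``vr_range`` (seeded by
    ``noise.seed``); the dipolar amplitude varies per cell through the
    field-scaling rule applied inside the simulation.  Returns
    ``(trace, vr, ground_truth)`` triples ready for regression and
    parameter-recovery studies.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = float(vr_range[0]), float(vr_range[1])
    if not hi > lo:
        raise ValueError(f"empty vr_range {vr_range}")
    rng = np.random.default_rng(noise.seed)
    vrs = rng.uniform(lo, hi, size=n_cells)
    cells = []
    for vr in vrs:
        cell_seed = int(rng.integers(0, 2**31 - 1))
        cell_cfg = cfg.with_vr(float(vr))
        trace, truth = generate_trace(
            cell_cfg, NoiseModel(sigma=noise.sigma, drift_rate=noise.drift_rate, seed=cell_seed)
        )
        trace.meta["field_scale"] = field_scale(cell_cfg.dipole, cell_cfg.membrane.vr)
        cells.append((trace, float(vr), truth))
    return cells
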