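"""Configuration loading/validation, trace CSV I/O, metrics export and plotting.

Configuration files are YAML (or JSON, which YAML subsumes) with five
sections — ``membrane``, ``photoswitch``, ``dipole``, ``protocol``,
``simulation`` — whose keys carry explicit units in their names
(``cm0_pF``, ``tau_on_c_ms``, ...).  Unknown sections or keys are rejected,
and every violation found is reported in one error message rather than only
the first.

Trace CSV dialect: UTF-8, '.' decimal separator, LF newlines, header
``time_ms,vm_mV`` (or ``time_ms,cm_pF`` / ``time_ms,vs_mV`` for coefficient
waveform dumps).  Values are written with full float precision so a
write/read round trip is lossless well below 1e-9 mV.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .dipole_mapping import DipoleConfig
from .membrane_model import MembraneParams, Trace
from .photokinetics import LightProtocol, PhotoswitchParams

__all__ = [
    "ConfigError",
    "TraceFormatError",
    "SimulationSettings",
    "RunConfig",
    "DEFAULT_CONFIG",
    "default_config",
    "load_config",
    "config_from_mapping",
    "read_trace",
    "write_trace",
    "metrics_frame",
    "plot_traces",
]

logger = logging.getLogger("photodipole")

TRACE_HEADERS = ("time_ms,vm_mV", "time_ms,cm_pF", "time_ms,vs_mV")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class TraceFormatError(ValueError):
    """Malformed trace CSV file."""


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings of a simulation run."""

    t_start: float = 0.0  # ms
    t_end: float = 500.0  # ms
    rate: float = 20.0  # kHz, matching a 20 kHz acquisition rate
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("simulation window is empty")
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0 kHz")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")

    @property
    def window(self) -> tuple[float, float]:
        return (self.t_start, self.t_end)


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of everything a protocol run needs."""

    membrane: MembraneParams
    photoswitch: PhotoswitchParams
    dipole: DipoleConfig
    protocol: LightProtocol
    simulation: SimulationSettings = field(default_factory=SimulationSettings)

    def __post_init__(self) -> None:
        self.protocol.require_baseline(self.simulation.t_start)
        if self.protocol.t_off >= self.simulation.t_end:
            raise ValueError("simulation window must extend past the light pulse")

    def with_vr(self, vr: float) -> "RunConfig":
        """Copy of this configuration at a different holding potential."""
        return replace(self, membrane=replace(self.membrane, vr=vr))


# Default study conditions.  Values marked (calibrated) were fixed once by
# scripts/calibrate.py and are frozen here; see docs/methods.md for provenance
# of every number.
DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "membrane": {
        "cm0_pF": 26.67,  # so a -15 % change is the 4 pF step
        "rm_GOhm": 1.0,  # typical HEK-293 whole-cell input resistance
        "vr_mV": -60.0,
        "vs0_mV": 15.0,  # (calibrated)
    },
    "photoswitch": {
        "dcm_rel": -0.15,
        "dvs_mV": 5.0,
        "tau_on_c_ms": 0.8,  # (calibrated)
        "tau_off_c_ms": 100.0,
        "tau_on_s_ms": 3.5,  # (calibrated)
        "tau_off_s_ms": 50.0,
    },
    "dipole": {
        "mu_trans_D": 1.05,
        "mu_cis_D": 7.35,
        "leaflet": "outer",
        "orientation": "away_from_core",
        "coupling_mV_per_D": 1.25,
        "field_scaling_enabled": True,
        "vref_mV": -60.0,
    },
    "protocol": {
        "t_on_ms": 50.0,
        "duration_ms": 20.0,
        "wavelength_nm": 470.0,
        "irradiance_mW_mm2": 50.0,
    },
    "simulation": {
        "t_start_ms": 0.0,
        "t_end_ms": 500.0,
        "rate_kHz": 20.0,
        "rtol": 1e-8,
        "atol": 1e-10,
    },
}

_SECTION_FIELDS = {name: tuple(sec.keys()) for name, sec in DEFAULT_CONFIG.items()}


def default_config() -> RunConfig:
    """The packaged default configuration as a validated :class:`RunConfig`."""
    return config_from_mapping(DEFAULT_CONFIG)


def _merge(base: dict, override: Mapping, errors: list[str]) -> dict:
    merged = copy.deepcopy(base)
    for section, content in override.items():
        if section not in _SECTION_FIELDS:
            errors.append(f"unknown config section {section!r}")
            continue
        if not isinstance(content, Mapping):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, value in content.items():
            if key not in _SECTION_FIELDS[section]:
                errors.append(f"unknown key {section}.{key!r}")
                continue
            merged[section][key] = value
    return merged


def config_from_mapping(mapping: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a (possibly partial) nested mapping.

    Missing keys take their defaults; unknown keys and every physical
    invariant violation are collected and reported together.
    """
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, mapping, errors)

    def build(name, factory):
        try:
            return factory()
        except (ValueError, TypeError) as exc:
            errors.append(f"{name}: {exc}")
            return None

    m, p, d, pr, s = cfg["membrane"], cfg["photoswitch"], cfg["dipole"], cfg["protocol"], cfg["simulation"]
    membrane = build("membrane", lambda: MembraneParams(
        cm0=float(m["cm0_pF"]), rm=float(m["rm_GOhm"]),
        vr=float(m["vr_mV"]), vs0=float(m["vs0_mV"]),
    ))
    photoswitch = build("photoswitch", lambda: PhotoswitchParams(
        dcm_rel=float(p["dcm_rel"]), dvs=float(p["dvs_mV"]),
        tau_on_c=float(p["tau_on_c_ms"]), tau_off_c=float(p["tau_off_c_ms"]),
        tau_on_s=float(p["tau_on_s_ms"]), tau_off_s=float(p["tau_off_s_ms"]),
    ))
    dipole = build("dipole", lambda: DipoleConfig(
        mu_trans=float(d["mu_trans_D"]), mu_cis=float(d["mu_cis_D"]),
        leaflet=d["leaflet"], orientation=d["orientation"],
        coupling_mV_per_D=None if d["coupling_mV_per_D"] is None else float(d["coupling_mV_per_D"]),
        field_scaling_enabled=bool(d["field_scaling_enabled"]),
        vref=float(d["vref_mV"]),
    ))
    protocol = build("protocol", lambda: LightProtocol(
        t_on=float(pr["t_on_ms"]), duration=float(pr["duration_ms"]),
        wavelength=float(pr["wavelength_nm"]), irradiance=float(pr["irradiance_mW_mm2"]),
    ))
    simulation = build("simulation", lambda: SimulationSettings(
        t_start=float(s["t_start_ms"]), t_end=float(s["t_end_ms"]),
        rate=float(s["rate_kHz"]), rtol=float(s["rtol"]), atol=float(s["atol"]),
    ))
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    try:
        return RunConfig(
            membrane=membrane, photoswitch=photoswitch, dipole=dipole,
            protocol=protocol, simulation=simulation,
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration file (defaults if ``path`` is None)."""
    if path is None:
        return default_config()
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path} must contain a mapping of config sections")
    logger.debug("loaded config overrides from %s: %s", path, data)
    return config_from_mapping(data)


def write_trace(trace: Trace, path: str | Path, kind: str = "vm") -> None:
    """Write a trace as CSV with header ``time_ms,{vm_mV|cm_pF|vs_mV}``."""
    header = {"vm": "time_ms,vm_mV", "cm": "time_ms,cm_pF", "vs": "time_ms,vs_mV"}[kind]
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for t, v in zip(trace.t.tolist(), trace.v.tolist()):
            fh.write(f"{t!r},{v!r}\n")


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV (see module docstring for the dialect).

    Malformed rows are reported with their line number; a non-uniform or
    non-monotonic time grid is rejected.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file") from None
        header_str = ",".join(h.strip() for h in header)
        if header_str not in TRACE_HEADERS:
            raise TraceFormatError(
                f"{path}: bad header {header_str!r}; expected one of {TRACE_HEADERS}"
            )
        t_vals, v_vals = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise TraceFormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            try:
                t_vals.append(float(row[0]))
                v_vals.append(float(row[1]))
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: {exc}") from None
    if len(t_vals) < 2:
        raise TraceFormatError(f"{path}: need at least two samples")
    t = np.asarray(t_vals)
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 3  # +2 header/1-based, +1 second row of pair
        raise TraceFormatError(f"{path}:{bad}: time grid not strictly increasing")
    step = float(np.median(dt))
    if not np.allclose(dt, step, rtol=1e-6, atol=1e-9):
        raise TraceFormatError(f"{path}: time grid is not uniform")
    return Trace(t=t, v=np.asarray(v_vals), rate=1.0 / step, meta={"source": str(path)})


def metrics_frame(metrics: Mapping[str, Any]):
    """Tabulate ``{trace_id: TraceMetrics}`` as a pandas DataFrame for CSV export."""
    import pandas as pd

    rows = [
        {
            "trace_id": label,
            "baseline_mV": m.baseline,
            "peak_mV": m.peak_deflection,
            "t_peak_ms": m.time_to_peak,
            "rebound_mV": m.rebound_peak,
            "plateau_mV": m.plateau,
        }
        for label, m in metrics.items()
    ]
    return pd.DataFrame(rows)


def write_summary_json(summary: Mapping[str, Any], path: str | Path) -> None:
    """Dump a summary mapping as JSON (numpy scalars coerced to python floats)."""

    def coerce(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(dict(summary), indent=2, default=coerce) + "\n",
                          encoding="utf-8")


def plot_traces(traces: Mapping[str, Trace], path: str | Path, title: str = "") -> None:
    """Plot labelled membrane-potential traces to ``path`` (PNG/PDF; optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, trace in traces.items():
        ax.plot(trace.t, trace.v, label=label, lw=1.0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V_m (mV)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
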