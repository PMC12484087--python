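"""Mapping from molecular dipoles and leaflet asymmetry to the surface-potential step.

Photo-isomerization changes the molecular dipole moment by Δμ = μ_cis − μ_trans.
Whether that change depolarizes or hyperpolarizes the cell is *not* set by the
sign of Δμ alone: it depends on which bilayer leaflet is enriched in
photoswitch and on how the dipole's positive end is oriented relative to the
bilayer midplane.  The polarity rule implemented here is the product

    sign(ΔV_s) = s_leaflet * s_orientation * sign(Δμ)

with ``s_leaflet = +1`` for the outer leaflet and −1 for the inner, and
``s_orientation = +1`` when the positive end points away from the bilayer core
(outward on the outer leaflet, cytosol-ward on the inner) and −1 otherwise.
Encoding orientation relative to the midplane rather than the lab frame is the
minimal convention under which one product rule covers both an outer-leaflet
dipole-lengthening switch (depolarizing) and an inner-leaflet
dipole-shortening switch with inward-pointing dipoles (also depolarizing).
This product rule is the simplest rule consistent with those two cases; it is
a modelling choice, not a derived electrostatic law.

Stronger transmembrane fields align the molecular dipoles more effectively and
amplify the surface-potential amplitude.  That is modelled by a single linear
amplitude factor ``v_hold / vref`` (clipped at zero), proxying the field by the
pre-pulse holding potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Leaflet",
    "Orientation",
    "DipoleConfig",
    "vs_step_sign",
    "vs_step_amplitude",
    "field_scale",
]


class Leaflet(str, Enum):
    """Bilayer monolayer enriched in photoswitch."""

    OUTER = "outer"
    INNER = "inner"


class Orientation(str, Enum):
    """Direction of the dipole's positive end relative to the bilayer midplane."""

    AWAY_FROM_CORE = "away_from_core"
    TOWARD_CORE = "toward_core"


@dataclass(frozen=True)
class DipoleConfig:
    """Molecular dipole moments, leaflet occupancy and field-coupling settings.

    Parameters
    ----------
    mu_trans, mu_cis : float
        Dipole moments of the trans and cis isomers, Debye (magnitudes, >= 0).
    leaflet : Leaflet
        Which leaflet holds the photoswitch excess.
    orientation : Orientation
        Dipole orientation relative to the bilayer core, at that leaflet.
    coupling_mV_per_D : float, optional
        Linear dipole-to-surface-potential coupling, mV per Debye.  Optional
        amplitude helper; protocols normally set the amplitude directly.
    field_scaling_enabled : bool
        Whether the surface-potential amplitude scales with holding potential.
    vref : float
        Reference holding potential (mV) at which the field scale is 1.
    """

    mu_trans: float
    mu_cis: float
    leaflet: Leaflet = Leaflet.OUTER
    orientation: Orientation = Orientation.AWAY_FROM_CORE
    coupling_mV_per_D: float | None = None
    field_scaling_enabled: bool = True
    vref: float = -60.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_trans) and self.mu_trans >= 0):
            raise ValueError(f"mu_trans must be >= 0 D, got {self.mu_trans!r}")
        if not (math.isfinite(self.mu_cis) and self.mu_cis >= 0):
            raise ValueError(f"mu_cis must be >= 0 D, got {self.mu_cis!r}")
        if self.vref == 0 or not math.isfinite(self.vref):
            raise ValueError("vref must be finite and non-zero mV")
        object.__setattr__(self, "leaflet", Leaflet(self.leaflet))
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    @property
    def delta_mu(self) -> float:
        """Signed dipole change Δμ = μ_cis − μ_trans, Debye."""
        return self.mu_cis - self.mu_trans


def vs_step_sign(cfg: DipoleConfig) -> int:
    """Polarity of the light-induced surface-potential step.

    Returns +1 (depolarizing, raises V_s), −1 (hyperpolarizing) or 0 (no
    dipole change), from the product of leaflet side, orientation and the sign
    of Δμ.
    """
    s_leaflet = 1 if cfg.leaflet is Leaflet.OUTER else -1
    s_orient = 1 if cfg.orientation is Orientation.AWAY_FROM_CORE else -1
    dmu = cfg.delta_mu
    s_mu = (dmu > 0) - (dmu < 0)
    return s_leaflet * s_orient * s_mu


def vs_step_amplitude(cfg: DipoleConfig) -> float:
    """Unsigned surface-potential amplitude from the linear Δμ coupling, mV.

    Helper only: ``coupling_mV_per_D * |Δμ|``.  Protocols may instead set the
    amplitude directly (the default configuration does).
    """
    if cfg.coupling_mV_per_D is None:
        raise ValueError("DipoleConfig.coupling_mV_per_D is not set")
    return cfg.coupling_mV_per_D * abs(cfg.delta_mu)


def field_scale(cfg: DipoleConfig, v_hold: float) -> float:
    """Dimensionless field-strength amplitude multiplier for a holding potential.

    1 when scaling is disabled; otherwise ``max(v_hold / vref, 0)`` — linear in
    the transmembrane field proxied by the holding potential, equal to 1 at the
    reference potential and clipped at zero when the field reverses.
    """
    if not cfg.field_scaling_enabled:
        return 1.0
    if not math.isfinite(v_hold):
        raise ValueError("v_hold must be finite mV")
    return max(v_hold / cfg.vref, 0.0)
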