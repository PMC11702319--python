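"""Water-mass classification from T-S properties and freshwater content.

Arctic fjord water columns are conventionally partitioned into Surface Water
(SW), Intermediate Water (IW), Local Water (LW), Transformed Atlantic Water
(TAW) and Atlantic Water (AW) by temperature-salinity bounds following the
Cottier et al. (2005) scheme for Kongsfjorden.  The freshwater content of a
station is the equivalent thickness (m) of pure freshwater implied by the
depth-integrated salinity deficit relative to a reference salinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "WaterMassRule",
    "DEFAULT_WATER_MASS_RULES",
    "classify_water_mass",
    "load_water_mass_rules",
    "DepthProfile",
    "freshwater_content",
    "specific_freshwater_content",
    "REFERENCE_SALINITY",
]

#: high-salinity reference for freshwater-content integration (practical
#: salinity of the Atlantic-derived source water)
REFERENCE_SALINITY = 34.86


@dataclass(frozen=True)
class WaterMassRule:
    """One T-S box; rules are evaluated in order, first match wins."""

    label: str
    t_min: float = -np.inf
    t_max: float = np.inf
    s_min: float = -np.inf
    s_max: float = np.inf

    def __post_init__(self):
        if self.t_min > self.t_max or self.s_min > self.s_max:
            raise ValueError(f"ill-formed interval in rule {self.label!r}")

    def matches(self, temperature: float, salinity: float) -> bool:
        return (self.t_min < temperature <= self.t_max
                and self.s_min < salinity <= self.s_max)


# Cottier-style default bounds; editable because published schemes vary in
# detail between studies.  Open intervals on the low side, closed on the high
# side, so every finite (T, S) maps to at most one label per rule.
DEFAULT_WATER_MASS_RULES: tuple[WaterMassRule, ...] = (
    WaterMassRule("AW", t_min=3.0, s_min=34.65),
    WaterMassRule("TAW", t_min=1.0, t_max=3.0, s_min=34.65),
    WaterMassRule("SW", s_max=34.0),
    WaterMassRule("IW", t_min=1.0, s_min=34.0, s_max=34.65),
    WaterMassRule("LW", t_max=1.0, s_min=34.3),
)

UNCLASSIFIED = "unclassified"


def classify_water_mass(temperature: float, salinity: float,
                        rules=DEFAULT_WATER_MASS_RULES) -> str:
    """Label a (T, S) pair by the first matching rule; fallback unclassified."""
    if not (np.isfinite(temperature) and np.isfinite(salinity)):
        raise ValueError("temperature and salinity must be finite")
    for rule in rules:
        if rule.matches(temperature, salinity):
            return rule.label
    return UNCLASSIFIED


def load_water_mass_rules(path) -> tuple[WaterMassRule, ...]:
    """Load an ordered rule list from YAML (label + optional t/s bounds)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(WaterMassRule(**entry) for entry in raw)


# ---------------------------------------------------------------------------
# Freshwater content
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Salinity against depth at one station.

    Depths must be strictly increasing; ``bottom_depth`` defaults to the
    deepest measured level when not stated.
    """

    station: str
    depths: np.ndarray
    salinities: np.ndarray
    bottom_depth: float | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.salinities = np.asarray(self.salinities, dtype=float)
        if self.depths.size == 0:
            raise ValueError("empty profile")
        if self.depths.size != self.salinities.size:
            raise ValueError("depths and salinities differ in length")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.depths < 0):
            raise ValueError("negative depth")
        if np.any((self.salinities < 0) | (self.salinities > 42)):
            raise ValueError("salinity outside [0, 42]")
        if self.bottom_depth is None:
            self.bottom_depth = float(self.depths[-1])
        if self.bottom_depth < self.depths[-1]:
            raise ValueError("bottom_depth shallower than deepest level")


def freshwater_content(profile: DepthProfile,
                       s_ref: float = REFERENCE_SALINITY) -> float:
    """Depth-integrated salinity deficit, in metres of pure freshwater.

    FWC = integral over the water column of (s_ref - S(z)) / s_ref dz,
    evaluated by the trapezoidal rule.  The shallowest measurement is
    extended unchanged to the surface and the deepest to the bottom depth.
    Local negative anomalies (S > s_ref) are retained with their sign so
    that dilution budgets conserve mass.
    """
    z = profile.depths
    s = profile.salinities
    if z[0] > 0.0:
        z = np.concatenate([[0.0], z])
        s = np.concatenate([[s[0]], s])
    if profile.bottom_depth > z[-1]:
        z = np.concatenate([z, [profile.bottom_depth]])
        s = np.concatenate([s, [s[-1]]])
    integrand = (s_ref - s) / s_ref
    return float(np.trapezoid(integrand, z))


def specific_freshwater_content(fwc: float, bottom_depth: float) -> float:
    """Freshwater content as a percentage of the water-column height."""
    if bottom_depth <= 0:
        raise ValueError("bottom depth must be positive")
    return 100.0 * fwc / bottom_depth
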