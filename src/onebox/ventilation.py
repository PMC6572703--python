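"""Air-exchange rates and ventilation flows from room geometry and air speeds.

ACH = Q / V with Q in m^3 h^-1 and V in m^3.  When only anemometer air speeds
at extraction openings are available, the total flow is the sum of
speed x opening-area products over all openings.  Open-door and closed-door
regimes are represented as two alternative specs for the same room; the
pipeline can run both and report both ratio sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .exceptions import ConfigurationError, DomainError

__all__ = ["VentilationSpec", "ach_from_flow", "flow_from_speeds", "ach_from_speeds"]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class VentilationSpec:
    """Measured air speeds at ventilation openings of one room regime.

    Attributes
    ----------
    openings : list of (speed, area)
        Air speed in m s^-1 (>= 0) and opening area in m^2 (> 0) per opening.
    volume : float
        Room volume in m^3.
    """

    openings: List[Tuple[float, float]]
    volume: float

    def __post_init__(self):
        if not self.volume > 0:
            raise DomainError("room volume must be > 0")
        for speed, area in self.openings:
            if speed < 0:
                raise DomainError("air speeds must be >= 0")
            if not area > 0:
                raise DomainError("opening areas must be > 0")


def ach_from_flow(flow_m3h: float, volume_m3: float) -> float:
    """Air changes per hour from total flow (m^3 h^-1) and volume (m^3)."""
    if not volume_m3 > 0:
        raise DomainError("room volume must be > 0")
    if flow_m3h < 0:
        raise DomainError("ventilation flow must be >= 0")
    return flow_m3h / volume_m3

def flow_from_speeds(spec: VentilationSpec) -> float:
    """Total ventilation flow in m^3 h^-1 summed over all openings."""
    if not spec.openings:
        raise ConfigurationError("ventilation spec has no openings")
    return sum(speed * area for speed, area in spec.openings) * SECONDS_PER_HOUR


def ach_from_speeds(spec: VentilationSpec) -> float:
    """Convenience chain: air speeds -> total flow -> ACH."""
    return ach_from_flow(flow_from_speeds(spec), spec.volume)
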