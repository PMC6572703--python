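"""Worked-example data: a four-day thermal-spraying measurement campaign.

Per-shift summary concentrations from an industrial thermal-spraying
workshop where nanoparticle exposure in the worker area was modeled with the
one-box balance.  Two spraying booths were monitored on alternate days
(booth 1: atmospheric plasma spraying, ~459 m^3 modeled area at ACH 35 h^-1;
booth 3: high-velocity oxy-fuel spraying, ~249 m^3 at ACH 25 h^-1).  For each
shift the table carries the one-box modeled mean concentration under each
emission-rate estimator, the means measured by the two particle counters,
and the background statistics of the lunch window.

Only shift-level summary values were published — the raw 1-minute series are
not available — so this dataset exercises the scalar parts of the evaluation
layer (ratios, significance); series-level behavior is covered by the
synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = ["ShiftRecord", "THERMAL_SPRAY_SHIFTS", "VENTILATION", "PUBLISHED_RATIOS"]


@dataclass(frozen=True)
class ShiftRecord:
    """Published summary concentrations of one monitored shift (cm^-3)."""

    day: int
    shift: str  # "morning" / "afternoon"
    booth: int
    modeled: Dict[str, float]  # estimator -> modeled mean
    measured: Dict[str, float]  # instrument -> measured mean
    background: Dict[str, float]  # instrument -> lunch-window mean


#: (flow m^3 h^-1, volume m^3, ACH h^-1) per modeled booth area.
VENTILATION = {1: (16078.0, 459.4, 35.0), 3: (6216.0, 248.6, 25.0)}

THERMAL_SPRAY_SHIFTS = (
    ShiftRecord(
        1, "afternoon", 1,
        modeled={"convolution": 1.4e4, "cyclic": 1.7e4},
        measured={"nanoscan": 4.2e4, "discmini": 6.4e3},
        background={"nanoscan": 1.4e4, "discmini": 1.2e4},
    ),
    ShiftRecord(
        2, "morning", 1,
        modeled={"convolution": 2.0e4, "cyclic": 2.0e4},
        measured={"nanoscan": 7.8e4, "discmini": 9.6e4},
        background={"nanoscan": 1.7e4, "discmini": 1.2e4},
    ),
    ShiftRecord(
        2, "afternoon", 1,
        modeled={"convolution": 2.4e4, "cyclic": 2.4e4},
        measured={"nanoscan": 4.9e4, "discmini": 6.7e4},
        background={"nanoscan": 1.7e4, "discmini": 1.2e4},
    ),
    ShiftRecord(
        3, "morning", 3,
        modeled={"convolution": 5.9e4, "cyclic": 4.5e4},
        measured={"nanoscan": 2.5e5, "discmini": 3.5e5},
        background={"nanoscan": 1.9e4, "discmini": 2.0e4},
    ),
    ShiftRecord(
        3, "afternoon", 3,
        modeled={"convolution": 6.0e4, "cyclic": 4.6e4},
        measured={"nanoscan": 9.0e4, "discmini": 1.1e5},
        background={"nanoscan": 1.9e4, "discmini": 2.0e4},
    ),
    ShiftRecord(
        4, "morning", 3,
        modeled={"convolution": 5.6e4, "cyclic": 7.1e4},
        measured={"nanoscan": 1.5e5, "discmini": 1.9e5},
        background={"nanoscan": 3.7e4, "discmini": 4.5e4},
    ),
    ShiftRecord(
        4, "afternoon", 3,
        modeled={"convolution": 5.3e4, "cyclic": 6.5e4},
        measured={"nanoscan": 1.3e5, "discmini": 1.6e5},
        background={"nanoscan": 3.7e4, "discmini": 4.5e4},
    ),
)

#: Published modeled/measured ratio cells, keyed
#: (day, shift, estimator, instrument) -> ratio rounded to 2 d.p.
PUBLISHED_RATIOS: Dict[Tuple[int, str, str, str], float] = {
    (1, "afternoon", "convolution", "nanoscan"): 0.33,
    (2, "morning", "convolution", "nanoscan"): 0.26,
    (2, "afternoon", "convolution", "nanoscan"): 0.49,
    (3, "morning", "convolution", "nanoscan"): 0.24,
    (3, "afternoon", "convolution", "nanoscan"): 0.67,
    (4, "morning", "convolution", "nanoscan"): 0.37,
    (4, "afternoon", "convolution", "nanoscan"): 0.41,
    (1, "afternoon", "cyclic", "nanoscan"): 0.40,
    (2, "morning", "cyclic", "nanoscan"): 0.26,
    (2, "afternoon", "cyclic", "nanoscan"): 0.49,
    (3, "morning", "cyclic", "nanoscan"): 0.18,
    (3, "afternoon", "cyclic", "nanoscan"): 0.51,
    (4, "morning", "cyclic", "nanoscan"): 0.47,
    (4, "afternoon", "cyclic", "nanoscan"): 0.50,
    (1, "afternoon", "convolution", "discmini"): 2.19,
    (2, "morning", "convolution", "discmini"): 0.21,
    (2, "afternoon", "convolution", "discmini"): 0.36,
    (3, "morning", "convolution", "discmini"): 0.17,
    (3, "afternoon", "convolution", "discmini"): 0.55,
    (4, "morning", "convolution", "discmini"): 0.29,
    (4, "afternoon", "convolution", "discmini"): 0.33,
    (1, "afternoon", "cyclic", "discmini"): 2.66,
    (2, "morning", "cyclic", "discmini"): 0.21,
    (2, "afternoon", "cyclic", "discmini"): 0.36,
    (3, "morning", "cyclic", "discmini"): 0.13,
    (3, "afternoon", "cyclic", "discmini"): 0.42,
    (4, "morning", "cyclic", "discmini"): 0.37,
    (4, "afternoon", "cyclic", "discmini"): 0.41,
}
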