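"""Emission-rate estimation from worker-area concentration series.

Two estimators of the source strength S_N (particles min^-1) transported from
a spraying booth into the worker area:

* **Deconvolution** of the one-box balance: for measurements on a regular
  grid the discrete inverse of the mass balance is

      S_tot(t) = V * (N(t) - N(t - dt) * exp(-gamma*dt)) / dt

  which yields a time-resolved total generation rate.  The background
  generation rate S_BG = Q * N_BG (infiltration) is subtracted to isolate the
  activity source.  Because the booth protection factor eps_C is unknown, the
  result is the lumped product eps_C * S_N.

* **Cyclic steady state**: S_N = C_hat * V / t_ESD, where C_hat is the mean
  concentration during spraying and t_ESD the duration of one spraying
  repetition.  The formula neglects removal during the burst, so it is a
  deliberate first-order approximation suited to preliminary assessment.

Activity segmentation uses a concentration threshold (default 1e5 cm^-3,
the level separating spray-ON from spray-OFF minutes), with an explicitly
configured source-off window (the lunch break) labeled background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .exceptions import ConfigurationError, DomainError, EstimationError, GridError
from .massbalance import (
    ConcentrationSeries,
    EmissionSchedule,
    flow_m3h_to_cm3min,
    _as_grid,
)

__all__ = [
    "BACKGROUND",
    "ACTIVITY",
    "OTHER",
    "DEFAULT_ACTIVITY_THRESHOLD",
    "SegmentLabels",
    "BackgroundEstimate",
    "EmissionEstimate",
    "detect_activity",
    "estimate_background",
    "deconvolve",
    "deconvolved_background_rate",
    "summarize_convolution",
    "activity_mean",
    "spraying_duration",
    "cyclic_steady_state",
]

BACKGROUND = "background"
ACTIVITY = "activity"
OTHER = "other"

#: Spray ON/OFF concentration threshold, cm^-3.
DEFAULT_ACTIVITY_THRESHOLD = 1.0e5


@dataclass(frozen=True)
class SegmentLabels:
    """Per-step classification {background, activity, other} on a time grid."""

    times: np.ndarray
    state: np.ndarray

    def __post_init__(self):
        t = _as_grid(self.times)
        s = np.asarray(self.state, dtype=object)
        if s.shape != t.shape:
            raise GridError("times and state must have the same length")
        bad = set(s) - {BACKGROUND, ACTIVITY, OTHER}
        if bad:
            raise DomainError(f"unknown segment states: {sorted(bad)}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "state", s)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def mask(self, which: str) -> np.ndarray:
        return self.state == which

    @property
    def activity(self) -> np.ndarray:
        return self.mask(ACTIVITY)

    @property
    def background(self) -> np.ndarray:
        return self.mask(BACKGROUND)

    def shifted(self, steps: int = 1) -> "SegmentLabels":
        """Labels displaced ``steps`` grid steps later (vacated steps: other).

        Source-aligned labels mark the step over which emission occurs;
        the deconvolved rate for that step is attached to the measurement at
        the step's *end*.  Shifting by one aligns source-step labels with the
        deconvolution grid.
        """
        s = np.full_like(self.state, OTHER)
        if steps == 0:
            s[:] = self.state
        elif steps > 0:
            s[steps:] = self.state[:-steps]
        else:
            s[:steps] = self.state[-steps:]
        return SegmentLabels(self.times, s)

    def activity_blocks(self) -> List[Tuple[int, int]]:
        """Contiguous activity runs as (start, stop) index pairs, stop exclusive."""
        a = self.activity.astype(int)
        edges = np.diff(np.concatenate(([0], a, [0])))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        return list(zip(starts.tolist(), stops.tolist()))


@dataclass(frozen=True)
class BackgroundEstimate:
    """Background concentration statistics and generation rate.

    ``sd`` is the sample (n-1) standard deviation: background windows are
    short, so the small-sample correction matters.  ``s_bg`` is the analytic
    background generation rate Q * N_BG in particles min^-1.
    """

    mean: float
    sd: float
    window: Tuple[float, float]
    s_bg: float

    def __post_init__(self):
        if self.sd < 0:
            raise DomainError("background sd must be >= 0")


@dataclass(frozen=True)
class EmissionEstimate:
    """Scalar emission-rate summary from one estimator.

    ``rate`` is the lumped transported source strength eps_C * S_N in
    particles min^-1 (the booth protection factor eps_C cannot be separated
    from worker-area data).  The convolution method also carries the full
    deconvolved net schedule; the cyclic method echoes its C_hat and t_ESD
    inputs, for which ``rate == c_hat * volume / t_esd`` holds exactly.
    """

    method: str
    rate: float
    series: Optional[EmissionSchedule] = None
    c_hat: Optional[float] = None
    t_esd: Optional[float] = None
    note: str = "rate is eps_C * S_N (booth protection factor lumped in)"


# ---------------------------------------------------------------------------
# Segmentation and background
# ---------------------------------------------------------------------------


def detect_activity(
    series: ConcentrationSeries,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    background_window: Optional[Tuple[float, float]] = None,
) -> SegmentLabels:
    """Classify each minute as activity (above threshold) or other.

    An explicitly supplied source-off window (e.g. the lunch break) overrides
    the threshold rule and is labeled background.  An empty activity set is a
    valid outcome.
    """
    if not threshold > 0:
        raise DomainError("activity threshold must be > 0")
    state = np.where(series.values > threshold, ACTIVITY, OTHER).astype(object)
    if background_window is not None:
        state[series.window_mask(background_window)] = BACKGROUND
    return SegmentLabels(series.times, state)


def estimate_background(
    series: ConcentrationSeries,
    window: Tuple[float, float],
    flow_m3h: float,
) -> BackgroundEstimate:
    """Mean/sd of a source-off window and the implied generation rate Q*N_BG.

    Parameters
    ----------
    series
        Worker-area concentration series.
    window
        ``(t0, t1)`` background span in minutes, half-open.
    flow_m3h
        Ventilation flow Q in m^3 h^-1, used for s_bg = Q * mean.
    """
    m = series.window_mask(window)
    if not m.any():
        raise ConfigurationError(f"background window {window} selects no data")
    v = series.values[m]
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    s_bg = flow_m3h_to_cm3min(flow_m3h) * mean
    return BackgroundEstimate(mean=mean, sd=sd, window=window, s_bg=s_bg)


# ---------------------------------------------------------------------------
# Deconvolution (convolution-theorem estimator)
# ---------------------------------------------------------------------------


def deconvolve(
    series: ConcentrationSeries, gamma: float, volume_cm3: float
) -> EmissionSchedule:
    """Invert the discrete one-box update into a total generation rate.

    ``rates[i]`` estimates the total source (activity plus background
    infiltration) over the step ending at ``times[i]``; the first step has no
    predecessor and is reported as NaN, never as zero.  Raw rates may be
    negative under measurement noise and are preserved — clipping before
    averaging would bias the mean upward; use
    :meth:`EmissionSchedule.clipped` for a physical view.
    """
    if gamma < 0:
        raise DomainError("loss rate gamma must be >= 0")
    if not volume_cm3 > 0:
        raise DomainError("volume must be > 0")
    dt = series.dt
    n = series.values
    rates = np.empty_like(n)
    rates[0] = np.nan
    rates[1:] = volume_cm3 * (n[1:] - n[:-1] * np.exp(-gamma * dt)) / dt
    return EmissionSchedule(series.times, rates)


def deconvolved_background_rate(
    schedule: EmissionSchedule, labels: SegmentLabels
) -> float:
    """Background generation rate S_BG from the source-off part of a schedule.

    Mean deconvolved total rate over background-labeled steps — the empirical
    counterpart of Q * N_BG, estimated exactly the way the activity rates are
    (so the discretization factor common to both cancels on subtraction).
    """
    m = labels.background & np.isfinite(schedule.rates)
    if not m.any():
        raise EstimationError("no background-labeled steps to estimate S_BG")
    return float(schedule.rates[m].mean())


def summarize_convolution(
    schedule: EmissionSchedule,
    labels: SegmentLabels,
    s_bg: float,
    physical: bool = False,
) -> EmissionEstimate:
    """Average the net deconvolved rate over activity-labeled steps.

    Parameters
    ----------
    schedule
        Raw deconvolved total rates.
    labels
        Segment labels on the same grid.  Note the deconvolution grid
        attaches each rate to the *end* of its step; labels derived from a
        source schedule should be passed through :meth:`SegmentLabels.shifted`
        first, while threshold-detected labels already live on that grid.
    s_bg
        Background generation rate to subtract (particles min^-1); either
        the analytic Q*N_BG or :func:`deconvolved_background_rate`.
    physical
        If true, clip negative net rates to zero before averaging (biased
        upward; default keeps the raw mean).
    """
    m = labels.activity & np.isfinite(schedule.rates)
    if not m.any():
        raise EstimationError("no activity-labeled steps: cannot summarize")
    net = schedule.rates - s_bg
    if physical:
        net = np.clip(net, 0.0, None)
    rate = float(net[m].mean())
    net_sched = EmissionSchedule(schedule.times, np.where(np.isfinite(schedule.rates), net, np.nan))
    return EmissionEstimate(method="convolution", rate=rate, series=net_sched)


# ---------------------------------------------------------------------------
# Cyclic steady-state estimator
# ---------------------------------------------------------------------------


def activity_mean(
    series: ConcentrationSeries,
    labels: SegmentLabels,
    subtract_background: bool = False,
    background: Optional[BackgroundEstimate] = None,
) -> float:
    """Mean concentration over activity-labeled minutes (C_hat).

    The plain mean follows the cyclic formula as written; the background
    rides on the assumption that pre-activity concentrations are much lower.
    ``subtract_background`` removes the background mean first for settings
    where that assumption is shaky.
    """
    m = labels.activity
    if not m.any():
        raise EstimationError("no activity-labeled minutes: C_hat undefined")
    c_hat = float(series.values[m].mean())
    if subtract_background:
        if background is None:
            raise ConfigurationError("background estimate required for subtraction")
        c_hat = max(c_hat - background.mean, 0.0)
    return c_hat


def spraying_duration(labels: SegmentLabels, mode: str = "per_repetition") -> float:
    """Spraying duration t_ESD in minutes from activity labels.

    ``per_repetition`` (default) returns the mean duration of a single
    contiguous activity block — the duration of one spraying cycle, which is
    what the cyclic steady-state formula's single-cycle derivation assumes.
    ``total`` returns the summed activity duration of the window.
    """
    blocks = labels.activity_blocks()
    if not blocks:
        raise EstimationError("no activity blocks: t_ESD undefined")
    durations = [(stop - start) * labels.dt for start, stop in blocks]
    if mode == "per_repetition":
        return float(np.mean(durations))
    if mode == "total":
        return float(np.sum(durations))
    raise ConfigurationError(f"unknown t_ESD mode: {mode!r}")


def cyclic_steady_state(c_hat: float, volume_cm3: float, t_esd: float) -> EmissionEstimate:
    """Cyclic steady-state source strength S_N = C_hat * V / t_ESD.

    Parameters
    ----------
    c_hat
        Mean concentration during spraying, cm^-3.
    volume_cm3
        Room volume in cm^3.
    t_esd
        Spraying (single-repetition) duration in minutes.
    """
    if not t_esd > 0:
        raise DomainError("spraying duration t_esd must be > 0")
    if not (c_hat > 0 and volume_cm3 > 0):
        raise DomainError("c_hat and volume must be > 0")
    rate = c_hat * volume_cm3 / t_esd
    return EmissionEstimate(method="cyclic_ss", rate=rate, c_hat=c_hat, t_esd=t_esd)
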