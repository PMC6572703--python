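"""Synthetic workshop scenarios with known ground truth.

Emulates a thermal-spraying workday as seen by a worker-area particle
counter: cyclic spraying bursts against a background of a few 1e4 cm^-3, a
ventilated room at ACH of a few tens per hour, multiplicative lognormal
instrument noise, and hard saturation of the counter near 4e6 cm^-3.  The
generated day runs 10:00–17:00 on a 1-minute grid with a source-off lunch
window 12:45–13:45 that serves as the background reference period, so the
default segmentation configuration works out of the box.

Two burst regimes bracket the processes of interest: short-cycle spraying
(5–10 min bursts, 7–9 per half day) and long-cycle spraying (20–30 min
bursts, 2–4 per half day).  The defaults describe a short-cycle day in a
249 m^3 room at ACH 25 h^-1 with a 1.9e4 cm^-3 background and a true source
of 1e13 particles min^-1.

All randomness derives from one integer seed; identical seeds give bitwise
identical output.  Independent substreams (schedule, background, noise) are
keyed so that, e.g., changing the noise level does not reshuffle the burst
layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .massbalance import ConcentrationSeries, EmissionSchedule, Scenario, simulate_one_box
from .emission import ACTIVITY, BACKGROUND, OTHER, SegmentLabels

__all__ = [
    "DAY_LENGTH_MIN",
    "LUNCH_WINDOW",
    "GeneratorConfig",
    "GroundTruth",
    "generate_schedule",
    "generate_measurements",
    "generate_ground_truth",
]

#: Monitored workday 10:00–17:00, minutes.
DAY_LENGTH_MIN = 420.0
#: Source-off lunch break 12:45–13:45, minutes from 10:00.
LUNCH_WINDOW = (165.0, 225.0)

_SCHEDULE_STREAM = 0
_BACKGROUND_STREAM = 1
_NOISE_STREAM = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic workshop day.

    Attributes
    ----------
    seed : int
        Root seed for all substreams.
    ach : float
        Air changes per hour, h^-1 (workshop regime: 25–35).
    volume : float
        Room volume, m^3.
    bg_mean : float
        Mean background concentration, cm^-3 (workshop days: 1.2–4.5e4).
    bg_cv : float
        Coefficient of variation of the minute-to-minute background, in
        [0, 1); lognormal around ``bg_mean``.
    n_bursts : int
        Number of spraying repetitions over the day.
    burst_duration : (float, float)
        Uniform range of single-burst durations, minutes.
    gap_duration : (float, float)
        Uniform range of pauses between bursts, minutes.
    true_rate : float
        Source strength during a burst, particles min^-1.
    noise_cv : float
        Multiplicative lognormal instrument noise CV, in [0, 1); mean-one.
    saturation : float
        Instrument ceiling, cm^-3; readings are clipped here.
    dt : float
        Grid step, minutes.
    bg_drift_phi : float, optional
        If set (0 < phi < 1), the background multiplier follows a slow AR(1)
        process with this persistence, emulating day-scale drift; default off.
    """

    seed: int = 0
    ach: float = 25.0
    volume: float = 248.6
    bg_mean: float = 1.9e4
    bg_cv: float = 0.05
    n_bursts: int = 7
    burst_duration: Tuple[float, float] = (5.0, 10.0)
    gap_duration: Tuple[float, float] = (10.0, 30.0)
    true_rate: float = 1.0e13
    noise_cv: float = 0.15
    saturation: float = 4.0e6
    dt: float = 1.0
    bg_drift_phi: Optional[float] = None

    def __post_init__(self):
        if min(self.ach, self.volume, self.bg_mean, self.true_rate, self.dt) <= 0:
            raise ConfigurationError("ach, volume, bg_mean, true_rate, dt must be > 0")
        if self.n_bursts < 0:
            raise ConfigurationError("n_bursts must be >= 0")
        for name in ("bg_cv", "noise_cv"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not self.saturation > self.bg_mean:
            raise ConfigurationError("saturation must exceed bg_mean")
        lo, hi = self.burst_duration
        if not (0 < lo <= hi):
            raise ConfigurationError("burst_duration range must be 0 < lo <= hi")
        lo, hi = self.gap_duration
        if not (0 < lo <= hi):
            raise ConfigurationError("gap_duration range must be 0 < lo <= hi")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    @property
    def grid(self) -> np.ndarray:
        return np.arange(0.0, DAY_LENGTH_MIN, self.dt)


@dataclass(frozen=True)
class GroundTruth:
    """A generated day with everything the pipeline may be tested against."""

    config: GeneratorConfig
    scenario: Scenario
    schedule: EmissionSchedule
    labels: SegmentLabels
    clean_series: ConcentrationSeries
    noisy_series: ConcentrationSeries


def _lognormal_multiplier(rng, cv: float, size: int) -> np.ndarray:
    """Mean-one lognormal draws with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_schedule(config: GeneratorConfig) -> Tuple[EmissionSchedule, SegmentLabels]:
    """Lay out spraying bursts over the day; deterministic given the seed.

    Bursts of uniform random duration are placed left to right separated by
    uniform random gaps; any burst that would overlap the lunch window is
    pushed past it, so the background reference period stays source-free.
    If the bursts cannot be packed into the day a configuration error is
    raised rather than silently dropping repetitions.
    """
    rng = config.rng(_SCHEDULE_STREAM)
    times = config.grid
    rates = np.zeros_like(times)
    state = np.full(times.shape, OTHER, dtype=object)

    lunch_lo, lunch_hi = LUNCH_WINDOW
    t = float(rng.uniform(*config.gap_duration))
    for _ in range(config.n_bursts):
        dur = float(rng.uniform(*config.burst_duration))
        if t < lunch_hi and t + dur > lunch_lo:  # would overlap lunch
            t = lunch_hi
        if t + dur > DAY_LENGTH_MIN:
            raise ConfigurationError(
                f"cannot pack {config.n_bursts} bursts of "
                f"{config.burst_duration} min into a {DAY_LENGTH_MIN:.0f}-min day"
            )
        on = (times >= t) & (times < t + dur)
        rates[on] = config.true_rate
        state[on] = ACTIVITY
        t += dur + float(rng.uniform(*config.gap_duration))

    in_lunch = (times >= lunch_lo) & (times < lunch_hi)
    state[in_lunch] = BACKGROUND
    return EmissionSchedule(times, rates), SegmentLabels(times, state)


def _background(config: GeneratorConfig) -> "ConcentrationSeries | float":
    """Background of the incoming air: constant, noisy, or slowly drifting."""
    if config.bg_cv == 0 and config.bg_drift_phi is None:
        return config.bg_mean
    rng = config.rng(_BACKGROUND_STREAM)
    times = config.grid
    mult = _lognormal_multiplier(rng, config.bg_cv, times.size)
    if config.bg_drift_phi is not None:
        phi = config.bg_drift_phi
        if not (0 < phi < 1):
            raise ConfigurationError("bg_drift_phi must lie in (0, 1)")
        # AR(1) smoothing of the log-multiplier keeps the mean near one.
        logm = np.log(mult)
        for i in range(1, logm.size):
            logm[i] = phi * logm[i - 1] + np.sqrt(1 - phi**2) * logm[i]
        mult = np.exp(logm)
    return ConcentrationSeries(times, config.bg_mean * mult / mult.mean(), "background")


def generate_measurements(truth: GroundTruth, config: Optional[GeneratorConfig] = None) -> ConcentrationSeries:
    """Instrument-like reading: clean series times mean-one lognormal noise,
    hard-clipped at the counter's saturation ceiling."""
    config = config or truth.config
    rng = config.rng(_NOISE_STREAM)
    clean = truth.clean_series
    noise = _lognormal_multiplier(rng, config.noise_cv, len(clean))
    values = np.minimum(clean.values * noise, config.saturation)
    return ConcentrationSeries(clean.times, values, label="synthetic instrument")


def generate_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Full generated day: scenario, schedule, labels, clean and noisy series."""
    schedule, labels = generate_schedule(config)
    scenario = Scenario(
        volume=config.volume,
        ach=config.ach,
        background=_background(config),
        dt=config.dt,
    )
    bg0 = scenario.background_on(schedule.times)[0]
    clean = simulate_one_box(scenario, schedule, n0=float(bg0))
    truth = GroundTruth(
        config=config,
        scenario=scenario,
        schedule=schedule,
        labels=labels,
        clean_series=clean,
        noisy_series=clean,  # placeholder, replaced below
    )
    noisy = generate_measurements(truth, config)
    return GroundTruth(config, scenario, schedule, labels, clean, noisy)
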