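"""Well-mixed one-compartment aerosol mass balance.

The room is treated as a single fully mixed box of volume ``V`` ventilated at
air-exchange rate ``ACH``.  Particle number concentration ``N`` (cm^-3) obeys

    dN/dt = lambda * N_BG(t) + S(t) / V - lambda * N(t)

where ``lambda = ACH / 60`` (min^-1) is the total loss rate (ventilation only;
gravitational deposition is negligible against ACH of tens per hour),
``N_BG`` is the particle concentration of the incoming air, and ``S`` is the
source strength in particles per minute.  For piecewise-constant ``N_BG`` and
``S`` the equation has an exact per-step solution, which :func:`simulate_one_box`
uses instead of an Euler scheme: at a 1-minute grid with ``lambda*dt`` of order
0.4-0.6 an explicit Euler step is visibly biased.

Unit conventions are fixed at ingestion and used everywhere downstream:
concentrations in cm^-3, volumes in cm^3, rates in min^-1, time in minutes.
Room volumes are supplied in m^3 and ventilation flows in m^3 h^-1 because
that is how building data are reported; the conversions are centralized in
:func:`m3_to_cm3`, :func:`flow_m3h_to_cm3min` and :func:`ach_to_loss_rate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DomainError, GridError

__all__ = [
    "M3_TO_CM3",
    "m3_to_cm3",
    "flow_m3h_to_cm3min",
    "ach_to_loss_rate",
    "ConcentrationSeries",
    "EmissionSchedule",
    "Scenario",
    "DecayFit",
    "simulate_one_box",
    "fit_decay",
]

# ---------------------------------------------------------------------------
# Unit conversions (the only place m^3 / hours enter the package)
# ---------------------------------------------------------------------------

M3_TO_CM3 = 1.0e6

#: Relative tolerance used when checking that two time grids coincide.
GRID_RTOL = 1.0e-9


def m3_to_cm3(volume_m3: float) -> float:
    """Convert a room volume from m^3 to cm^3."""
    return volume_m3 * M3_TO_CM3


def flow_m3h_to_cm3min(flow_m3h: float) -> float:
    """Convert a ventilation flow from m^3 h^-1 to cm^3 min^-1."""
    return flow_m3h * M3_TO_CM3 / 60.0


def ach_to_loss_rate(ach_per_h: float) -> float:
    """Convert air changes per hour to the first-order loss rate in min^-1."""
    return ach_per_h / 60.0


# ---------------------------------------------------------------------------
# Time-series containers
# ---------------------------------------------------------------------------


def _as_grid(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise GridError("a time grid needs at least two points")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise GridError("times must be strictly increasing")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise GridError("times must be equally spaced")
    return t


def _same_grid(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and np.allclose(a, b, rtol=GRID_RTOL, atol=1e-9)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Particle number concentrations on a regular time grid.

    Parameters
    ----------
    times
        Minutes from series start, strictly increasing and equally spaced.
    values
        Concentrations in cm^-3, non-negative.
    label
        Free-text instrument or source tag (e.g. ``"NanoScan WA"``).
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = _as_grid(self.times)
        v = np.asarray(self.values, dtype=float)
        if v.shape != t.shape:
            raise GridError("times and values must have the same length")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise DomainError("concentrations must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def mean(self) -> float:
        return float(self.values.mean())

    def window_mask(self, window: Tuple[float, float]) -> np.ndarray:
        """Boolean mask for times in ``[window[0], window[1])``."""
        t0, t1 = window
        return (self.times >= t0) & (self.times < t1)

    def window(self, window: Tuple[float, float]) -> "ConcentrationSeries":
        m = self.window_mask(window)
        if m.sum() < 2:
            raise GridError(f"window {window} selects fewer than two points")
        return ConcentrationSeries(self.times[m], self.values[m], self.label)


@dataclass(frozen=True)
class EmissionSchedule:
    """Piecewise-constant source strength S(t) in particles per minute.

    ``rates[i]`` applies over the step ``[times[i], times[i] + dt)``.  Raw
    deconvolved schedules may contain negative rates (measurement noise) and
    a NaN at the first step, where the backward difference is undefined; a
    schedule marked ``physical`` asserts non-negative, finite rates.
    """

    times: np.ndarray
    rates: np.ndarray
    physical: bool = False

    def __post_init__(self):
        t = _as_grid(self.times)
        r = np.asarray(self.rates, dtype=float)
        if r.shape != t.shape:
            raise GridError("times and rates must have the same length")
        if self.physical and (np.any(~np.isfinite(r)) or np.any(r < 0)):
            raise DomainError("a physical schedule requires finite rates >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rates", r)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def clipped(self) -> "EmissionSchedule":
        """Non-negative view: negatives -> 0, NaN -> 0, marked physical."""
        r = np.where(np.isfinite(self.rates), np.clip(self.rates, 0.0, None), 0.0)
        return EmissionSchedule(self.times, r, physical=True)

    @staticmethod
    def constant(times, rate: float) -> "EmissionSchedule":
        t = _as_grid(times)
        return EmissionSchedule(t, np.full_like(t, float(rate)))


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Room geometry, ventilation and background for the one-box model.

    Exactly one of ``flow``/``ach`` may be omitted; the other is derived via
    ACH = Q/V.  If both are given they must agree to 1e-6 relative.

    Attributes
    ----------
    volume : float
        Room volume in m^3.
    flow : float, optional
        Ventilation volume flow Q in m^3 h^-1.
    ach : float, optional
        Air changes per hour, h^-1.
    background : float or ConcentrationSeries
        Concentration of the incoming air N_BG in cm^-3 (the background enters
        the balance as inflow ``lambda * N_BG``, not as an additive offset).
    dt : float
        Model time step in minutes (default 1, the instrument log resolution).
    """

    volume: float
    flow: Optional[float] = None
    ach: Optional[float] = None
    background: Union[float, ConcentrationSeries] = 0.0
    dt: float = 1.0

    def __post_init__(self):
        if not self.volume > 0:
            raise ConfigurationError("room volume must be > 0")
        if not self.dt > 0:
            raise ConfigurationError("time step dt must be > 0")
        if self.flow is None and self.ach is None:
            raise ConfigurationError("provide ventilation flow or ACH")
        flow, ach = self.flow, self.ach
        if flow is None:
            flow = ach * self.volume
        elif ach is None:
            ach = flow / self.volume
        else:
            if ach > 0 and abs(ach - flow / self.volume) / ach >= 1e-6:
                raise ConfigurationError(
                    f"inconsistent ventilation: ACH={ach} but Q/V="
                    f"{flow / self.volume:.6g} h^-1"
                )
        if flow < 0:
            raise ConfigurationError("ventilation flow must be >= 0")
        object.__setattr__(self, "flow", float(flow))
        object.__setattr__(self, "ach", float(ach))

    @property
    def volume_cm3(self) -> float:
        return m3_to_cm3(self.volume)

    @property
    def flow_cm3min(self) -> float:
        return flow_m3h_to_cm3min(self.flow)

    @property
    def loss_rate(self) -> float:
        """Total first-order particle loss rate lambda in min^-1 (= ACH/60)."""
        return ach_to_loss_rate(self.ach)

    def background_on(self, times: np.ndarray) -> np.ndarray:
        """Background concentration sampled on a model grid."""
        if isinstance(self.background, ConcentrationSeries):
            if not _same_grid(self.background.times, np.asarray(times, float)):
                raise GridError("background series grid does not match model grid")
            return self.background.values
        bg = float(self.background)
        if bg < 0:
            raise DomainError("background concentration must be >= 0")
        return np.full(np.asarray(times).shape, bg)

    def with_ach(self, ach: float) -> "Scenario":
        """Same room under a different air-exchange regime (e.g. doors open)."""
        return replace(self, ach=float(ach), flow=None)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def simulate_one_box(
    scenario: Scenario,
    emissions: EmissionSchedule,
    n0: Optional[float] = None,
) -> ConcentrationSeries:
    """Integrate the one-box balance over the schedule's grid.

    Each step uses the exact solution for piecewise-constant inputs,

        N(t+dt) = N* + (N(t) - N*) * exp(-lambda*dt),
        N*      = N_BG(t) + S(t) / (lambda * V),

    so the result is unbiased regardless of ``lambda*dt``.  With ``S == 0``
    and constant background the output relaxes monotonically toward N_BG.

    Parameters
    ----------
    scenario
        Room, ventilation and background definition.
    emissions
        Source schedule; its grid is the output grid and must use the
        scenario's ``dt``.
    n0
        Initial concentration in cm^-3.  Defaults to the background value at
        the first step.
    """
    times = emissions.times
    if not np.isclose(emissions.dt, scenario.dt, rtol=1e-6):
        raise GridError(
            f"schedule step {emissions.dt} min != scenario dt {scenario.dt} min"
        )
    lam = scenario.loss_rate
    rates = np.nan_to_num(emissions.rates, nan=0.0)
    if lam <= 0 and np.any(rates != 0):
        raise ConfigurationError(
            "non-positive loss rate with a nonzero source: concentration "
            "grows without bound"
        )
    bg = scenario.background_on(times)
    if n0 is None:
        n0 = float(bg[0])
    if n0 < 0:
        raise DomainError("initial concentration must be >= 0")

    n = np.empty_like(times)
    n[0] = n0
    if lam <= 0:
        # No ventilation and (checked above) no source: nothing changes.
        n[:] = n0
        return ConcentrationSeries(times, n, label="modeled")

    dt = scenario.dt
    decay = np.exp(-lam * dt)
    lam_v = lam * scenario.volume_cm3
    for i in range(times.size - 1):
        n_star = bg[i] + rates[i] / lam_v
        n[i + 1] = n_star + (n[i] - n_star) * decay
    return ConcentrationSeries(times, n, label="modeled")


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayFit:
    """Log-linear fit N(t) = N0 * exp(-gamma * t) over a window.

    ``increasing`` flags windows whose concentration trends upward (gamma < 0);
    that is reported, not raised, because noisy near-background windows do it
    routinely.
    """

    gamma: float
    n0: float
    r2: float
    window: Tuple[float, float]
    increasing: bool = False


def fit_decay(
    series: ConcentrationSeries,
    window: Optional[Tuple[float, float]] = None,
    floor: float = 0.0,
) -> DecayFit:
    """Fit the first-order decay rate from a source-off segment.

    Ordinary least squares of ``ln N`` on ``t``; ``gamma`` is minus the slope.
    The fit assumes decay toward zero, i.e. the background contribution is
    negligible against the window's concentrations (or has been subtracted).

    Parameters
    ----------
    series
        Concentration series containing the decay.
    window
        ``(t0, t1)`` span in minutes (half-open); default: the whole series.
    floor
        All window values must exceed this concentration (>= 0); guards
        against taking logs at or below the instrument noise floor.
    """
    if window is None:
        window = (float(series.times[0]), float(series.times[-1]) + series.dt)
    m = series.window_mask(window)
    t = series.times[m]
    v = series.values[m]
    if t.size < 3:
        raise DomainError("decay window must contain at least 3 points")
    if floor < 0:
        raise DomainError("floor must be >= 0")
    if np.any(v <= floor) or np.any(v <= 0):
        raise DomainError("decay window contains values at or below the floor")

    logv = np.log(v)
    if np.allclose(logv, logv[0], rtol=0, atol=1e-15):
        # Constant series: zero decay, the constant model fits perfectly.
        return DecayFit(0.0, float(v[0]), 1.0, window)
    res = stats.linregress(t, logv)
    gamma = -float(res.slope)
    n0 = float(np.exp(res.intercept))
    r2 = float(res.rvalue**2)
    return DecayFit(gamma, n0, r2, window, increasing=gamma < 0)
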