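"""Model-performance evaluation: significance, ratios, RMSLE, percentiles.

A spraying period raises exposure significantly when its mean concentration
exceeds BG + 3*sigma_BG.  Modeled and measured activity means are compared as
a plain ratio, and full series via the root mean squared logarithmic error

    RMSLE = sqrt( mean_t (ln N_mod(t) - ln N_meas(t))^2 )

which penalizes the ratio of change rather than absolute differences — the
appropriate metric when concentrations span decades.  Both ratio and RMSLE
are compared against the 0.5–2 model-performance benchmark commonly used for
indoor exposure models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .emission import BackgroundEstimate
from .massbalance import ConcentrationSeries

__all__ = [
    "BENCHMARK",
    "EvaluationReport",
    "significance",
    "mean_ratio",
    "rmsle",
    "summarize_distribution",
]

#: Model-performance benchmark band (applied to both ratio and RMSLE).
BENCHMARK = (0.5, 2.0)

PERCENTILES = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-shift, per-method comparison of modeled against measured exposure."""

    shift_id: str
    method: str
    modeled_mean: float
    measured_mean: float
    ratio: float
    rmsle: float
    significant: bool
    benchmark_flags: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.rmsle < 0:
            raise DomainError("RMSLE must be >= 0")


def significance(activity_mean: float, bg: BackgroundEstimate) -> bool:
    """Did the activity raise exposure beyond background variability?

    True iff mean concentration during spraying > BG + 3 * sigma_BG.
    """
    return activity_mean > bg.mean + 3.0 * bg.sd


def _mean(x: Union[float, ConcentrationSeries]) -> float:
    return x.mean() if isinstance(x, ConcentrationSeries) else float(x)


def mean_ratio(
    modeled: Union[float, ConcentrationSeries],
    measured: Union[float, ConcentrationSeries],
) -> float:
    """Ratio of modeled to measured activity-window mean concentrations."""
    meas = _mean(measured)
    if not meas > 0:
        raise DomainError("measured mean must be > 0 to form a ratio")
    return _mean(modeled) / meas


def rmsle(
    modeled: Union[np.ndarray, ConcentrationSeries],
    measured: Union[np.ndarray, ConcentrationSeries],
    base: Optional[float] = None,
) -> float:
    """Root mean squared logarithmic error between aligned series.

    Natural log by default, with no "+1" offset: number concentrations are
    orders of magnitude above 1 cm^-3, so the offset would be pure noise.
    ``base`` switches the log base (e.g. 10) for comparison with conventions
    that report decadic errors.  Symmetric in its arguments; zero iff the
    series are identical.
    """
    a = modeled.values if isinstance(modeled, ConcentrationSeries) else np.asarray(modeled, float)
    b = measured.values if isinstance(measured, ConcentrationSeries) else np.asarray(measured, float)
    if a.shape != b.shape:
        raise DomainError("modeled and measured series must be aligned")
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError("RMSLE requires strictly positive concentrations")
    err = np.log(a) - np.log(b)
    if base is not None:
        err = err / np.log(base)
    return float(np.sqrt(np.mean(err**2)))


def summarize_distribution(values: Sequence[float]) -> Dict[str, float]:
    """Box-plot style percentile summary of a set of evaluation metrics.

    Returns the 10th/25th/50th/75th/90th percentiles (median under both
    ``"p50"`` and ``"median"``), using linear interpolation between order
    statistics — the common box-plot convention.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ConfigurationError("cannot summarize an empty set of values")
    out = {f"p{p}": float(np.percentile(v, p)) for p in PERCENTILES}
    out["median"] = out["p50"]
    return out


def evaluate_shift(
    shift_id: str,
    method: str,
    modeled: ConcentrationSeries,
    measured: ConcentrationSeries,
    activity_mask: np.ndarray,
    bg: BackgroundEstimate,
) -> EvaluationReport:
    """Build the per-shift report from aligned modeled and measured series.

    Means, ratio and RMSLE are computed over the activity-labeled steps of
    the shift; significance tests the *measured* activity mean against the
    background.
    """
    if not activity_mask.any():
        raise ConfigurationError(f"shift {shift_id!r} has no activity steps")
    mod = modeled.values[activity_mask]
    meas = measured.values[activity_mask]
    modeled_mean = float(mod.mean())
    measured_mean = float(meas.mean())
    r = mean_ratio(modeled_mean, measured_mean)
    e = rmsle(mod, meas)
    lo, hi = BENCHMARK
    return EvaluationReport(
        shift_id=shift_id,
        method=method,
        modeled_mean=modeled_mean,
        measured_mean=measured_mean,
        ratio=r,
        rmsle=e,
        significant=significance(measured_mean, bg),
        benchmark_flags={"ratio": lo <= r <= hi, "rmsle": lo <= e <= hi},
    )
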