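"""First-order thermal-inactivation kinetics.

Residual enzyme activity after heating for time t at a fixed temperature is
modelled as A(t) = A0 * exp(-kd * t): irreversible first-order loss with
deactivation rate constant kd (min^-1).  kd is estimated by ordinary least
squares of ln(residual fraction) on time, and two derived times summarize
it: the half-life t1/2 = ln2/kd (time to 50 % activity) and the decimal
reduction time D = ln10/kd (time to 10 %).  Their ratio D/t1/2 = log2(10)
is a constant of the model, which makes printed (t1/2, D) pairs checkable
for internal consistency.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "ThermalSeries",
    "DecayFit",
    "PairConsistency",
    "KELVIN_OFFSET",
    "fit_first_order_decay",
    "half_life",
    "d_value",
    "half_life_from_d_value",
    "d_value_from_half_life",
    "check_half_life_d_value",
    "summarize_inactivation",
]

logger = logging.getLogger(__name__)

KELVIN_OFFSET = 273.15

#: D-value / half-life under first-order kinetics, ln10/ln2 = log2(10).
D_TO_HALF_LIFE_RATIO = math.log(10.0) / math.log(2.0)


@dataclass(frozen=True)
class ThermalSeries:
    """A residual-activity time course at one temperature (or pH) level.

    ``residual_activity`` is in percent of the unheated control; times are
    minutes and must be strictly increasing.  Points with non-positive
    activity are tolerated at construction and excluded (with a warning)
    from the logarithmic fit.
    """

    level: float
    times_min: tuple[float, ...]
    residual_activity: tuple[float, ...]
    form: str = "free"
    level_kind: str = "temperature_C"  # or "pH"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_min", tuple(float(t) for t in self.times_min))
        object.__setattr__(
            self, "residual_activity",
            tuple(float(a) for a in self.residual_activity))
        if len(self.times_min) != len(self.residual_activity):
            raise ValidationError("times_min and residual_activity lengths differ")
        if any(not math.isfinite(t) for t in self.times_min):
            raise ValidationError("times_min contains non-finite values")
        if any(not math.isfinite(a) for a in self.residual_activity):
            raise ValidationError("residual_activity contains non-finite values")
        if any(t < 0 for t in self.times_min):
            raise ValidationError("times_min must be >= 0")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValidationError("times_min must be strictly increasing")
        if self.form not in ("free", "immobilized"):
            raise ValidationError(
                f"form must be 'free' or 'immobilized', got {self.form!r}")

    @property
    def temperature_K(self) -> float:
        """Level converted to Kelvin (only meaningful for temperature series)."""
        return self.level + KELVIN_OFFSET


@dataclass(frozen=True)
class DecayFit:
    """A fitted first-order deactivation.

    ``kd`` is -slope of the ln(residual fraction) vs time regression; for a
    genuine decay the slope is negative and kd > 0.  ``half_life_min`` and
    ``d_value_min`` are ln2/kd and ln10/kd (NaN when the series does not
    decay).  ``decaying`` is False when the fitted slope is >= 0, which the
    caller must treat as "no measurable inactivation", not as a rate.
    """

    kd: float
    intercept: float
    r_squared: float
    half_life_min: float
    d_value_min: float
    n_points: int
    decaying: bool = True


def half_life(kd: float) -> float:
    """Half-life t1/2 = ln2/kd in minutes, for kd in min^-1."""
    if not math.isfinite(kd) or kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd!r}")
    return math.log(2.0) / kd


def d_value(kd: float) -> float:
    """Decimal reduction time D = ln10/kd in minutes, for kd in min^-1."""
    if not math.isfinite(kd) or kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd!r}")
    return math.log(10.0) / kd


def d_value_from_half_life(half_life_min: float) -> float:
    """Convert t1/2 to D via the model constant D = log2(10) * t1/2."""
    if not math.isfinite(half_life_min) or half_life_min <= 0:
        raise DomainError(f"half-life must be > 0, got {half_life_min!r}")
    return D_TO_HALF_LIFE_RATIO * half_life_min


def half_life_from_d_value(d_value_min: float) -> float:
    """Convert D to t1/2 via t1/2 = D / log2(10)."""
    if not math.isfinite(d_value_min) or d_value_min <= 0:
        raise DomainError(f"D-value must be > 0, got {d_value_min!r}")
    return d_value_min / D_TO_HALF_LIFE_RATIO


@dataclass(frozen=True)
class PairConsistency:
    """Consistency report for a reported (t1/2, D) pair.

    Under first-order kinetics both numbers derive from one kd, so
    D must equal log2(10) * t1/2.  ``deviation_min`` is the signed
    difference (reported D minus implied D) in minutes; ``consistent``
    is False when |deviation| exceeds ``tolerance_min``.  Printed tables
    rounded to whole minutes can legitimately deviate by up to ~2 min.
    """

    half_life_min: float
    d_value_min: float
    implied_d_value_min: float
    deviation_min: float
    tolerance_min: float
    consistent: bool


def check_half_life_d_value(half_life_min: float, d_value_min: float,
                            tolerance_min: float = 2.0) -> PairConsistency:
    """Check a reported (t1/2, D) pair against D = log2(10) * t1/2."""
    implied = d_value_from_half_life(half_life_min)
    if not math.isfinite(d_value_min) or d_value_min <= 0:
        raise DomainError(f"D-value must be > 0, got {d_value_min!r}")
    deviation = d_value_min - implied
    return PairConsistency(
        half_life_min=half_life_min,
        d_value_min=d_value_min,
        implied_d_value_min=implied,
        deviation_min=deviation,
        tolerance_min=tolerance_min,
        consistent=abs(deviation) <= tolerance_min,
    )


def fit_first_order_decay(series: ThermalSeries,
                          min_points: int = 3) -> DecayFit:
    """Fit ln(residual fraction) = intercept - kd * t by unweighted OLS.

    Residual activities are converted to fractions of the 100 % control
    before taking the natural log; a 0-minute point of 100 % enters the
    regression like any other (the intercept is not forced to 0).  Points
    with residual activity <= 0 cannot be logged and are dropped with a
    warning.  Fewer usable points than ``min_points`` triggers a warning;
    fewer than 2 is an error.  A non-negative fitted slope is reported as
    ``decaying=False`` with NaN half-life and D-value.

    Natural logarithms are used throughout so that kd feeds t1/2 = ln2/kd
    directly; a base-10 fit would only rescale the slope and yields
    identical half-lives.
    """
    t = np.asarray(series.times_min, dtype=float)
    a = np.asarray(series.residual_activity, dtype=float)
    usable = a > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "excluding %d non-positive residual-activity point(s) from log fit "
            "(form=%s, level=%s)", n_dropped, series.form, series.level)
    t, a = t[usable], a[usable]
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 points with positive residual activity, have {t.size}")
    if t.size < min_points:
        warnings.warn(
            f"fitting decay with only {t.size} points (< {min_points}); "
            "the fit has no redundancy", stacklevel=2)
    y = np.log(a / 100.0)
    res = stats.linregress(t, y)
    slope = float(res.slope)
    r2 = float(res.rvalue) ** 2
    kd = -slope
    decaying = slope < 0
    return DecayFit(
        kd=kd,
        intercept=float(res.intercept),
        r_squared=r2,
        half_life_min=half_life(kd) if decaying else math.nan,
        d_value_min=d_value(kd) if decaying else math.nan,
        n_points=int(t.size),
        decaying=decaying,
    )


def summarize_inactivation(series_set: Iterable[ThermalSeries],
                           min_points: int = 3) -> pd.DataFrame:
    """Fit every series and tabulate (form, level, kd, r2, t1/2, D).

    Rows are ordered by form then level.  Fit errors are re-raised with the
    identity of the offending series attached.  An empty input yields an
    empty table with the full column set and a warning.
    """
    columns = ["form", "level", "kd_per_min", "r_squared",
               "half_life_min", "d_value_min", "n_points", "decaying"]
    rows = []
    for series in series_set:
        try:
            fit = fit_first_order_decay(series, min_points=min_points)
        except (InsufficientDataError, ValidationError) as exc:
            raise type(exc)(
                f"series form={series.form!r} level={series.level!r}: {exc}"
            ) from exc
        rows.append({
            "form": series.form,
            "level": series.level,
            "kd_per_min": fit.kd,
            "r_squared": fit.r_squared,
            "half_life_min": fit.half_life_min,
            "d_value_min": fit.d_value_min,
            "n_points": fit.n_points,
            "decaying": fit.decaying,
        })
    if not rows:
        warnings.warn("summarize_inactivation received no series", stacklevel=2)
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(["form", "level"], kind="stable").reset_index(drop=True)


def series_from_frame(frame: pd.DataFrame, form_col: str = "form",
                      level_col: str = "temperature_C",
                      time_col: str = "time_min",
                      value_col: str = "residual_pct") -> list[ThermalSeries]:
    """Group a long-format stability table into one ThermalSeries per
    (form, level), preserving time order within each group."""
    out: list[ThermalSeries] = []
    for (form, level), grp in frame.groupby([form_col, level_col], sort=True):
        grp = grp.sort_values(time_col)
        out.append(ThermalSeries(
            level=float(level),
            times_min=tuple(grp[time_col].astype(float)),
            residual_activity=tuple(grp[value_col].astype(float)),
            form=str(form),
            level_kind=level_col,
        ))
    return out
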