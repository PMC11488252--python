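"""Arrhenius regressions for activation and deactivation energies.

A rate (or rate-like response) obeying k = A * exp(-E / (R T)) is linear in
Arrhenius coordinates: ln k = ln A - (E/R) * (1/T).  Ordinary least squares
of ln(response) on 1/T therefore estimates -E/R as the slope, and the
energy follows as E = -slope * R.

Two uses are distinguished only by what the response is:

* activation mode — response is enzyme activity or production on the
  rising limb of a temperature profile; the energy is the activation
  energy Ea of catalysis/production.
* deactivation mode — response is the first-order deactivation rate
  constant kd across temperatures; the energy is the deactivation
  (denaturation) energy Ed.  Higher Ed means the deactivation rate
  accelerates less with temperature, i.e. a sturdier catalyst.

One sign convention, E = -slope * R, serves both modes: any physically
increasing rate gives a negative slope against 1/T and hence a positive
energy.  A negative energy is reported with ``well_posed=False`` instead
of being silently returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .assay_units import ConditionProfile, normalize_profile
from .errors import InsufficientDataError, ValidationError
from .inactivation_kinetics import KELVIN_OFFSET

__all__ = [
    "GAS_CONSTANT",
    "ArrheniusPoint",
    "ArrheniusResult",
    "fit_arrhenius",
    "select_ascending_limb",
]

#: Molar gas constant R, J K^-1 mol^-1.
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class ArrheniusPoint:
    """One (temperature, response) point of an Arrhenius plot.

    ``response`` must be positive (its log is taken) and may be a relative
    activity in percent, a production in SU/ml, or a kd in min^-1 —
    the fitted energy does not depend on the response's scale.
    """

    temperature_K: float
    response: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature_K) or self.temperature_K <= 200:
            raise ValidationError(
                f"temperature_K must be a physical temperature > 200 K, "
                f"got {self.temperature_K!r}")
        if not math.isfinite(self.response) or self.response <= 0:
            raise ValidationError(
                f"response must be > 0 (its log is taken), got {self.response!r}")

    @classmethod
    def from_celsius(cls, temperature_C: float, response: float) -> "ArrheniusPoint":
        return cls(temperature_K=temperature_C + KELVIN_OFFSET, response=response)


@dataclass(frozen=True)
class ArrheniusResult:
    """A fitted Arrhenius line and the derived energy.

    ``slope_K`` is on the 1/T (K^-1) axis; plotting against 1000/T instead
    rescales the slope by exactly 1000 (``slope_per_1000K``) and leaves the
    energy unchanged.  ``energy_kJ_mol`` = -slope_K * R / 1000.
    """

    slope_K: float
    intercept: float
    energy_kJ_mol: float
    mode: str
    r_squared: float
    n_points: int
    well_posed: bool
    gas_constant: float = GAS_CONSTANT

    @property
    def slope_per_1000K(self) -> float:
        """Slope on the conventional 1000/T plotting axis."""
        return self.slope_K / 1000.0


def fit_arrhenius(points: Sequence[ArrheniusPoint],
                  mode: str = "deactivation") -> ArrheniusResult:
    """OLS of ln(response) on 1/T (K^-1) and the implied energy in kJ/mol.

    ``mode`` is "activation" (Ea from activity/production) or
    "deactivation" (Ed from kd); both use energy = -slope * R, so a
    response that grows with temperature yields a positive energy.
    Requires >= 2 points at distinct temperatures.
    """
    if mode not in ("activation", "deactivation"):
        raise ValidationError(
            f"mode must be 'activation' or 'deactivation', got {mode!r}")
    points = list(points)
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >= 2 Arrhenius points, have {len(points)}")
    temps = np.array([p.temperature_K for p in points], dtype=float)
    if np.unique(temps).size < len(points):
        raise InsufficientDataError(
            "Arrhenius points must be at distinct temperatures")
    y = np.log([p.response for p in points])
    res = stats.linregress(1.0 / temps, y)
    slope = float(res.slope)
    energy = -slope * GAS_CONSTANT / 1000.0
    return ArrheniusResult(
        slope_K=slope,
        intercept=float(res.intercept),
        energy_kJ_mol=energy,
        mode=mode,
        r_squared=float(res.rvalue) ** 2,
        n_points=len(points),
        well_posed=energy > 0,
    )


def select_ascending_limb(profile: ConditionProfile) -> list[ArrheniusPoint]:
    """Points on the rising limb of an activity-temperature profile.

    Activity below the optimum temperature is rate-limited and Arrhenius-
    like; above it, denaturation dominates and the points no longer follow
    the activation law.  This selects the records at temperatures <= the
    optimum (first maximum on ties, so a plateau contributes only its
    first temperature and the limb stays monotone) whose activity is
    positive, converted to Kelvin.  Condition labels must be numeric
    temperatures in Celsius.
    """
    norm = normalize_profile(profile)
    try:
        temps = [float(lbl) for lbl in norm.labels]
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            "ascending-limb selection needs numeric temperature labels") from exc
    optimum = float(norm.optimum)
    limb = [ArrheniusPoint.from_celsius(t, rec.activity)
            for t, rec in zip(temps, norm.records)
            if t <= optimum and rec.activity > 0]
    if len(limb) < 2:
        raise InsufficientDataError(
            f"ascending limb has {len(limb)} point(s); need >= 2 "
            "(is the optimum at the first temperature?)")
    return limb


def points_from_decay_summary(summary, form: str | None = None) -> list[ArrheniusPoint]:
    """Build (T, kd) Arrhenius points from an inactivation summary table.

    ``summary`` is the DataFrame produced by ``summarize_inactivation``
    with levels in Celsius; optionally restricted to one form.
    """
    frame = summary if form is None else summary[summary["form"] == form]
    return [ArrheniusPoint.from_celsius(float(row.level), float(row.kd_per_min))
            for row in frame.itertuples()]
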