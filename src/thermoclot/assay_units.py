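"""Unit-level statistics for milk-clotting assays.

Covers the Soxhlet-unit activity statistic computed from a clotting time,
normalization of activity profiles to a 100 % optimum, the milk-clotting to
general-protease activity ratio used to judge cheese-making suitability,
cell-leakage percentage from culture-filtrate optical densities, and
reuse-cycle retention for immobilized biocatalysts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import DegenerateProfileError, DomainError, ValidationError

__all__ = [
    "ClottingAssay",
    "ActivityRecord",
    "ConditionProfile",
    "ReuseSeries",
    "LeakageResult",
    "compute_soxhlet_units",
    "mca_pa_ratio",
    "leakage_percent",
    "normalize_profile",
    "reuse_retention",
]


@dataclass(frozen=True)
class ClottingAssay:
    """One milk-clotting measurement.

    A Soxhlet unit (SU) is the amount of enzyme that clots 1 ml of a
    standard skim-milk/CaCl2 solution in 40 min (2400 s) at 35 °C.  The
    assay adds ``enzyme_volume_ml`` of (possibly diluted) test material to
    ``milk_volume_ml`` of milk and records the clotting time T in seconds.

    Parameters
    ----------
    clotting_time_s:
        Time from enzyme addition to first visible clot, seconds (> 0).
    dilution:
        Dilution factor D of the test material (>= 1; 1 = undiluted).
    milk_volume_ml:
        Volume of milk substrate, default 5 ml.
    enzyme_volume_ml:
        Volume of test material added, default 0.5 ml.
    reference_time_s:
        The 40-minute reference clotting time defining one SU, 2400 s.
    """

    clotting_time_s: float
    dilution: float = 1.0
    milk_volume_ml: float = 5.0
    enzyme_volume_ml: float = 0.5
    reference_time_s: float = 2400.0

    def __post_init__(self) -> None:
        for name in ("clotting_time_s", "milk_volume_ml",
                     "enzyme_volume_ml", "reference_time_s"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {value!r}")
        if not math.isfinite(self.dilution) or self.dilution < 1:
            raise ValidationError(f"dilution must be >= 1, got {self.dilution!r}")


def compute_soxhlet_units(assay: ClottingAssay) -> float:
    """Milk-clotting activity in Soxhlet units per ml of test material.

    SU/ml = (reference_time_s x milk_volume_ml x D) / (T x enzyme_volume_ml),
    which at the default volumes reduces to 24000 * D / T.

    The grouping places the enzyme volume in the denominator.  A literal
    left-to-right reading of the conventional one-line formula
    (2400 x 5 x D/T x 0.5) would give 6000 * D / T, which fails the unit's
    own definitional check: 0.5 ml of material holding 5 SU clots 5 ml of
    milk in exactly 40 min, so an undiluted sample with T = 2400 s must
    score 10 SU/ml.  Only the 24000 * D / T grouping satisfies it.
    """
    return (assay.reference_time_s * assay.milk_volume_ml * assay.dilution) / (
        assay.clotting_time_s * assay.enzyme_volume_ml
    )


def mca_pa_ratio(mca: float, pa: float) -> float:
    """Ratio of milk-clotting activity to general protease activity.

    A high ratio is desirable for cheese making: the enzyme clots milk
    without digesting the curd.  ``mca`` is in SU/ml, ``pa`` in protease
    assay units per ml; the ratio is dimensionless and conventionally
    reported to the nearest integer.
    """
    if not math.isfinite(pa) or pa <= 0:
        raise DomainError(f"protease activity must be > 0, got {pa!r}")
    if not math.isfinite(mca) or mca < 0:
        raise ValidationError(f"milk-clotting activity must be >= 0, got {mca!r}")
    return mca / pa


@dataclass(frozen=True)
class LeakageResult:
    """Cell-leakage percentage with an out-of-range flag.

    ``percent`` may be negative when the immobilized-culture filtrate is
    denser than the free-culture filtrate (measurement noise); such values
    are reported with ``out_of_range=True`` rather than clamped or refused.
    """

    percent: float
    out_of_range: bool = False


def leakage_percent(od_immobilized_filtrate: float,
                    od_free_filtrate: float) -> LeakageResult:
    """Percent of cells retained by the beads, from filtrate turbidity.

    Computed as 100 - 100 * OD_immobilized / OD_free: the optical density of
    the immobilized-cell culture filtrate relative to that of free cells
    measures how much biomass escaped the alginate beads.
    """
    if not math.isfinite(od_free_filtrate) or od_free_filtrate <= 0:
        raise DomainError(
            f"od_free_filtrate must be > 0, got {od_free_filtrate!r}")
    if not math.isfinite(od_immobilized_filtrate) or od_immobilized_filtrate < 0:
        raise ValidationError(
            f"od_immobilized_filtrate must be >= 0, got {od_immobilized_filtrate!r}")
    pct = 100.0 - 100.0 * od_immobilized_filtrate / od_free_filtrate
    return LeakageResult(percent=pct, out_of_range=pct < 0)


@dataclass(frozen=True)
class ActivityRecord:
    """Activity at one level of a swept condition (temperature, pH, medium
    component, ...).

    ``spread`` holds the reported dispersion (e.g. a printed "±" value) and
    is carried along but never propagated through computations.
    """

    condition_label: object
    activity: float
    spread: float | None = None
    form: str = "free"

    def __post_init__(self) -> None:
        if not math.isfinite(self.activity) or self.activity < 0:
            raise ValidationError(f"activity must be >= 0, got {self.activity!r}")
        if self.spread is not None and (not math.isfinite(self.spread) or self.spread < 0):
            raise ValidationError(f"spread must be >= 0, got {self.spread!r}")
        if self.form not in ("free", "immobilized"):
            raise ValidationError(
                f"form must be 'free' or 'immobilized', got {self.form!r}")


@dataclass(frozen=True)
class ConditionProfile:
    """Ordered activities across one swept variable, e.g. temperature.

    After :func:`normalize_profile`, ``normalized`` holds percentages of the
    maximum (the optimum condition scores exactly 100) and ``optimum`` the
    condition label of the first maximum.
    """

    records: tuple[ActivityRecord, ...]
    variable: str = "condition"
    normalized: tuple[float, ...] | None = None
    optimum: object | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("profile must contain at least one record")
        if self.normalized is not None:
            object.__setattr__(self, "normalized", tuple(self.normalized))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[object, float]],
                   variable: str = "condition",
                   form: str = "free") -> "ConditionProfile":
        records = tuple(ActivityRecord(condition_label=lbl, activity=act, form=form)
                        for lbl, act in pairs)
        return cls(records=records, variable=variable)

    @property
    def activities(self) -> tuple[float, ...]:
        return tuple(r.activity for r in self.records)

    @property
    def labels(self) -> tuple[object, ...]:
        return tuple(r.condition_label for r in self.records)


def normalize_profile(profile: ConditionProfile) -> ConditionProfile:
    """Express each activity as a percentage of the profile maximum.

    The condition with the highest activity is the optimum and is assigned
    100 %; on ties the first occurrence wins (so a plateau reports the
    lower temperature as the optimum).  Normalization preserves rank order
    and is idempotent up to floating-point identity.
    """
    acts = profile.activities
    peak = max(acts)
    if peak <= 0:
        raise DegenerateProfileError(
            "cannot normalize a profile whose activities are all zero")
    # divide before scaling so the maximum maps to exactly 100.0
    normalized = tuple(100.0 * (a / peak) for a in acts)
    optimum = profile.labels[acts.index(peak)]
    return replace(profile, normalized=normalized, optimum=optimum)


@dataclass(frozen=True)
class ReuseSeries:
    """Per-cycle enzyme production of a reused immobilized biocatalyst.

    ``retention`` is each cycle's production as a percent of cycle 1;
    cycle 1 is therefore 100 by construction.
    """

    cycle: tuple[int, ...]
    production: tuple[float, ...]
    retention: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycle", tuple(int(c) for c in self.cycle))
        object.__setattr__(self, "production", tuple(float(p) for p in self.production))
        object.__setattr__(self, "retention", tuple(float(r) for r in self.retention))
        if len(self.cycle) != len(self.production):
            raise ValidationError("cycle and production must have equal length")
        if any(c < 1 for c in self.cycle):
            raise ValidationError("cycle indices must be positive")
        if any(not math.isfinite(p) or p < 0 for p in self.production):
            raise ValidationError("productions must be finite and >= 0")


def reuse_retention(productions: Sequence[float]) -> ReuseSeries:
    """Retention of enzyme production across reuse cycles.

    retention_c = 100 * production_c / production_1.  The first cycle must
    have positive production; retention is invariant to rescaling all
    productions by a positive constant.
    """
    productions = [float(p) for p in productions]
    if not productions:
        raise ValidationError("reuse series is empty")
    if productions[0] <= 0:
        raise ValidationError(
            f"cycle-1 production must be > 0, got {productions[0]!r}")
    retention = tuple(100.0 * p / productions[0] for p in productions)
    return ReuseSeries(
        cycle=tuple(range(1, len(productions) + 1)),
        production=tuple(productions),
        retention=retention,
    )
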