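"""Synthetic inputs for every stage of the pipeline.

Generates thermal-inactivation time courses whose rate constants follow an
Arrhenius law (or are given explicitly), reuse-cycle production series with
a plateau followed by geometric decline, and clotting-time assays inverted
from a known activity — each with optional, seeded measurement noise — so
that every estimator in the package can be validated by parameter recovery
without any external data.

All generators take an explicit seed and use an independent
``numpy.random.Generator`` per call; identical (config, seed) pairs produce
bit-identical output.

The default noise model is multiplicative lognormal: activity measurements
are positive and their reported dispersions scale roughly with the mean,
which is the signature of multiplicative rather than additive error.
Additive Gaussian noise is provided for robustness testing; it can drive
residual activities to or below zero, in which case the affected values
are floored at a small positive epsilon and the series is flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assay_units import ClottingAssay, ReuseSeries
from .errors import ValidationError
from .inactivation_kinetics import KELVIN_OFFSET, ThermalSeries
from .arrhenius_thermo import GAS_CONSTANT

__all__ = [
    "SimulationConfig",
    "arrhenius_kd",
    "generate_thermal_series",
    "generate_reuse_series",
    "generate_clotting_times",
]

logger = logging.getLogger(__name__)

NOISE_MODELS = ("none", "multiplicative_lognormal", "additive_gaussian")

#: Floor applied when additive noise drives a residual activity <= 0 (%).
ACTIVITY_FLOOR_PCT = 1e-6

#: Default heating design: 25-60 degC in 5 degC steps, 0-60 min in 15 min steps.
DEFAULT_TEMPERATURES_C = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0)
DEFAULT_TIMES_MIN = (0.0, 15.0, 30.0, 45.0, 60.0)


def arrhenius_kd(temperature_C: float, pre_exponential_per_min: float,
                 energy_kJ_mol: float) -> float:
    """kd(T) = A * exp(-E / (R T)) with T in Celsius, E in kJ/mol."""
    T = temperature_C + KELVIN_OFFSET
    return pre_exponential_per_min * math.exp(
        -energy_kJ_mol * 1000.0 / (GAS_CONSTANT * T))


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a simulated thermal-stability experiment.

    Either ``kd_by_temperature`` maps each temperature (degC) to an explicit
    rate constant (min^-1), or ``arrhenius_A`` (min^-1) and ``arrhenius_E``
    (kJ/mol) define a law from which kd is computed at every temperature;
    exactly one of the two must be given.

    ``noise_sd`` is the sigma of the ln-scale perturbation for
    multiplicative lognormal noise, or in percent-activity units for
    additive Gaussian noise.
    """

    temperatures_C: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    times_min: tuple[float, ...] = DEFAULT_TIMES_MIN
    kd_by_temperature: Mapping[float, float] | None = None
    arrhenius_A: float | None = None
    arrhenius_E: float | None = None
    noise_model: str = "none"
    noise_sd: float = 0.0
    seed: int = 0
    n_replicates: int = 1
    form: str = "free"

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures_C",
                           tuple(float(t) for t in self.temperatures_C))
        object.__setattr__(self, "times_min",
                           tuple(float(t) for t in self.times_min))
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}")
        if not math.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if any(t < 0 for t in self.times_min):
            raise ValidationError("times_min must be >= 0")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValidationError("times_min must be strictly increasing")
        have_law = self.arrhenius_A is not None and self.arrhenius_E is not None
        have_map = self.kd_by_temperature is not None
        if have_law == have_map:
            raise ValidationError(
                "give either kd_by_temperature or (arrhenius_A, arrhenius_E)")
        if have_law and (self.arrhenius_A <= 0 or self.arrhenius_E <= 0):
            raise ValidationError("arrhenius_A and arrhenius_E must be > 0")
        if have_map:
            missing = [t for t in self.temperatures_C
                       if t not in self.kd_by_temperature]
            if missing:
                raise ValidationError(
                    f"kd_by_temperature lacks entries for temperatures {missing}")
            if any(k <= 0 for k in self.kd_by_temperature.values()):
                raise ValidationError("all kd values must be > 0")

    def kd_at(self, temperature_C: float) -> float:
        if self.kd_by_temperature is not None:
            return float(self.kd_by_temperature[temperature_C])
        return arrhenius_kd(temperature_C, self.arrhenius_A, self.arrhenius_E)


def _apply_noise(values: np.ndarray, model: str, sd: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Return noisy values and whether any were floored."""
    if model == "none" or sd == 0.0:
        return values, False
    if model == "multiplicative_lognormal":
        return values * np.exp(rng.normal(0.0, sd, size=values.shape)), False
    # additive_gaussian, in percent units
    noisy = values + rng.normal(0.0, sd, size=values.shape)
    floored = bool(np.any(noisy <= 0))
    if floored:
        noisy = np.maximum(noisy, ACTIVITY_FLOOR_PCT)
    return noisy, floored


def generate_thermal_series(config: SimulationConfig) -> list[ThermalSeries]:
    """Simulate residual-activity time courses, one (or n_replicates) per
    temperature.

    The noiseless signal is residual(t) = 100 * exp(-kd * t) percent.
    Output order is: temperatures in the configured order, replicates
    innermost.  Deterministic for a fixed config (the seed is part of it).
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times_min, dtype=float)
    out: list[ThermalSeries] = []
    for temp in config.temperatures_C:
        kd = config.kd_at(temp)
        clean = 100.0 * np.exp(-kd * times)
        for _ in range(config.n_replicates):
            noisy, floored = _apply_noise(clean, config.noise_model,
                                          config.noise_sd, rng)
            if floored:
                logger.warning(
                    "additive noise drove residual activity <= 0 at %s degC; "
                    "values floored at %g %%", temp, ACTIVITY_FLOOR_PCT)
            out.append(ThermalSeries(
                level=temp,
                times_min=tuple(times),
                residual_activity=tuple(noisy),
                form=config.form,
            ))
    return out


def generate_reuse_series(initial: float, plateau_cycles: int,
                          per_cycle_decline: float, n_cycles: int,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> ReuseSeries:
    """Simulate per-cycle enzyme production of reused immobilized beads.

    Production stays at ``initial`` through ``plateau_cycles`` cycles, then
    declines geometrically by ``per_cycle_decline`` per cycle:
    production_c = initial * (1 - decline)^(c - plateau) for c > plateau.
    Optional multiplicative lognormal noise (sigma ``noise_sd`` on the
    ln scale) is applied per cycle.
    """
    if not math.isfinite(initial) or initial <= 0:
        raise ValidationError(f"initial production must be > 0, got {initial!r}")
    if not 0.0 <= per_cycle_decline < 1.0:
        raise ValidationError(
            f"per_cycle_decline must be in [0, 1), got {per_cycle_decline!r}")
    if plateau_cycles < 0:
        raise ValidationError("plateau_cycles must be >= 0")
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    cycles = np.arange(1, n_cycles + 1)
    decayed = np.maximum(cycles - max(plateau_cycles, 1), 0)
    production = initial * (1.0 - per_cycle_decline) ** decayed
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        production = production * np.exp(rng.normal(0.0, noise_sd, size=n_cycles))
    retention = 100.0 * production / production[0]
    return ReuseSeries(cycle=tuple(int(c) for c in cycles),
                       production=tuple(production),
                       retention=tuple(retention))


def generate_clotting_times(true_su_per_ml: float,
                            dilutions: Sequence[float],
                            noise_sd: float = 0.0,
                            seed: int = 0) -> list[ClottingAssay]:
    """Invert the Soxhlet-unit formula to simulate clotting assays.

    For a sample of true activity SU (per ml) measured at dilution D with
    the default volumes, the noiseless clotting time is T = 24000 * D / SU
    seconds; multiplicative lognormal noise (sigma ``noise_sd``) perturbs T.
    Feeding the noiseless output to ``compute_soxhlet_units`` recovers the
    true activity exactly.
    """
    if not math.isfinite(true_su_per_ml) or true_su_per_ml <= 0:
        raise ValidationError(
            f"true_su_per_ml must be > 0, got {true_su_per_ml!r}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    assays = []
    for d in dilutions:
        d = float(d)
        t = 24000.0 * d / true_su_per_ml
        if noise_sd > 0:
            t *= math.exp(rng.normal(0.0, noise_sd))
        assays.append(ClottingAssay(clotting_time_s=t, dilution=d))
    return assays
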