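"""Thermoluminescent-dosimeter reading reduction.

A raw chip reading becomes a dose rate per unit air-kerma strength through

    D(r,θ)/SK = R_net(r,θ) / (t_eff · SK · ε_λ · E(r,θ))

where R_net is the background-subtracted, sensitivity-normalized reading,
t_eff the decay-corrected effective exposure time, ε_λ the reader calibration
factor from a Co-60 reference beam (dose per reader unit) and E(r,θ) an
optional relative energy/position response correction.  Replicate chips at
the same position are averaged; the type-A uncertainty reported per position
is the relative sample standard deviation of a single reading (k = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CalibrationError, DomainError, ValidationError

__all__ = [
    "ChipReading",
    "TLDReadingSet",
    "CalibrationSet",
    "UncertaintyBudget",
    "ReducedDose",
    "sensitivity_factors",
    "effective_exposure_time",
    "reduce",
    "combine_uncertainty",
    "PD103_HALF_LIFE_DAYS",
]

PD103_HALF_LIFE_DAYS = 16.991  # commonly rounded to 17 d

_POS_DECIMALS = 6  # positions matched after rounding to this many decimals


@dataclass(frozen=True)
class ChipReading:
    """One raw TLD reading at polar position (r cm, θ degrees)."""

    chip_id: str
    r: float
    theta: float
    reading: float


@dataclass
class TLDReadingSet:
    """Raw chip readings from one exposure, plus background chips.

    ``exposure_hours`` is the wall-clock exposure duration T.
    """

    readings: Sequence[ChipReading]
    background_readings: Sequence[float]
    exposure_hours: float
    exposure_start: str | None = None

    def __post_init__(self) -> None:
        v: list[str] = []
        if any(c.reading < 0 for c in self.readings):
            v.append("raw readings must be >= 0")
        if any(b < 0 for b in self.background_readings):
            v.append("background readings must be >= 0")
        if not self.exposure_hours > 0:
            v.append(f"exposure_hours must be > 0, got {self.exposure_hours}")
        if v:
            raise ValidationError(v)


@dataclass
class CalibrationSet:
    """Everything needed to turn reader units into dose.

    ``sensitivity`` maps chip id → relative sensitivity factor (batch mean 1);
    ``energy_response`` maps rounded (r, θ) → unitless E(r,θ), defaulting to 1
    everywhere when no table is supplied.  ``type_b_components`` lists
    (label, relative %) systematic contributions.
    """

    epsilon_lambda: float
    sensitivity: Mapping[str, float]
    energy_response: Mapping[tuple[float, float], float] | None = None
    type_b_components: Sequence[tuple[str, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        v: list[str] = []
        if not self.epsilon_lambda > 0:
            v.append(f"epsilon_lambda must be > 0, got {self.epsilon_lambda}")
        factors = list(self.sensitivity.values())
        if factors:
            if any(f <= 0 for f in factors):
                v.append("sensitivity factors must be > 0")
            elif abs(float(np.mean(factors)) - 1.0) > 1e-6:
                v.append(f"sensitivity batch mean {np.mean(factors)!r} differs from 1")
        if self.energy_response is not None and any(
            e <= 0 for e in self.energy_response.values()
        ):
            v.append("energy response corrections must be > 0")
        if v:
            raise ValidationError(v)

    def response_at(self, r: float, theta: float) -> float:
        if self.energy_response is None:
            return 1.0
        key = (round(r, _POS_DECIMALS), round(theta, _POS_DECIMALS))
        try:
            return self.energy_response[key]
        except KeyError:
            raise CalibrationError(
                f"no energy response entry for position (r={r}, theta={theta})"
            ) from None

    @property
    def type_b_combined(self) -> float:
        """Quadrature sum of the type-B components, relative %."""
        return math.sqrt(sum(p * p for _, p in self.type_b_components))


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative (%) type-A, type-B and combined standard uncertainty."""

    type_a: float
    type_b: float
    combined: float

    def __post_init__(self) -> None:
        expected = math.sqrt(self.type_a**2 + self.type_b**2)
        if abs(self.combined - expected) > 1e-12:
            raise ValidationError(
                [f"combined {self.combined} is not sqrt(a²+b²) = {expected}"]
            )


@dataclass(frozen=True)
class ReducedDose:
    """Per-position reduced result: dose rate per SK and its type-A %."""

    r: float
    theta: float
    dose_per_sk: float
    type_a_percent: float
    n_chips: int
    clamped: bool = False  # True when a negative corrected reading was zeroed


def sensitivity_factors(co_irradiation_readings: Mapping[str, float]) -> dict[str, float]:
    """Per-chip sensitivity factors from a uniform calibration irradiation.

    factor_i = reading_i / mean(readings); the batch mean of the factors is 1
    by construction.
    """
    if len(co_irradiation_readings) < 2:
        raise CalibrationError("need readings from at least 2 chips")
    values = np.array(list(co_irradiation_readings.values()), dtype=float)
    if np.any(values <= 0):
        raise CalibrationError("all calibration readings must be > 0")
    mean = float(values.mean())
    return {cid: v / mean for cid, v in co_irradiation_readings.items()}


def effective_exposure_time(T_hours: float, half_life_days: float) -> float:
    """Decay-weighted effective exposure time (1 − e^{−λT})/λ, in hours.

    Converts the reading integrated over an exposure of duration T from a
    source decaying with constant λ = ln2/half-life into an initial dose
    rate; reduces to T as λT → 0.
    """
    if not T_hours > 0:
        raise DomainError(f"T must be > 0, got {T_hours}")
    if not half_life_days > 0:
        raise DomainError(f"half-life must be > 0, got {half_life_days}")
    lam = math.log(2.0) / (half_life_days * 24.0)
    return -math.expm1(-lam * T_hours) / lam


def reduce(
    readings: TLDReadingSet,
    cal: CalibrationSet,
    sk: float,
    half_life_days: float = PD103_HALF_LIFE_DAYS,
) -> list[ReducedDose]:
    """Reduce raw TLD readings to dose rates per unit air-kerma strength.

    Per chip: subtract the mean background, divide by the chip's sensitivity
    factor, then by t_eff · SK · ε_λ · E(r,θ).  Replicates at the same
    position are averaged; type-A % is the relative sample standard deviation
    (k = 1) over the replicates, 0 for a single chip.  Corrected readings
    below zero are clamped to 0 with a warning (near-background chips at
    large distance are expected), never an error.
    """
    if not sk > 0:
        raise DomainError(f"SK must be > 0, got {sk}")
    missing = sorted({c.chip_id for c in readings.readings} - set(cal.sensitivity))
    if missing:
        raise CalibrationError(f"no sensitivity factor for chips: {', '.join(missing)}")
    bg = float(np.mean(readings.background_readings)) if readings.background_readings else 0.0
    t_eff = effective_exposure_time(readings.exposure_hours, half_life_days)

    by_pos: dict[tuple[float, float], list[tuple[float, bool]]] = {}
    order: list[tuple[float, float]] = []
    for chip in readings.readings:
        net = (chip.reading - bg) / cal.sensitivity[chip.chip_id]
        clamped = net < 0
        if clamped:
            warnings.warn(
                f"chip {chip.chip_id} at (r={chip.r}, theta={chip.theta}): corrected "
                "reading below background, clamped to 0",
                stacklevel=2,
            )
            net = 0.0
        dose = net / (t_eff * sk * cal.epsilon_lambda * cal.response_at(chip.r, chip.theta))
        key = (round(chip.r, _POS_DECIMALS), round(chip.theta, _POS_DECIMALS))
        if key not in by_pos:
            by_pos[key] = []
            order.append(key)
        by_pos[key].append((dose, clamped))

    out: list[ReducedDose] = []
    for key in order:
        doses = np.array([d for d, _ in by_pos[key]])
        mean = float(doses.mean())
        if len(doses) > 1 and mean > 0:
            type_a = float(doses.std(ddof=1) / mean * 100.0)
        else:
            type_a = 0.0
        out.append(
            ReducedDose(
                r=key[0],
                theta=key[1],
                dose_per_sk=mean,
                type_a_percent=type_a,
                n_chips=len(doses),
                clamped=any(c for _, c in by_pos[key]),
            )
        )
    return out


def combine_uncertainty(type_a: float, type_b: float) -> UncertaintyBudget:
    """Combined standard uncertainty: quadrature sum of type A and type B (%)."""
    if type_a < 0 or type_b < 0:
        raise DomainError("uncertainty components must be >= 0")
    return UncertaintyBudget(
        type_a=type_a, type_b=type_b, combined=math.sqrt(type_a**2 + type_b**2)
    )
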