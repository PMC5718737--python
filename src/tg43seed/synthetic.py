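"""Synthetic dose grids, ring-kerma profiles and TLD experiments with known truth.

The generator stands in for Monte Carlo transport runs and phantom
measurements: an analytic separable kernel

    D(r,θ) = S · c · G(r,θ) · A(r) · f(θ)

with G the line-source geometry function (optionally a discrete five-bead
sum), A(r) = e^{−μr}(1 + b1·μr·e^{−b2·μr}) a medium attenuation/buildup
proxy, and f(θ) = e^{−μTi·t(θ)} an effective capsule filtration factor with
a smooth monotone oblique path t(θ) through end cap and side wall.  The
kernel is *not* a transport code; its contract is qualitative structure —
g(r) falling from ≈1.45 at 0.5 cm to ≈0.16 at 5 cm, F rising from ≈0.2 on
the long axis to 1 on the transverse axis — plus exact knowledge of the
implied g, F, SK and Λ, which makes every analysis stage testable.

The calibration constant c (dose to medium per unit air kerma) is chosen so
the noiseless seed has a stated dose-rate constant; air-kerma profiles are
generated without medium or capsule factors, so SK_true equals the emission
strength S.  All noise is multiplicative lognormal (mean 1) and reproducible
from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError
from .sources import (
    DoseRateGrid,
    RingKermaProfile,
    SeedGeometry,
    default_seed_geometry,
)
from .tg43 import GeometryModel, geometry_function
from .tld import CalibrationSet, ChipReading, TLDReadingSet, effective_exposure_time

__all__ = [
    "SimulatorConfig",
    "SyntheticTruth",
    "simulate_dose_grid",
    "simulate_ring_kerma",
    "simulate_tld_experiment",
    "RADIAL_PHANTOM_RADII",
    "ANISOTROPY_PHANTOM_RADII",
    "MC_GRID_RADII",
    "MC_GRID_ANGLES",
]

# Measurement/simulation lattices of the study design: TLD radial phantom
# distances, TLD anisotropy phantom radii, and the Monte Carlo ring-detector
# lattice (10-degree increments, 0.25-5 cm).
RADIAL_PHANTOM_RADII = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
ANISOTROPY_PHANTOM_RADII = (1.5, 2.0, 3.0, 5.0)
MC_GRID_RADII = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
MC_GRID_ANGLES = tuple(float(a) for a in range(0, 91, 10))


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of the analytic seed kernel.

    ``medium_mu`` (cm⁻¹) and ``buildup_coefficients`` shape the radial
    falloff; defaults give g(0.5)≈1.45 and g(5)≈0.16.  ``capsule_mu_ti`` is
    an effective titanium attenuation coefficient (cm⁻¹) folding source
    self-absorption into the end-cap term; with the default capsule it gives
    F(0°)≈0.2.  ``emission_strength`` is SK_true in U.
    ``reference_lambda`` fixes the noiseless dose-rate constant (cGy/(h·U)).
    """

    geometry: SeedGeometry = field(default_factory=default_seed_geometry)
    medium_mu: float = 0.45
    buildup_coefficients: tuple[float, float] = (9.0, 10.0)
    capsule_mu_ti: float = 29.0
    obliquity_exponent: float = 3.0
    emission_strength: float = 1000.0
    reference_lambda: float = 0.690
    cutoff_delta: float = 5.0
    noise_relative_sigma: float = 0.01
    random_seed: int = 0
    discrete_beads: bool = False

    def __post_init__(self) -> None:
        if self.medium_mu < 0 or self.capsule_mu_ti < 0:
            raise DomainError("attenuation coefficients must be >= 0")
        if self.noise_relative_sigma < 0:
            raise DomainError("noise sigma must be >= 0")
        if not (self.emission_strength > 0 and self.reference_lambda > 0):
            raise DomainError("emission_strength and reference_lambda must be > 0")

    # -- kernel pieces ------------------------------------------------------

    def attenuation(self, r):
        """Medium attenuation/buildup factor A(r)."""
        mu = self.medium_mu
        b1, b2 = self.buildup_coefficients
        x = mu * np.asarray(r, dtype=float)
        return np.exp(-x) * (1.0 + b1 * x * np.exp(-b2 * x))

    def capsule_path(self, theta_deg):
        """Effective straight-ray path (cm) through the capsule at angle θ.

        Smooth monotone interpolation between the end-cap thickness on the
        long axis and the side-wall thickness on the transverse axis:
        t(θ) = w + (t_cap − w)·|cosθ|^p.
        """
        w = self.geometry.wall_thickness
        t_cap = self.geometry.end_cap_thickness
        c = np.abs(np.cos(np.radians(np.asarray(theta_deg, dtype=float))))
        return w + (t_cap - w) * c**self.obliquity_exponent

    def filtration(self, theta_deg):
        """Capsule filtration factor f(θ) = e^{−μTi·t(θ)}."""
        return np.exp(-self.capsule_mu_ti * self.capsule_path(theta_deg))

    def geometry_factor(self, r, theta_deg):
        """Line-source G(r,θ), or a five-bead discrete sum when enabled."""
        if not self.discrete_beads:
            return geometry_function(r, theta_deg, GeometryModel.line(self.geometry.active_length))
        n = self.geometry.bead_count
        half = (self.geometry.active_length - self.geometry.bead_diameter) / 2.0
        centers = np.linspace(-half, half, n)
        r = np.asarray(r, dtype=float)
        th = np.radians(np.asarray(theta_deg, dtype=float))
        x = r * np.sin(th)
        z = r * np.cos(th)
        d2 = (x[..., None]) ** 2 + (z[..., None] - centers) ** 2
        if np.any(d2 <= 0):
            raise DomainError("field point coincides with a bead center")
        out = np.mean(1.0 / d2, axis=-1)
        return out if out.ndim else float(out)

    @property
    def dose_conversion(self) -> float:
        """Dose-to-medium per air-kerma calibration constant c.

        Chosen so the noiseless kernel has Λ = ``reference_lambda``:
        c = Λ_ref / (G(1,90°)·A(1)·f(90°)).
        """
        g0 = self.geometry_factor(1.0, 90.0)
        return self.reference_lambda / (g0 * float(self.attenuation(1.0)) * float(self.filtration(90.0)))

    def dose_rate(self, r, theta_deg):
        """Noiseless dose rate D(r,θ) in the medium, cGy/h."""
        return (
            self.emission_strength
            * self.dose_conversion
            * self.geometry_factor(r, theta_deg)
            * self.attenuation(r)
            * self.filtration(theta_deg)
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact quantities implied by a kernel configuration."""

    lambda_true: float
    sk_true: float
    g_true: Callable[[float], float]
    F_true: Callable[[float, float], float]
    g_description: str = "A(r)/A(1) with A(r) = exp(-mu r) (1 + b1 mu r exp(-b2 mu r))"
    F_description: str = "f(theta)/f(90) with f = exp(-mu_Ti t(theta)), independent of r"

    def __post_init__(self) -> None:
        if not (self.lambda_true > 0 and self.sk_true > 0):
            raise DomainError("truth values must be positive")


def _truth(config: SimulatorConfig) -> SyntheticTruth:
    a1 = float(config.attenuation(1.0))
    f90 = float(config.filtration(90.0))

    def g_true(r: float) -> float:
        return float(config.attenuation(r)) / a1

    def F_true(r: float, theta: float) -> float:
        return float(config.filtration(theta)) / f90

    return SyntheticTruth(
        lambda_true=config.reference_lambda,
        sk_true=config.emission_strength,
        g_true=g_true,
        F_true=F_true,
    )


def _lognormal_factors(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    """Multiplicative mean-one lognormal noise factors with relative σ."""
    if sigma == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sigma, size=shape) - sigma * sigma / 2.0)


def simulate_dose_grid(
    config: SimulatorConfig,
    radii: Sequence[float] = MC_GRID_RADII,
    angles: Sequence[float] = MC_GRID_ANGLES,
    medium: str = "water",
) -> tuple[DoseRateGrid, SyntheticTruth]:
    """Generate a polar dose-rate grid with its exact analytic truth.

    Radii must exceed L/2 so axial samples stay outside the source extent.
    Noise is multiplicative lognormal with the configured relative σ, drawn
    from the configured seed (same config ⇒ bit-identical grid).
    """
    radii = np.asarray(radii, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if radii.size == 0 or angles.size == 0:
        raise DomainError("radii and angles must be non-empty")
    if np.any(radii <= config.geometry.active_length / 2.0):
        raise DomainError("all radii must exceed L/2 (outside the source extent)")
    if np.any(np.diff(radii) <= 0) or np.any(np.diff(angles) <= 0):
        raise DomainError("radii and angles must be strictly increasing")
    values = config.dose_rate(radii[:, None], angles[None, :])
    rng = np.random.default_rng(config.random_seed)
    values = values * _lognormal_factors(rng, config.noise_relative_sigma, values.shape)
    grid = DoseRateGrid(
        radii=radii,
        angles=angles,
        values=values,
        medium=medium,
        uncertainty=np.full(values.shape, config.noise_relative_sigma),
    )
    return grid, _truth(config)


def simulate_ring_kerma(
    config: SimulatorConfig, distances: Sequence[float]
) -> RingKermaProfile:
    """Vacuum ring-kerma profile K̇δ(r) = S·G(r,90°) on the transverse axis.

    No medium attenuation applies in vacuum, so K̇·r² rises monotonically to
    the asymptote S as the finite line looks ever more point-like.
    Distances follow the far-field layout (≥ 5 cm).
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise DomainError("distances must be non-empty")
    if np.any(distances < 5.0):
        raise DomainError("ring distances must be >= 5 cm (far-field layout)")
    if np.any(np.diff(distances) <= 0):
        raise DomainError("distances must be strictly increasing")
    kerma = config.emission_strength * np.asarray(
        config.geometry_factor(distances, np.full_like(distances, 90.0))
    )
    return RingKermaProfile(
        distances=distances, kerma_rates=kerma, cutoff_delta=config.cutoff_delta
    )


def simulate_tld_experiment(
    config: SimulatorConfig,
    phantom_layout: Sequence[tuple[float, float]] | None = None,
    n_background: int = 4,
    chip_sensitivity_sigma: float = 0.03,
    chips_per_position: int = 4,
    reading_noise_sigma: float = 0.029,
    exposure_hours: float = 24.0,
    epsilon_lambda: float = 10.0,
    background_level: float = 2.0,
    half_life_days: float = 16.991,
) -> tuple[TLDReadingSet, CalibrationSet, SyntheticTruth]:
    """Generate one phantom TLD experiment with its calibration and truth.

    The default layout is the radial spiral phantom: four chips at each of
    r = 0.5…5 cm on the transverse axis.  Per-chip readings are

        R = background + D(r,θ) · t_eff · ε_λ · s_i · noise

    with exact per-chip sensitivities s_i (batch mean 1) carried in the
    returned :class:`CalibrationSet`, and ``reading_noise_sigma`` relative
    lognormal noise on the signal (default 2.9%, the type-A dispersion of
    the measurement design this emulates).
    """
    if phantom_layout is None:
        phantom_layout = [(r, 90.0) for r in RADIAL_PHANTOM_RADII]
    if not phantom_layout:
        raise DomainError("phantom layout must be non-empty")
    if chips_per_position < 1 or n_background < 1:
        raise DomainError("need at least one chip per position and one background chip")

    rng = np.random.default_rng(config.random_seed)
    n_chips = len(phantom_layout) * chips_per_position
    raw_sens = np.exp(rng.normal(0.0, chip_sensitivity_sigma, size=n_chips))
    sens = raw_sens / raw_sens.mean()  # batch mean exactly 1
    t_eff = effective_exposure_time(exposure_hours, half_life_days)

    readings: list[ChipReading] = []
    k = 0
    for r, theta in phantom_layout:
        dose = float(config.dose_rate(r, theta))
        for _ in range(chips_per_position):
            noise = float(_lognormal_factors(rng, reading_noise_sigma, ()))
            signal = dose * t_eff * epsilon_lambda * sens[k] * noise
            readings.append(
                ChipReading(chip_id=f"chip{k:03d}", r=r, theta=theta, reading=background_level + signal)
            )
            k += 1
    bg = background_level * _lognormal_factors(rng, reading_noise_sigma, n_background)

    reading_set = TLDReadingSet(
        readings=readings, background_readings=bg.tolist(), exposure_hours=exposure_hours
    )
    cal = CalibrationSet(
        epsilon_lambda=epsilon_lambda,
        sensitivity={f"chip{i:03d}": float(sens[i]) for i in range(n_chips)},
        type_b_components=(),
    )
    return reading_set, cal, _truth(config)
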