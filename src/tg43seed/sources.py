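"""Domain types and packaged reference data for low-energy seed dosimetry.

The central container is :class:`ConsensusDataset`: per source model it bundles
the dose-rate constant Λ (experimental, Monte Carlo, and their consensus
average), the radial dose function g(r), the 2D anisotropy function F(r,θ),
the capsule geometry and the nuclide.  Datasets are stored as human-diffable
YAML documents with explicit units; the reference dataset for the IR06-type
Pd-103 seed ships with the package.

Angles are degrees everywhere at this layer; trigonometric work happens in
radians inside :mod:`tg43seed.tg43`.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "SeedGeometry",
    "Nuclide",
    "DoseRateGrid",
    "RingKermaProfile",
    "RadialDoseTable",
    "AnisotropyTable",
    "ValueWithSigma",
    "ConsensusDataset",
    "PolynomialFit",
    "LambdaRecord",
    "validate_grid",
    "load_consensus_dataset",
    "save_consensus_dataset",
    "ir06",
    "reference_lambdas",
    "default_seed_geometry",
    "default_nuclide",
]

_NORM_TOL = 1e-12


# ---------------------------------------------------------------------------
# simple value types


@dataclass(frozen=True)
class ValueWithSigma:
    """A scalar with a 1σ absolute uncertainty."""

    value: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError([f"sigma must be >= 0, got {self.sigma}"])


@dataclass(frozen=True)
class SeedGeometry:
    """Physical description of a cylindrical encapsulated seed (lengths in cm).

    ``active_length`` is the effective line-source length L used by the
    line geometry function.
    """

    physical_length: float
    active_length: float
    capsule_outer_diameter: float
    capsule_inner_diameter: float
    end_cap_thickness: float
    bead_count: int
    bead_diameter: float
    capsule_material: str = "titanium"
    core_material: str = "resin"
    core_mass_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v: list[str] = []
        if not self.active_length > 0:
            v.append(f"active_length must be > 0, got {self.active_length}")
        if self.active_length > self.physical_length:
            v.append("active_length exceeds physical_length")
        if not self.capsule_inner_diameter < self.capsule_outer_diameter:
            v.append("capsule inner diameter must be smaller than outer diameter")
        if self.core_mass_fractions:
            total = sum(self.core_mass_fractions.values())
            if abs(total - 1.0) > 1e-9:
                v.append(f"core mass fractions sum to {total!r}, expected 1")
        if v:
            raise ValidationError(v)

    @property
    def wall_thickness(self) -> float:
        """Radial thickness of the capsule side wall, cm."""
        return (self.capsule_outer_diameter - self.capsule_inner_diameter) / 2.0


@dataclass(frozen=True)
class Nuclide:
    """Radionuclide with half-life in days and an optional photon spectrum.

    ``spectrum`` is a sequence of (energy keV, intensity per decay) pairs;
    it may be empty when the user supplies it separately.
    """

    name: str
    half_life_days: float
    spectrum: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        v: list[str] = []
        if not self.half_life_days > 0:
            v.append(f"half_life_days must be > 0, got {self.half_life_days}")
        if any(i < 0 for _, i in self.spectrum):
            v.append("spectrum intensities must be >= 0")
        if v:
            raise ValidationError(v)

    @property
    def decay_constant_per_hour(self) -> float:
        return math.log(2.0) / (self.half_life_days * 24.0)


# ---------------------------------------------------------------------------
# grids and profiles


@dataclass
class DoseRateGrid:
    """Polar samples of dose rate around a seed in a stated medium.

    ``values[i, j]`` is the dose rate at ``(radii[i], angles[j])`` in an
    arbitrary but internally consistent unit (cGy/h or per source history).
    ``uncertainty`` holds relative 1σ values of the same shape, if known.
    """

    radii: np.ndarray
    angles: np.ndarray
    values: np.ndarray
    medium: str = "water"
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)

    def require_valid(self) -> None:
        violations = validate_grid(self)
        if violations:
            raise ValidationError(violations)


def validate_grid(grid: DoseRateGrid) -> list[str]:
    """Check every :class:`DoseRateGrid` invariant; return the violations.

    Returns an empty list iff the grid is well formed.  Never raises.
    """
    v: list[str] = []
    r, a, d = grid.radii, grid.angles, grid.values
    if r.ndim != 1 or a.ndim != 1:
        v.append("radii and angles must be one-dimensional")
        return v
    if len(r) and not np.all(r > 0):
        v.append("radii must all be > 0")
    if len(r) > 1 and not np.all(np.diff(r) > 0):
        v.append("radii not increasing")
    if len(a) > 1 and not np.all(np.diff(a) > 0):
        v.append("angles not increasing")
    if len(a) and (a[0] < 0 or a[-1] > 360):
        v.append("angles must lie in [0, 360]")
    expected = (len(r), len(a))
    if d.shape != expected:
        v.append(f"values shape {d.shape} does not match expected {expected}")
        return v
    for i, j in zip(*np.nonzero(d < 0)):
        v.append(f"negative dose rate at cell ({i}, {j})")
    if grid.uncertainty is not None and grid.uncertainty.shape != expected:
        v.append(
            f"uncertainty shape {grid.uncertainty.shape} does not match expected {expected}"
        )
    return v


@dataclass
class RingKermaProfile:
    """Vacuum ring-kerma rates K̇δ(r) on the transverse axis vs distance (cm).

    ``cutoff_delta`` is the photon energy cutoff δ in keV used to suppress
    capsule characteristic X rays.
    """

    distances: np.ndarray
    kerma_rates: np.ndarray
    cutoff_delta: float = 5.0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.kerma_rates = np.asarray(self.kerma_rates, dtype=float)
        v: list[str] = []
        if len(self.distances) > 1 and not np.all(np.diff(self.distances) > 0):
            v.append("distances not increasing")
        if not np.all(self.kerma_rates > 0):
            v.append("kerma rates must be > 0")
        if len(self.distances) != len(self.kerma_rates):
            v.append("distances and kerma_rates differ in length")
        if v:
            raise ValidationError(v)


# ---------------------------------------------------------------------------
# TG-43 function tables


@dataclass
class RadialDoseTable:
    """Radial dose function g(r), unitless, normalized to 1 at ``reference_radius``."""

    radii: np.ndarray
    g_values: np.ndarray
    geometry_model: str = "line"
    reference_radius: float = 1.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        v: list[str] = []
        if self.geometry_model not in ("point", "line"):
            v.append(f"geometry_model must be 'point' or 'line', got {self.geometry_model!r}")
        if len(self.radii) != len(self.g_values):
            v.append("radii and g_values differ in length")
            raise ValidationError(v)
        if len(self.radii) > 1 and not np.all(np.diff(self.radii) > 0):
            v.append("radii not increasing")
        if not np.all(self.g_values > 0):
            v.append("g values must be > 0")
        idx = np.nonzero(np.isclose(self.radii, self.reference_radius, atol=1e-9))[0]
        if idx.size and abs(self.g_values[idx[0]] - 1.0) > _NORM_TOL:
            v.append(
                f"g({self.reference_radius} cm) = {self.g_values[idx[0]]!r}, "
                "expected 1 (normalization)"
            )
        if v:
            raise ValidationError(v)


@dataclass
class AnisotropyTable:
    """2D anisotropy function F(r,θ) on a polar lattice, θ in degrees.

    The column at θ0 = 90°, when tabulated, is identically 1 (normalization).
    Sparse measured tables without a 90° column are allowed.
    """

    radii: np.ndarray
    angles: np.ndarray
    F_values: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.F_values = np.asarray(self.F_values, dtype=float)
        v: list[str] = []
        if self.F_values.shape != (len(self.radii), len(self.angles)):
            v.append(
                f"F shape {self.F_values.shape} does not match "
                f"expected {(len(self.radii), len(self.angles))}"
            )
            raise ValidationError(v)
        if len(self.radii) > 1 and not np.all(np.diff(self.radii) > 0):
            v.append("radii not increasing")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            v.append("angles not increasing")
        if len(self.angles) and (self.angles[0] < 0 or self.angles[-1] > 180):
            v.append("angles must lie in [0, 180]")
        if not np.all(self.F_values > 0):
            v.append("F values must be > 0")
        ref = np.nonzero(np.isclose(self.angles, 90.0, atol=1e-9))[0]
        if ref.size and np.any(np.abs(self.F_values[:, ref[0]] - 1.0) > _NORM_TOL):
            v.append("F(r, 90 deg) column must be identically 1 (normalization)")
        if v:
            raise ValidationError(v)


@dataclass(frozen=True)
class PolynomialFit:
    """Fifth-order polynomial model of g(r): g(r) = a0 + a1 r + ... + a5 r^5."""

    coefficients: tuple[float, ...]
    r_range: tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        v: list[str] = []
        if len(self.coefficients) != 6:
            v.append(f"expected 6 coefficients (degree 5), got {len(self.coefficients)}")
        if not self.r_range[0] < self.r_range[1]:
            v.append("r_range min must be < max")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            v.append(f"r_squared must lie in [0, 1], got {self.r_squared}")
        if v:
            raise ValidationError(v)


# ---------------------------------------------------------------------------
# consensus dataset


@dataclass(frozen=True)
class LambdaRecord:
    """One dose-rate-constant determination for a source model."""

    source: str
    method: str
    medium: str
    value: float
    sigma: float = 0.0
    citation: str = ""


@dataclass
class ConsensusDataset:
    """Per-source-model consensus dosimetry parameters with provenance.

    ``lambda_consensus`` is the plain average of the experimental and Monte
    Carlo dose-rate constants in the stated medium.  ``g_tables`` may carry
    several determinations (e.g. Monte Carlo in water and in the phantom
    medium, plus TLD measurements); ``consensus_g`` names the column used by
    forward dose reconstruction.
    """

    source_name: str
    lambda_exp: ValueWithSigma
    lambda_mc: ValueWithSigma
    lambda_consensus: float
    g_tables: dict[str, RadialDoseTable]
    consensus_g: str
    F_table: AnisotropyTable
    geometry: SeedGeometry
    nuclide: Nuclide
    medium: str = "perspex"
    lambda_mc_water: ValueWithSigma | None = None
    F_measured: AnisotropyTable | None = None

    def __post_init__(self) -> None:
        v: list[str] = []
        for label, lam in (
            ("lambda_exp", self.lambda_exp.value),
            ("lambda_mc", self.lambda_mc.value),
            ("lambda_consensus", self.lambda_consensus),
        ):
            if not lam > 0:
                v.append(f"{label} must be > 0, got {lam}")
        expected = (self.lambda_exp.value + self.lambda_mc.value) / 2.0
        # consensus is stored at printed precision; allow half a unit in the
        # last stored decimal place (3 decimals in the reference data)
        if abs(self.lambda_consensus - expected) > 5e-4 + 1e-12:
            v.append(
                f"lambda_consensus {self.lambda_consensus} is not the average of "
                f"lambda_exp and lambda_mc ({expected:.6f}) within stored precision"
            )
        if self.consensus_g not in self.g_tables:
            v.append(f"consensus_g {self.consensus_g!r} not among g_tables")
        if v:
            raise ValidationError(v)

    @property
    def g_table(self) -> RadialDoseTable:
        """The g(r) determination used for dose reconstruction."""
        return self.g_tables[self.consensus_g]


# ---------------------------------------------------------------------------
# YAML serialization

_SECTIONS = ("source", "lambda", "geometry", "nuclide", "g_table", "F_table")


def _get(mapping: Mapping, key: str, where: str):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise FormatError(f"missing or malformed field {key!r} in section {where!r}") from None


def _dataset_from_mapping(doc: Mapping) -> ConsensusDataset:
    for section in _SECTIONS:
        if section not in doc:
            raise FormatError(f"missing section {section!r}")
    src = doc["source"]
    lam = doc["lambda"]
    geo = doc["geometry"]
    nuc = doc["nuclide"]
    gt = doc["g_table"]
    ft = doc["F_table"]

    geometry = SeedGeometry(
        physical_length=_get(geo, "physical_length", "geometry"),
        active_length=_get(geo, "active_length", "geometry"),
        capsule_outer_diameter=_get(geo, "capsule_outer_diameter", "geometry"),
        capsule_inner_diameter=_get(geo, "capsule_inner_diameter", "geometry"),
        end_cap_thickness=_get(geo, "end_cap_thickness", "geometry"),
        bead_count=_get(geo, "bead_count", "geometry"),
        bead_diameter=_get(geo, "bead_diameter", "geometry"),
        capsule_material=geo.get("capsule_material", "titanium"),
        core_material=geo.get("core_material", "resin"),
        core_mass_fractions=dict(geo.get("core_mass_fractions", {})),
    )
    nuclide = Nuclide(
        name=_get(nuc, "name", "nuclide"),
        half_life_days=_get(nuc, "half_life_days", "nuclide"),
        spectrum=tuple(tuple(p) for p in nuc.get("spectrum", []) or []),
    )
    radii = _get(gt, "radii", "g_table")
    g_tables = {
        name: RadialDoseTable(
            radii=radii,
            g_values=col,
            geometry_model=gt.get("geometry_model", "line"),
            reference_radius=gt.get("reference_radius", 1.0),
        )
        for name, col in _get(gt, "columns", "g_table").items()
    }
    F_table = AnisotropyTable(
        radii=_get(ft, "radii", "F_table"),
        angles=_get(ft, "angles", "F_table"),
        F_values=_get(ft, "values", "F_table"),
    )
    F_measured = None
    if "F_measured" in doc and doc["F_measured"]:
        fm = doc["F_measured"]
        F_measured = AnisotropyTable(
            radii=_get(fm, "radii", "F_measured"),
            angles=_get(fm, "angles", "F_measured"),
            F_values=_get(fm, "values", "F_measured"),
        )
    mc_water = lam.get("monte_carlo_water")
    return ConsensusDataset(
        source_name=_get(src, "name", "source"),
        medium=src.get("medium", "perspex"),
        lambda_exp=ValueWithSigma(
            _get(lam["experimental"], "value", "lambda.experimental"),
            lam["experimental"].get("sigma", 0.0),
        ),
        lambda_mc=ValueWithSigma(
            _get(lam["monte_carlo"], "value", "lambda.monte_carlo"),
            lam["monte_carlo"].get("sigma", 0.0),
        ),
        lambda_consensus=_get(lam, "consensus", "lambda"),
        lambda_mc_water=(
            ValueWithSigma(mc_water["value"], mc_water.get("sigma", 0.0)) if mc_water else None
        ),
        g_tables=g_tables,
        consensus_g=gt.get("consensus_column", next(iter(g_tables))),
        F_table=F_table,
        F_measured=F_measured,
        geometry=geometry,
        nuclide=nuclide,
    )


def load_consensus_dataset(path: str | Path) -> ConsensusDataset:
    """Load and validate a consensus dataset from its YAML document.

    Raises
    ------
    FormatError
        If the document cannot be parsed or a required field is missing.
    ValidationError
        If any domain invariant fails (normalization, ordering, positivity).
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path.name} is not a mapping document")
    return _dataset_from_mapping(doc)


def _dataset_to_mapping(ds: ConsensusDataset) -> dict:
    gt0 = next(iter(ds.g_tables.values()))
    doc: dict = {
        "source": {"name": ds.source_name, "medium": ds.medium},
        "lambda": {
            "units": "cGy/(h*U)",
            "experimental": {"value": ds.lambda_exp.value, "sigma": ds.lambda_exp.sigma},
            "monte_carlo": {"value": ds.lambda_mc.value, "sigma": ds.lambda_mc.sigma},
            "consensus": ds.lambda_consensus,
        },
        "geometry": {
            "units": "cm",
            "physical_length": ds.geometry.physical_length,
            "active_length": ds.geometry.active_length,
            "capsule_outer_diameter": ds.geometry.capsule_outer_diameter,
            "capsule_inner_diameter": ds.geometry.capsule_inner_diameter,
            "end_cap_thickness": ds.geometry.end_cap_thickness,
            "bead_count": ds.geometry.bead_count,
            "bead_diameter": ds.geometry.bead_diameter,
            "capsule_material": ds.geometry.capsule_material,
            "core_material": ds.geometry.core_material,
            "core_mass_fractions": dict(ds.geometry.core_mass_fractions),
        },
        "nuclide": {
            "name": ds.nuclide.name,
            "half_life_days": ds.nuclide.half_life_days,
            "spectrum": [list(p) for p in ds.nuclide.spectrum],
        },
        "g_table": {
            "units": {"radii": "cm"},
            "radii": gt0.radii.tolist(),
            "geometry_model": gt0.geometry_model,
            "reference_radius": gt0.reference_radius,
            "consensus_column": ds.consensus_g,
            "columns": {name: t.g_values.tolist() for name, t in ds.g_tables.items()},
        },
        "F_table": {
            "units": {"radii": "cm", "angles": "deg"},
            "radii": ds.F_table.radii.tolist(),
            "angles": ds.F_table.angles.tolist(),
            "values": ds.F_table.F_values.tolist(),
        },
    }
    if ds.lambda_mc_water is not None:
        doc["lambda"]["monte_carlo_water"] = {
            "value": ds.lambda_mc_water.value,
            "sigma": ds.lambda_mc_water.sigma,
        }
    if ds.F_measured is not None:
        doc["F_measured"] = {
            "radii": ds.F_measured.radii.tolist(),
            "angles": ds.F_measured.angles.tolist(),
            "values": ds.F_measured.F_values.tolist(),
        }
    return doc


def save_consensus_dataset(ds: ConsensusDataset, path: str | Path) -> None:
    """Write a dataset as YAML; numeric fields round-trip losslessly."""
    Path(path).write_text(yaml.safe_dump(_dataset_to_mapping(ds), sort_keys=False))


# ---------------------------------------------------------------------------
# packaged reference data


def default_seed_geometry() -> SeedGeometry:
    """Capsule geometry of the IR06-type Pd-103 seed.

    Titanium cylinder 4.7 mm long, 0.8/0.7 mm outer/inner diameter with
    0.6 mm end caps; five 0.6 mm resin beads; effective source length 3 mm.
    """
    return SeedGeometry(
        physical_length=0.47,
        active_length=0.30,
        capsule_outer_diameter=0.08,
        capsule_inner_diameter=0.07,
        end_cap_thickness=0.06,
        bead_count=5,
        bead_diameter=0.06,
        capsule_material="titanium",
        core_material="resin",
        core_mass_fractions={"H": 0.08, "C": 0.90, "N": 0.003, "Cl": 0.007, "Pd": 0.01},
    )


def default_nuclide() -> Nuclide:
    """Pd-103: half-life 16.991 d; photon spectrum user-supplied."""
    return Nuclide(name="Pd-103", half_life_days=16.991)


def _data_path(name: str):
    return resources.files("tg43seed.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def ir06() -> ConsensusDataset:
    """The packaged IR06 Pd-103 seed consensus dataset."""
    with resources.as_file(_data_path("ir06.yaml")) as p:
        return load_consensus_dataset(p)


@functools.lru_cache(maxsize=None)
def reference_lambdas() -> tuple[LambdaRecord, ...]:
    """Published dose-rate constants for comparable commercial Pd-103 seeds."""
    with resources.as_file(_data_path("reference_lambdas.yaml")) as p:
        doc = yaml.safe_load(Path(p).read_text())
    return tuple(
        LambdaRecord(
            source=row["source"],
            method=row["method"],
            medium=row["medium"],
            value=row["value"],
            sigma=row.get("sigma", 0.0),
            citation=str(row.get("citation", "")),
        )
        for row in doc["records"]
    )
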