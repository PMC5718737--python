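"""The TG-43U1 two-dimensional dose-calculation formalism.

The dose rate around a cylindrically symmetric seed is factorized as

    D(r,θ) = SK · Λ · [G(r,θ) / G(r0,θ0)] · g(r) · F(r,θ)

with reference point r0 = 1 cm, θ0 = 90°.  This module provides the point-
and line-source geometry functions G, the extraction of the radial dose
function g(r) and the 2D anisotropy function F(r,θ) from polar dose-rate
grids, air-kerma strength SK from vacuum ring-kerma profiles, the dose-rate
constant Λ and its experimental/Monte-Carlo consensus average, polynomial
modelling of g(r), interpolation of the tabulated functions, and forward
dose reconstruction.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateInputError,
    DomainError,
    ExtractionError,
    ExtrapolationError,
    UnderdeterminedError,
)
from .sources import (
    AnisotropyTable,
    ConsensusDataset,
    DoseRateGrid,
    PolynomialFit,
    RadialDoseTable,
    RingKermaProfile,
)

__all__ = [
    "GeometryModel",
    "DosePoint",
    "SkEstimate",
    "geometry_function",
    "extract_radial_dose",
    "extract_anisotropy",
    "fold_angles",
    "air_kerma_strength",
    "dose_rate_constant",
    "consensus_lambda",
    "fit_gl_polynomial",
    "evaluate_gl",
    "evaluate_f",
    "reconstruct_dose_rate",
    "reconstruct_grid",
    "R0_CM",
    "THETA0_DEG",
]

R0_CM = 1.0
THETA0_DEG = 90.0

# |sin θ| below this uses the axial limiting form 1/(r² − L²/4); avoids
# catastrophic cancellation in β/(L r sin θ).
_SIN_TOL = 1e-6
_ANGLE_MATCH_TOL = 1e-6  # degrees


@dataclass(frozen=True)
class GeometryModel:
    """Point- or line-source geometry model; L is the active length in cm."""

    kind: str = "line"
    L: float = 0.3  # ignored by the point model

    def __post_init__(self) -> None:
        if self.kind not in ("point", "line"):
            raise DomainError(f"kind must be 'point' or 'line', got {self.kind!r}")
        if self.kind == "line" and not self.L > 0:
            raise DomainError(f"line model requires L > 0, got {self.L}")

    @classmethod
    def point(cls) -> "GeometryModel":
        return cls(kind="point")

    @classmethod
    def line(cls, L: float) -> "GeometryModel":
        return cls(kind="line", L=L)


@dataclass(frozen=True)
class DosePoint:
    """A dose-rate sample at polar position (r cm, θ degrees)."""

    r: float
    theta: float
    dose_rate: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise DomainError(f"r must be > 0, got {self.r}")


def geometry_function(r, theta, model: GeometryModel):
    """Geometry function G(r,θ) in cm⁻²; vectorized over r and θ.

    The point model returns 1/r².  The line model returns β/(L·r·sinθ) where
    β is the angle subtended by the active line at the field point, computed
    in one two-argument arctangent of the cross and dot products of the
    end-point vectors, β = atan2(L·r·sinθ, r² − L²/4): this handles obtuse
    geometries (r·cosθ < L/2) without branch errors and keeps full relative
    accuracy as β → 0.  For |sinθ| below an angular tolerance the limiting
    value 1/(r² − L²/4) is used.

    Raises
    ------
    DomainError
        If r ≤ 0, or if an axial query with the line model has r ≤ L/2
        (the point lies inside the source extent).
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(r <= 0):
        raise DomainError("r must be > 0")
    if model.kind == "point":
        out = 1.0 / (r * r) + np.zeros_like(theta)
        return out if out.ndim else float(out)

    L = model.L
    th = np.radians(theta)
    s, c = np.sin(th), np.cos(th)
    axial = np.abs(s) < _SIN_TOL
    if np.any(axial & (np.broadcast_to(r, np.broadcast_shapes(r.shape, th.shape)) <= L / 2)):
        raise DomainError(
            f"axial query with r <= L/2 = {L / 2} cm lies inside the source extent"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(L * r * s, r * r - L * L / 4.0)
        gl = beta / (L * r * s)
    limiting = 1.0 / (r * r - L * L / 4.0)
    out = np.where(axial, limiting, gl)
    return out if out.ndim else float(out)


def _reference_angle_column(grid: DoseRateGrid, theta0: float = THETA0_DEG) -> int:
    idx = np.nonzero(np.isclose(grid.angles, theta0, atol=_ANGLE_MATCH_TOL))[0]
    if not idx.size:
        raise ExtractionError(
            f"grid has no angle column within {_ANGLE_MATCH_TOL} deg of θ0 = {theta0}°"
        )
    return int(idx[0])


def _transverse_dose_at(grid: DoseRateGrid, r0: float, j0: int) -> float:
    """Transverse-axis dose at r0, linearly interpolated in r if untabulated."""
    col = grid.values[:, j0]
    if r0 < grid.radii[0] or r0 > grid.radii[-1]:
        raise ExtractionError(
            f"reference radius {r0} cm lies outside grid radii "
            f"[{grid.radii[0]}, {grid.radii[-1]}]"
        )
    return float(np.interp(r0, grid.radii, col))


def extract_radial_dose(
    grid: DoseRateGrid, model: GeometryModel, r0: float = R0_CM
) -> RadialDoseTable:
    """Extract the radial dose function g(r) from a polar dose-rate grid.

    g(r) = [D(r,θ0) / D(r0,θ0)] · [G(r0,θ0) / G(r,θ0)] with θ0 = 90°.
    The result is exactly 1 at r0 when r0 is a tabulated radius.
    """
    grid.require_valid()
    j0 = _reference_angle_column(grid)
    d0 = _transverse_dose_at(grid, r0, j0)
    if d0 <= 0:
        raise DegenerateInputError(f"zero dose rate at reference point (r0={r0}, 90°)")
    dcol = grid.values[:, j0]
    G = geometry_function(grid.radii, THETA0_DEG, model)
    G0 = geometry_function(r0, THETA0_DEG, model)
    g = (dcol / d0) * (G0 / G)
    i0 = np.nonzero(np.isclose(grid.radii, r0, atol=1e-9))[0]
    if i0.size:
        g[i0[0]] = 1.0  # exact normalization at the tabulated reference radius
    return RadialDoseTable(
        radii=grid.radii.copy(), g_values=g, geometry_model=model.kind, reference_radius=r0
    )


def extract_anisotropy(grid: DoseRateGrid, model: GeometryModel) -> AnisotropyTable:
    """Extract the 2D anisotropy function F(r,θ) from a polar dose-rate grid.

    F(r,θ) = [D(r,θ) / D(r,θ0)] · [G(r,θ0) / G(r,θ)] with θ0 = 90°; the
    90° column of the result is exactly 1 for every radius.
    """
    grid.require_valid()
    j0 = _reference_angle_column(grid)
    d90 = grid.values[:, j0]
    if np.any(d90 <= 0):
        bad = grid.radii[np.nonzero(d90 <= 0)[0][0]]
        raise DegenerateInputError(f"zero dose rate at (r={bad}, 90°)")
    G = geometry_function(grid.radii[:, None], grid.angles[None, :], model)
    G90 = geometry_function(grid.radii, THETA0_DEG, model)
    F = (grid.values / d90[:, None]) * (G90[:, None] / G)
    F[:, j0] = 1.0  # exact normalization on the transverse axis
    return AnisotropyTable(radii=grid.radii.copy(), angles=grid.angles.copy(), F_values=F)


def fold_angles(grid: DoseRateGrid) -> DoseRateGrid:
    """Fold a full-revolution grid onto the [0°, 90°] quadrant.

    θ > 180° maps to 360° − θ, then θ > 90° maps to 180° − θ; values landing
    on the same folded angle are averaged with equal weights.  Measurement
    layouts sample 0°–330° in 30° steps; a cylindrically and mirror
    symmetric source makes the four images of each quadrant angle replicates.
    """
    grid.require_valid()
    folded = np.asarray(grid.angles, dtype=float) % 360.0
    folded = np.where(folded > 180.0, 360.0 - folded, folded)
    folded = np.where(folded > 90.0, 180.0 - folded, folded)
    out_angles = np.unique(np.round(folded, 9))
    values = np.zeros((len(grid.radii), len(out_angles)))
    counts = np.zeros(len(out_angles))
    for j, a in enumerate(folded):
        k = int(np.nonzero(np.isclose(out_angles, a, atol=1e-9))[0][0])
        values[:, k] += grid.values[:, j]
        counts[k] += 1
    values /= counts[None, :]
    return DoseRateGrid(
        radii=grid.radii.copy(), angles=out_angles, values=values, medium=grid.medium
    )


@dataclass(frozen=True)
class SkEstimate:
    """Air-kerma strength with per-distance diagnostics.

    ``per_distance`` lists (r cm, K̇δ(r)·r² in U); ``converged`` is False when
    the maximum relative deviation from the mean exceeds ``tolerance``.
    """

    sk: float
    per_distance: tuple[tuple[float, float], ...]
    converged: bool
    max_relative_spread: float
    tolerance: float


def air_kerma_strength(profile: RingKermaProfile, tolerance: float = 0.01) -> SkEstimate:
    """Air-kerma strength SK = mean over distances of K̇δ(r)·r² (unit U).

    The product should be independent of distance for a far-field profile;
    ``converged`` flags profiles whose estimates spread more than
    ``tolerance`` (relative) about their mean.
    """
    if len(profile.distances) == 0:
        raise DomainError("empty ring-kerma profile")
    if len(profile.distances) < 2:
        raise DomainError("need at least 2 distances to assess distance independence")
    estimates = profile.kerma_rates * profile.distances**2
    sk = float(np.mean(estimates))
    spread = float(np.max(np.abs(estimates - sk)) / sk)
    return SkEstimate(
        sk=sk,
        per_distance=tuple(zip(profile.distances.tolist(), estimates.tolist())),
        converged=spread <= tolerance,
        max_relative_spread=spread,
        tolerance=tolerance,
    )


def dose_rate_constant(dose_at_ref: float, sk: float) -> float:
    """Λ = dose rate to the medium at (1 cm, 90°) per unit air-kerma strength."""
    if not sk > 0:
        raise DomainError(f"SK must be > 0, got {sk}")
    return dose_at_ref / sk


def consensus_lambda(lambda_exp: float, lambda_mc: float) -> float:
    """Consensus dose-rate constant: plain average of experiment and Monte Carlo."""
    if not (lambda_exp > 0 and lambda_mc > 0):
        raise DomainError("dose-rate constants must be > 0")
    return (lambda_exp + lambda_mc) / 2.0


def fit_gl_polynomial(table: RadialDoseTable, degree: int = 5) -> PolynomialFit:
    """Ordinary least-squares polynomial fit g(r) = Σ aᵢ rⁱ.

    R² = 1 − SSres/SStot with SStot taken about the mean of the g values.
    """
    n = len(table.radii)
    if n <= degree:
        raise UnderdeterminedError(
            f"{n} points cannot determine a degree-{degree} polynomial"
        )
    coeffs = np.polynomial.polynomial.polyfit(table.radii, table.g_values, degree)
    pred = np.polynomial.polynomial.polyval(table.radii, coeffs)
    ss_res = float(np.sum((table.g_values - pred) ** 2))
    ss_tot = float(np.sum((table.g_values - np.mean(table.g_values)) ** 2))
    if ss_tot == 0:
        # constant data: the LS minimizer is the constant itself; any residual
        # is roundoff
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, float(np.sum(table.g_values**2))) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PolynomialFit(
        coefficients=tuple(coeffs.tolist()),
        r_range=(float(table.radii[0]), float(table.radii[-1])),
        r_squared=min(r2, 1.0),
    )


def evaluate_gl(table_or_fit: RadialDoseTable | PolynomialFit, r: float) -> float:
    """Evaluate g(r): piecewise-linear for tables, polynomial for fits.

    Tabulated radii evaluate to their stored values exactly.  Queries outside
    the radial range raise :class:`ExtrapolationError` — never silent
    extrapolation.
    """
    if isinstance(table_or_fit, PolynomialFit):
        lo, hi = table_or_fit.r_range
        if not lo <= r <= hi:
            raise ExtrapolationError(f"r={r} cm outside fit range [{lo}, {hi}]")
        return float(np.polynomial.polynomial.polyval(r, table_or_fit.coefficients))
    t = table_or_fit
    if not t.radii[0] <= r <= t.radii[-1]:
        raise ExtrapolationError(
            f"r={r} cm outside tabulated range [{t.radii[0]}, {t.radii[-1]}]"
        )
    return float(np.interp(r, t.radii, t.g_values))


def evaluate_f(table: AnisotropyTable, r: float, theta: float) -> float:
    """Bilinear interpolation of F on the (r, θ) lattice; exact at nodes."""
    if not table.radii[0] <= r <= table.radii[-1]:
        raise ExtrapolationError(
            f"r={r} cm outside tabulated range [{table.radii[0]}, {table.radii[-1]}]"
        )
    if not table.angles[0] <= theta <= table.angles[-1]:
        raise ExtrapolationError(
            f"theta={theta} deg outside tabulated range "
            f"[{table.angles[0]}, {table.angles[-1]}]"
        )
    j = int(np.searchsorted(table.angles, theta, side="right") - 1)
    j = min(j, len(table.angles) - 2) if len(table.angles) > 1 else 0
    if len(table.angles) == 1:
        return float(np.interp(r, table.radii, table.F_values[:, 0]))
    a0, a1 = table.angles[j], table.angles[j + 1]
    w = 0.0 if a1 == a0 else (theta - a0) / (a1 - a0)
    col = (1 - w) * table.F_values[:, j] + w * table.F_values[:, j + 1]
    return float(np.interp(r, table.radii, col))


def reconstruct_dose_rate(
    dataset: ConsensusDataset, sk: float, r: float, theta: float
) -> float:
    """Forward TG-43 dose rate D(r,θ) = SK·Λ·[G/G(1,90°)]·g(r)·F(r,θ), cGy/h.

    Uses the line geometry model with the dataset's active length and the
    dataset's consensus Λ, g and F tables.
    """
    if not sk > 0:
        raise DomainError(f"SK must be > 0, got {sk}")
    model = GeometryModel.line(dataset.geometry.active_length)
    G = geometry_function(r, theta, model)
    G0 = geometry_function(R0_CM, THETA0_DEG, model)
    g = evaluate_gl(dataset.g_table, r)
    F = evaluate_f(dataset.F_table, r, theta)
    return sk * dataset.lambda_consensus * (G / G0) * g * F


def reconstruct_grid(
    g_table: RadialDoseTable,
    F_table: AnisotropyTable,
    lam: float,
    sk: float,
    model: GeometryModel,
    radii,
    angles,
    medium: str = "water",
) -> DoseRateGrid:
    """Forward-evaluate the TG-43 factorization on a polar lattice.

    Composing this with :func:`extract_radial_dose` / :func:`extract_anisotropy`
    is the identity on lattice points of any positive grid.
    """
    radii = np.asarray(radii, dtype=float)
    angles = np.asarray(angles, dtype=float)
    G = geometry_function(radii[:, None], angles[None, :], model)
    G0 = geometry_function(R0_CM, THETA0_DEG, model)
    g = np.array([evaluate_gl(g_table, r) for r in radii])
    F = np.array([[evaluate_f(F_table, r, a) for a in angles] for r in radii])
    values = sk * lam * (G / G0) * g[:, None] * F
    return DoseRateGrid(radii=radii, angles=angles, values=values, medium=medium)
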