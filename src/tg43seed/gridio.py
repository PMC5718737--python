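"""CSV exchange formats for grids, profiles and TLD readings.

Polar grids travel as CSV with a ``r_cm`` column and one ``theta_<deg>``
column per angle; ring profiles as ``r_cm,kerma_rate``; TLD readings as
``chip_id,r_cm,theta_deg,reading,is_background``.  Calibration sets are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .sources import DoseRateGrid, RingKermaProfile
from .tld import CalibrationSet, ChipReading, TLDReadingSet

__all__ = [
    "read_grid_csv",
    "write_grid_csv",
    "read_ring_profile_csv",
    "write_ring_profile_csv",
    "read_tld_readings_csv",
    "write_tld_readings_csv",
    "read_calibration_yaml",
    "write_calibration_yaml",
]


def write_grid_csv(grid: DoseRateGrid, path: str | Path) -> None:
    cols = {"r_cm": grid.radii}
    for j, a in enumerate(grid.angles):
        label = f"{a:g}"
        cols[f"theta_{label}"] = grid.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_grid_csv(path: str | Path, medium: str = "water") -> DoseRateGrid:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read grid CSV {path}: {exc}") from exc
    if "r_cm" not in df.columns:
        raise FormatError("grid CSV must have a 'r_cm' column")
    theta_cols = [c for c in df.columns if c.startswith("theta_")]
    if not theta_cols:
        raise FormatError("grid CSV must have at least one 'theta_<deg>' column")
    try:
        angles = np.array([float(c.removeprefix("theta_")) for c in theta_cols])
    except ValueError as exc:
        raise FormatError(f"malformed theta column header: {exc}") from exc
    order = np.argsort(angles)
    values = df[theta_cols].to_numpy(dtype=float)[:, order]
    return DoseRateGrid(
        radii=df["r_cm"].to_numpy(dtype=float),
        angles=angles[order],
        values=values,
        medium=medium,
    )


def write_ring_profile_csv(profile: RingKermaProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"r_cm": profile.distances, "kerma_rate": profile.kerma_rates}
    ).to_csv(path, index=False)


def read_ring_profile_csv(path: str | Path, cutoff_delta: float = 5.0) -> RingKermaProfile:
    df = pd.read_csv(path)
    for col in ("r_cm", "kerma_rate"):
        if col not in df.columns:
            raise FormatError(f"ring profile CSV must have a {col!r} column")
    return RingKermaProfile(
        distances=df["r_cm"].to_numpy(dtype=float),
        kerma_rates=df["kerma_rate"].to_numpy(dtype=float),
        cutoff_delta=cutoff_delta,
    )


def write_tld_readings_csv(readings: TLDReadingSet, path: str | Path) -> None:
    rows = [
        {
            "chip_id": c.chip_id,
            "r_cm": c.r,
            "theta_deg": c.theta,
            "reading": c.reading,
            "is_background": 0,
        }
        for c in readings.readings
    ]
    rows += [
        {"chip_id": f"bg{i:03d}", "r_cm": 0.0, "theta_deg": 0.0, "reading": b, "is_background": 1}
        for i, b in enumerate(readings.background_readings)
    ]
    df = pd.DataFrame(rows)
    df.attrs["exposure_hours"] = readings.exposure_hours
    df.to_csv(path, index=False)


def read_tld_readings_csv(path: str | Path, exposure_hours: float) -> TLDReadingSet:
    df = pd.read_csv(path)
    required = {"chip_id", "r_cm", "theta_deg", "reading", "is_background"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"TLD readings CSV missing columns: {sorted(missing)}")
    fg = df[df["is_background"] == 0]
    bg = df[df["is_background"] == 1]
    return TLDReadingSet(
        readings=[
            ChipReading(
                chip_id=str(row.chip_id), r=float(row.r_cm), theta=float(row.theta_deg),
                reading=float(row.reading),
            )
            for row in fg.itertuples()
        ],
        background_readings=bg["reading"].astype(float).tolist(),
        exposure_hours=exposure_hours,
    )


def write_calibration_yaml(cal: CalibrationSet, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "epsilon_lambda": cal.epsilon_lambda,
                "sensitivity": {k: float(v) for k, v in cal.sensitivity.items()},
                "energy_response": (
                    None
                    if cal.energy_response is None
                    else [
                        {"r_cm": k[0], "theta_deg": k[1], "E": v}
                        for k, v in cal.energy_response.items()
                    ]
                ),
                "type_b_components": [list(t) for t in cal.type_b_components],
            },
            sort_keys=False,
        )
    )


def read_calibration_yaml(path: str | Path) -> CalibrationSet:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse calibration file: {exc}") from exc
    if not isinstance(doc, dict) or "epsilon_lambda" not in doc or "sensitivity" not in doc:
        raise FormatError("calibration YAML needs 'epsilon_lambda' and 'sensitivity'")
    er = doc.get("energy_response")
    energy_response = (
        None
        if er is None
        else {(float(e["r_cm"]), float(e["theta_deg"])): float(e["E"]) for e in er}
    )
    return CalibrationSet(
        epsilon_lambda=float(doc["epsilon_lambda"]),
        sensitivity={str(k): float(v) for k, v in doc["sensitivity"].items()},
        energy_response=energy_response,
        type_b_components=tuple(
            (str(label), float(pct)) for label, pct in doc.get("type_b_components", [])
        ),
    )
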