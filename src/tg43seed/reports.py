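"""Comparison reports and table rendering.

Reproduces the study's summary artifacts: a dose-rate-constant comparison
across source models and methods, and the g(r)/F(r,θ) tables in their
customary layout (radii as rows, angles as columns).  Reports render floats
at the customary precision (3 decimals for g/F, 3 significant figures for
Λ); data files keep full precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DomainError
from .sources import AnisotropyTable, ConsensusDataset, LambdaRecord

__all__ = ["ComparisonRow", "ComparisonReport", "build_comparison", "render_tables",
           "relative_difference_percent"]


def relative_difference_percent(value: float, reference: float) -> float:
    """|value − reference| / reference × 100 (the reference is the denominator)."""
    if reference == 0:
        raise DomainError("reference value must be nonzero")
    return abs(value - reference) / abs(reference) * 100.0


@dataclass(frozen=True)
class ComparisonRow:
    source: str
    method: str
    medium: str
    value: float
    sigma: float
    reference: float | None
    relative_difference_percent: float | None


@dataclass(frozen=True)
class ComparisonReport:
    """Λ comparison table across sources and methods."""

    rows: tuple[ComparisonRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "method": r.method,
                    "medium": r.medium,
                    "lambda": r.value,
                    "sigma": r.sigma,
                    "reference": r.reference,
                    "rel_diff_pct": r.relative_difference_percent,
                }
                for r in self.rows
            ]
        )

    def to_markdown(self) -> str:
        lines = [
            "| Source | Method | Medium | Λ (cGy/(h·U)) | Reference | Δ (%) |",
            "|---|---|---|---|---|---|",
        ]
        for r in self.rows:
            lam = f"{r.value:.3g}" + (f" ± {r.sigma:.2g}" if r.sigma else "")
            ref = "n/a" if r.reference is None else f"{r.reference:.3g}"
            diff = "n/a" if r.relative_difference_percent is None else f"{r.relative_difference_percent:.2g}"
            lines.append(f"| {r.source} | {r.method} | {r.medium} | {lam} | {ref} | {diff} |")
        return "\n".join(lines) + "\n"


def build_comparison(
    datasets: Sequence[ConsensusDataset | LambdaRecord],
    references: Sequence[LambdaRecord] | dict[str, float],
) -> ComparisonReport:
    """Tabulate Λ determinations against published reference values.

    ``datasets`` may mix full consensus datasets (expanded into their
    experimental, Monte Carlo and consensus rows) and bare
    :class:`LambdaRecord` determinations.  References are matched by source
    label; a row without a matching reference is reported with its cells
    marked unavailable rather than erroring.
    """
    if not datasets:
        raise DomainError("need at least one dataset to compare")
    if isinstance(references, dict):
        ref_by_source = dict(references)
    else:
        ref_by_source = {r.source: r.value for r in references}

    records: list[LambdaRecord] = []
    for ds in datasets:
        if isinstance(ds, LambdaRecord):
            records.append(ds)
            continue
        records.extend(
            [
                LambdaRecord(ds.source_name, "TLD dosimetry", ds.medium,
                             ds.lambda_exp.value, ds.lambda_exp.sigma),
                LambdaRecord(ds.source_name, "Monte Carlo simulation", ds.medium,
                             ds.lambda_mc.value, ds.lambda_mc.sigma),
                LambdaRecord(ds.source_name, "Consensus value", ds.medium,
                             ds.lambda_consensus, 0.0),
            ]
        )
        if ds.lambda_mc_water is not None:
            records.append(
                LambdaRecord(ds.source_name, "Monte Carlo simulation", "liquid water",
                             ds.lambda_mc_water.value, ds.lambda_mc_water.sigma)
            )

    rows = []
    for rec in records:
        ref = ref_by_source.get(rec.source)
        rows.append(
            ComparisonRow(
                source=rec.source,
                method=rec.method,
                medium=rec.medium,
                value=rec.value,
                sigma=rec.sigma,
                reference=ref,
                relative_difference_percent=(
                    None if ref is None else relative_difference_percent(rec.value, ref)
                ),
            )
        )
    return ComparisonReport(rows=tuple(rows))


def _radial_frame(ds: ConsensusDataset) -> pd.DataFrame:
    cols = {"r_cm": next(iter(ds.g_tables.values())).radii}
    for name, table in ds.g_tables.items():
        cols[name] = table.g_values
    return pd.DataFrame(cols)


def _anisotropy_frame(table: AnisotropyTable) -> pd.DataFrame:
    cols = {"r_cm": table.radii}
    for j, a in enumerate(table.angles):
        cols[f"theta_{a:g}"] = table.F_values[:, j]
    return pd.DataFrame(cols)


def _frame_to_markdown(df: pd.DataFrame, ndec: int = 3) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "---|" * len(df.columns)
    lines = [header, sep]
    for _, row in df.iterrows():
        cells = []
        for col in df.columns:
            x = row[col]
            cells.append(f"{x:g}" if col == "r_cm" else f"{x:.{ndec}f}")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_tables(dataset: ConsensusDataset, format: str = "csv") -> str:
    """Render the dataset's g and F tables as one document.

    ``csv`` emits two CSV blocks separated by a blank line (full precision,
    lossless round trip through ``pandas.read_csv``); ``markdown`` emits pipe
    tables at 3-decimal precision.
    """
    gdf = _radial_frame(dataset)
    fdf = _anisotropy_frame(dataset.F_table)
    if format == "csv":
        out = io.StringIO()
        out.write("# g_table\n")
        gdf.to_csv(out, index=False)
        out.write("\n# F_table\n")
        fdf.to_csv(out, index=False)
        return out.getvalue()
    if format == "markdown":
        parts = [
            f"## Radial dose function g(r) — {dataset.source_name}\n\n",
            _frame_to_markdown(gdf),
            f"\n## Anisotropy function F(r,θ) — {dataset.source_name}\n\n",
            _frame_to_markdown(fdf),
        ]
        return "".join(parts)
    raise DomainError(f"unknown format {format!r}; use 'csv' or 'markdown'")
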