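#!/usr/bin/env python
"""Render the seed's g/F tables and the dose-rate-constant comparison
against published values for comparable commercial Pd-103 sources."""

from pathlib import Path

import tg43seed as t
from tg43seed import reports

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = t.ir06()
    (RESULTS / "seed_tables.md").write_text(reports.render_tables(ds, "markdown"))
    (RESULTS / "seed_tables.csv").write_text(reports.render_tables(ds, "csv"))

    records = t.reference_lambdas()
    refs = {
        r.source: r.value
        for r in records
        if r.citation == "published" and "Monte Carlo" in r.method
    }
    report = reports.build_comparison([ds, *records], refs)
    (RESULTS / "lambda_comparison.md").write_text(report.to_markdown())
    report.to_frame().to_csv(RESULTS / "lambda_comparison.csv", index=False)

    bench = next(r for r in report.rows
                 if r.source == "Theragenics 200" and "MCNP5" in r.method)
    print(report.to_markdown())
    print(
        f"benchmark check: {bench.value} vs published {bench.reference} -> "
        f"{bench.relative_difference_percent:.2f}% difference"
    )


if __name__ == "__main__":
    main()
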