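#!/usr/bin/env python
"""Air-kerma strength, dose-rate constant, consensus averaging, and the
fifth-order polynomial model of g(r).

SK comes from the simulated vacuum ring profile (distance-independence
check included); Lambda from the simulated transverse dose at 1 cm over SK;
the consensus value from the packaged seed dataset; and the polynomial fit
from the packaged Monte Carlo g(r) table.  Results go to results/ as JSON.
"""

import argparse
import json
from pathlib import Path

import tg43seed as t
from tg43seed import gridio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    profile = gridio.read_ring_profile_csv(RESULTS / "ring_kerma.csv")
    est = t.air_kerma_strength(profile)
    print(
        f"SK = {est.sk:.4f} U from {len(est.per_distance)} ring distances "
        f"(max spread {est.max_relative_spread:.2e}, converged={est.converged})"
    )

    grid = gridio.read_grid_csv(RESULTS / "grid_water.csv")
    i0 = list(grid.radii).index(1.0)
    j0 = list(grid.angles).index(90.0)
    lam = t.dose_rate_constant(grid.values[i0, j0], est.sk)
    print(f"Lambda = D(1 cm, 90 deg)/SK = {lam:.4f} cGy/(h*U)")

    ds = t.ir06()
    consensus = t.consensus_lambda(ds.lambda_exp.value, ds.lambda_mc.value)
    print(
        f"consensus Lambda for {ds.source_name}: "
        f"({ds.lambda_exp.value} + {ds.lambda_mc.value})/2 = {consensus:.3f} cGy/(h*U)"
    )

    fit = t.fit_gl_polynomial(ds.g_tables["perspex_mc"], degree=5)
    print(
        f"degree-5 fit of g(r), 0.5-5 cm: a0 = {fit.coefficients[0]:.3g}, "
        f"R^2 = {fit.r_squared:.4f}"
    )

    (RESULTS / "consensus_and_fit.json").write_text(
        json.dumps(
            {
                "sk_U": est.sk,
                "sk_converged": est.converged,
                "lambda_recovered": lam,
                "lambda_consensus": consensus,
                "poly_coefficients": list(fit.coefficients),
                "poly_r_squared": fit.r_squared,
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
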