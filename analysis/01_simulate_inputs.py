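#!/usr/bin/env python
"""Generate the synthetic study inputs: a Monte-Carlo-like polar dose-rate
grid in water and in Perspex, a vacuum ring-kerma profile on the transverse
axis (5-150 cm), and one radial-phantom TLD experiment.  Everything is
written under results/ in the exchange formats the analysis commands read.
"""

import argparse
from pathlib import Path

import numpy as np

import tg43seed as t
from tg43seed import gridio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--noise", type=float, default=0.01)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cfg = t.SimulatorConfig(random_seed=args.seed, noise_relative_sigma=args.noise)
    for medium, mu_scale in (("water", 1.0), ("perspex", 1.19)):
        mcfg = t.SimulatorConfig(
            random_seed=args.seed, noise_relative_sigma=args.noise,
            medium_mu=cfg.medium_mu * mu_scale,
        )
        grid, truth = t.simulate_dose_grid(mcfg, medium=medium)
        gridio.write_grid_csv(grid, RESULTS / f"grid_{medium}.csv")
        print(
            f"simulated {medium} grid {grid.values.shape} "
            f"(Lambda_true={truth.lambda_true}, SK_true={truth.sk_true} U)"
        )

    profile = t.simulate_ring_kerma(cfg, np.arange(5.0, 151.0, 5.0))
    gridio.write_ring_profile_csv(profile, RESULTS / "ring_kerma.csv")
    print(f"simulated ring-kerma profile at {len(profile.distances)} distances")

    rs, cal, truth = t.simulate_tld_experiment(cfg)
    gridio.write_tld_readings_csv(rs, RESULTS / "tld_readings.csv")
    gridio.write_calibration_yaml(cal, RESULTS / "tld_calibration.yaml")
    print(
        f"simulated TLD experiment: {len(rs.readings)} chips + "
        f"{len(rs.background_readings)} background, exposure {rs.exposure_hours} h"
    )


if __name__ == "__main__":
    main()
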