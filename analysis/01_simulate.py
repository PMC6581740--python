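#!/usr/bin/env python
"""Generate the benchmark AP-MS screens used throughout the analysis.

Writes three synthetic datasets under results/data/:

* ``spikein/`` — 20 true interactors (half with transient recruitment
  kinetics, half constitutive) among 500 background proteins plus 10
  sticky contaminants; tagged-bait vs untagged-control, 0/0.5/2/5/15 min
  time course, 3 replicates.
* ``null/`` — 2,000 background proteins and no interactors, for
  calibration checks.
* ``silac/`` — a heavy/light mixed-cell screen with interactor origins
  programmed fully-light / even / fully-heavy.
"""

import argparse
from pathlib import Path

import numpy as np

from apmsdia.simulate import SimConfig, simulate_experiment, write_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    configs = {
        "spikein": SimConfig(
            n_background_proteins=500, n_true_interactors=20, n_contaminants=10,
            seed=args.seed,
        ),
        "null": SimConfig(
            n_background_proteins=2000, n_true_interactors=0, n_contaminants=0,
            missing_rate=0.0, time_points=(0.0, 2.0), seed=args.seed + 1,
        ),
        "silac": SimConfig(
            n_background_proteins=50, n_true_interactors=9, n_contaminants=0,
            occupancy_fractions=tuple(np.geomspace(0.1, 0.5, 9)),
            silac=True, time_points=(2.0, 5.0), seed=args.seed + 2,
        ),
    }
    for name, cfg in configs.items():
        exp = simulate_experiment(cfg)
        write_experiment(exp, args.out / name)
        n_int = int(exp.truth["is_true_interactor"].sum())
        print(
            f"{name}: {len(exp.fragments):,} fragment rows, {len(exp.design)} samples, "
            f"{exp.truth.shape[0]} proteins ({n_int} true interactors) -> {args.out / name}"
        )


if __name__ == "__main__":
    main()
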