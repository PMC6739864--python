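"""Build the default encoder populations and summarise their responses.

Writes results/population_v1.json (the full population config) and
results/population_summary.csv with per-kind response statistics over a
reference phase sweep, confirming the retina/LGN variance calibration.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from untangling import make_population, mean_response_matrix

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 0):
    rng = np.random.default_rng(seed)
    phases = 360.0 * np.arange(60) / 60
    ensemble = (
        np.repeat(180.0 * np.arange(24) / 24, 60),
        np.tile(phases, 24),
        np.full(24 * 60, 3.0),
        np.full(24 * 60, 1.0),
    )
    rows = []
    pops = {}
    for kind in ("V1", "retina", "LGN"):
        pop = make_population(500, kind, np.random.default_rng(seed))
        pops[kind] = pop
        u = mean_response_matrix(pop, ensemble)
        rows.append(
            dict(
                kind=kind,
                mean_mV=u.mean(),
                per_cell_sd_mV=u.std(axis=0).mean(),
                min_mV=u.min(),
                max_mV=u.max(),
            )
        )
    pops["V1"].to_json(OUT / "population_v1.json")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "population_summary.csv", index=False)
    print(df.round(3).to_string(index=False))
    print("\nPer-cell response SDs match across kinds by construction "
          "(variance-calibrated retina/LGN gains).")


if __name__ == "__main__":
    main()
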