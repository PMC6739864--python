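"""Robust-performance regimes and the four recorded simple cells.

Computes the representational-untangling (RU) and infomax robust regimes on
a reduced grid (five FRNL exponents between 1 and 2, 2 mV thresholds) at
the recorded cells' noise-to-signal ratios, tests the cells' membership,
and runs the parameter-shuffling permutation test.  Writes
results/robust_regimes.csv and results/cell_optimality.json.

Runtime: ~10 minutes single-core.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from untangling import (
    BankSpec,
    Nuisance,
    RECORDED_CELLS,
    normalise_cells,
    optimality_test,
    robust_regime,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 5):
    cells = RECORDED_CELLS
    xis = sorted(c.noise_to_signal for c in cells)
    rng = np.random.default_rng(seed)
    ru = robust_regime(
        xis, rng, "RU",
        spec=BankSpec(m_theta=6, m_rep=3, m_rep_test=8, phase=Nuisance.var(24)),
        n=500, normalized_thresholds=np.arange(-1 / 6, 0.834, 1 / 6),
    )
    im = robust_regime(
        xis, rng, "infomax",
        spec=BankSpec(m_theta=4, m_rep=1, m_rep_test=6, phase=Nuisance.var(16)),
        n=500, normalized_thresholds=np.arange(-0.5, 1.001, 1 / 6),
        opt_eval_rows=1200,
    )
    bands = pd.DataFrame(
        dict(noise_to_signal=xis, ru_lo=ru.lo, ru_hi=ru.hi, infomax_lo=im.lo, infomax_hi=im.hi)
    )
    bands.to_csv(OUT / "robust_regimes.csv", index=False)
    print(bands.round(3).to_string(index=False))

    report = {}
    for name, regime in (("RU", ru), ("infomax", im)):
        inside, p, meta = optimality_test(cells, regime, n_shuffles=10_000, rng=rng)
        report[name] = dict(inside=inside, p_value=p, **{k: v for k, v in meta.items() if k != "observed"})
        print(f"{name}: {inside}/4 cells inside, permutation p = {p:.3f}")
    report["cells"] = [
        dict(noise_to_signal=c.noise_to_signal, normalized_threshold=c.normalized_threshold)
        for c in normalise_cells(RECORDED_CELLS)
    ]
    with open(OUT / "cell_optimality.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 5)
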