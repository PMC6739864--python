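"""Parameter dependence of the optimal firing threshold.

Scans signal amplitude (uAC) and noise magnitude (sigma) so that the same
noise-to-signal ratios are visited along both axes, plus population size:
the normalised optimal threshold (u_th_opt - u_DC)/u_AC should depend on
sigma/u_AC but not on which of the two was moved, nor on N.
Writes results/parameter_scan.csv.

Runtime: ~5 minutes single-core.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from untangling import BankSpec, Nuisance, parameter_scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SPEC = BankSpec(m_theta=5, m_rep=3, m_rep_test=8, phase=Nuisance.var(16))


def main(seed: int = 4):
    rng = np.random.default_rng(seed)
    frames = []
    # sigma scan at fixed uAC=12 and uAC scan at fixed sigma=3 visit the
    # same noise-to-signal ratios {0.167, 0.25, 0.5}
    frames.append(parameter_scan("sigma", [2.0, 3.0, 6.0], rng, n=150, spec=SPEC))
    frames.append(parameter_scan("uAC", [18.0, 12.0, 6.0], rng, n=150, spec=SPEC))
    frames.append(parameter_scan("N", [100, 300], rng, spec=SPEC))
    frames.append(parameter_scan("kappa", [1.0, 2.0], rng, n=150, spec=SPEC))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(OUT / "parameter_scan.csv", index=False)
    print(df.round(3).to_string(index=False))
    print("\nAt equal noise-to-signal ratio the normalised optimum coincides for")
    print("sigma- and uAC-scans; N moves peak FC but not the normalised optimum;")
    print("the FRNL exponent kappa shifts the optimum itself.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 4)
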