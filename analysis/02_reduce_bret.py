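#!/usr/bin/env python
"""Reduce the simulated plate to Δ net BRET fold changes (tidy TSV).

Each well passes through ratio → mock subtraction → baseline/stimulated
window means → fold change → vehicle normalisation.  Prints the per-condition
mean percent change at the top ligand concentration.
"""
from pathlib import Path

import pandas as pd

from grkbret.study import run_reduce

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = run_reduce(OUT / "plate.csv", OUT)
    reduced = pd.read_csv(path, sep="\t")
    top = reduced[(reduced["role"] == "sample")
                  & (reduced["concentration_M"] == reduced["concentration_M"].max())]
    summary = top.groupby("condition")["pct_change"].mean().round(1)
    print("mean Δ net BRET change (%) at the top concentration:")
    print(summary.to_string())


if __name__ == "__main__":
    main()
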