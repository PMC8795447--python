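#!/usr/bin/env python
"""Generate the synthetic study: BRET plates, DMR traces, receptor segments.

Writes plate.csv, dmr.csv, segments.fasta and truth.json under results/.
The study contains two GPCR–arrestin pairs — one regulated by GRK2/3 only
(with GRK2-driven pre-coupling), one by all four kinases — measured in six
rescue conditions at five ligand concentrations plus vehicle, n = 4.
"""
import sys
from pathlib import Path

from grkbret.study import run_simulate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    paths = run_simulate(OUT, seed=SEED)
    print(f"seed {SEED}: wrote")
    for k, p in paths.items():
        print(f"  {k}: {p}")


if __name__ == "__main__":
    main()
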