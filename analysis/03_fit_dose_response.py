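#!/usr/bin/env python
"""Gate each condition and fit concentration-response curves.

Conditions whose top-dose response is not significantly above vehicle
(one-sided t) are refused a curve; the rest get per-experiment log-logistic
fits (Hill slope fixed at 1) with across-experiment logEC50 mean ± SEM.
"""
import json
from pathlib import Path

from grkbret.study import run_fit

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = run_fit(OUT / "reduced.tsv", OUT)
    fits = json.loads(Path(path).read_text())
    for cond, entry in fits.items():
        if entry["fit"] is None:
            print(f"{cond}: not functional (gate p = {entry['gate']['p_value']:.3g})")
        else:
            f = entry["fit"]
            print(f"{cond}: logEC50 = {f['log_ec50']:.2f} ± {f['log_ec50_sem']:.2f}")


if __name__ == "__main__":
    main()
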