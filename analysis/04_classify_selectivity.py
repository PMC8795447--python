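#!/usr/bin/env python
"""Selectivity classification: comparisons, heatmap, clustering, pre-coupling.

Compares each pair's saturating-concentration Δ net fold changes across the
rescue conditions (ANOVA + Bonferroni vs the knockout + empty vector),
builds the signed −log10(p) heatmap, clusters pairs by Canberra distance,
assigns GRK2/3 vs GRK2/3/5/6 vs unclassified, and tests baseline elevation
(one-sided Dunnett) for pre-coupling.
"""
import json
from pathlib import Path

from grkbret.study import run_classify

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    res = run_classify(OUT / "reduced.tsv", OUT)
    print("leaf order:", " | ".join(res["leaf_order"]))
    for pair, entry in res["calls"].items():
        pre = [g for g, f in entry["precoupling"].items() if f]
        print(f"{pair}: {entry['group']}-regulated"
              + (f"; pre-coupling via {', '.join(pre)}" if pre else ""))


if __name__ == "__main__":
    main()
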