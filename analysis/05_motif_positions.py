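#!/usr/bin/env python
"""Phospho-motif positional analysis of the simulated receptor segments.

Scans all segments for the four motif grammars, dichotomises match positions
at the 0.25/0.75 breakpoints, and tests the central-vs-peripheral ×
selectivity-group association of PXPP with Fisher's exact test.
"""
from pathlib import Path

from grkbret.study import run_motifs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    assoc = run_motifs(OUT / "segments.fasta", OUT)
    r = assoc["PXPP_group"]
    odds = "inf" if r["odds_ratio"] is None else f"{r['odds_ratio']:.3g}"
    print("PXPP central/peripheral × group contingency:", r["contingency"])
    print(f"Fisher's exact test: odds ratio = {odds}, p = {r['p_two_sided']:.3g}")


if __name__ == "__main__":
    main()
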