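#!/usr/bin/env python
"""Model-human alignment summary over the Experiment-1 tables.

Reads the CCI tables written by analysis/03, recomputes accuracy, bias,
normalized error, Lin's CCC, the leave-one-out human agreement and the
normalized CCC per agent and scene grouping, and writes a flat metrics
table. The ncCCC column answers the headline question: does any agent
track the mean human observer better than individual humans do (> 1)?
"""

import sys
from pathlib import Path

import pandas as pd

from constancy import pipeline as pl

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    src = OUT / "exp1_cci.csv"
    if not src.exists():
        sys.exit("run analysis/03_experiment1_mechanisms.py first")
    cci = pd.read_csv(src).fillna({"surround": ""})
    frames = []
    for grouping in ("all", "indoor", "outdoor"):
        sub = cci if grouping == "all" else cci[cci["scene"] == grouping]
        rep = pl.agreement_reports(sub)
        rep.insert(0, "grouping", grouping)
        frames.append(rep)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "agreement_metrics.csv", index=False)
    pretty = table.set_index(["grouping", "agent"]).round(3)
    print(pretty.to_string())
    best = table[(table["grouping"] == "all")
                 & (~table["agent"].isin(["oracle", "tristimulus"]))]
    top = best.sort_values("nccc", ascending=False).iloc[0]
    print(f"\nBest human alignment (all conditions): {top.agent} "
          f"(ncCCC = {top.nccc:.3f}, LOO = {top.loo:.3f}).")


if __name__ == "__main__":
    main()
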