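#!/usr/bin/env python
"""Experiment 1: cue-silencing mechanisms, all agents.

Scores synthetic human observers, the trained reflectance net (if
analysis/02 has produced a checkpoint), the five classical estimators and
the oracle/tristimulus anchors over {scene x mechanism x illuminant},
writes the CCI and ΔCCI tables, and prints the mechanism ranking that the
study design is built to expose.
"""

import sys
from pathlib import Path

from constancy import pipeline as pl
from constancy import reflectance as rf

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    OUT.mkdir(exist_ok=True)
    config = pl.ExperimentConfig(seed=SEED)
    ckpt = OUT / "reflectance_net.npz"
    model = rf.load_model(ckpt) if ckpt.exists() else None
    if model is None:
        print("note: no checkpoint at results/reflectance_net.npz; "
              "running without the learned model (see analysis/02).")
    tables = pl.run_experiment1(config, model=model)
    tables["cci"].to_csv(OUT / "exp1_cci.csv", index=False)
    tables["delta"].to_csv(OUT / "exp1_delta.csv", index=False)
    tables["agreement"].to_csv(OUT / "exp1_agreement.csv", index=False)
    print(pl.make_report(tables))

    # Inter-/intra-participant variability of the synthetic observer pool.
    from constancy import scaling as sca

    cci = tables["cci"]
    humans = cci[cci["kind"] == "human"]
    for scene, grp in humans.groupby("scene"):
        vectors = {a: g.sort_values(["mechanism", "illuminant"])["cci"].to_numpy()
                   for a, g in grp.groupby("agent")}
        inter, intra = sca.variability_stats(vectors)
        import numpy as np

        print(f"{scene}: inter-participant r mean {np.mean(list(inter.values())):.2f}"
              f", intra-participant CV mean {np.mean(list(intra.values())):.3f}")


if __name__ == "__main__":
    main()
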