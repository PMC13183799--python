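#!/usr/bin/env python
"""Experiment 2: local-surround color x illuminant direction.

Runs the per-surround baseline vs. silenced-leaf comparison for the four
colored surrounds, labels illuminants Neighboring/Opposing, writes the
tables, and prints the ΔCCI split by direction — the signature of the
surround-illuminant interaction.
"""

import sys
from pathlib import Path

from constancy import pipeline as pl
from constancy import reflectance as rf

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    OUT.mkdir(exist_ok=True)
    config = pl.ExperimentConfig(seed=SEED, n_participants_exp2=8,
                                 mlds_restarts=6)
    ckpt = OUT / "reflectance_net.npz"
    model = rf.load_model(ckpt) if ckpt.exists() else None
    tables = pl.run_experiment2(config, model=model)
    tables["cci"].to_csv(OUT / "exp2_cci.csv", index=False)
    tables["delta"].to_csv(OUT / "exp2_delta.csv", index=False)

    d = tables["delta"]
    print("Mean ΔCCI by direction (local-surround silencing):")
    for kind in ("human", "image_agent"):
        sub = d[d["kind"] == kind]
        if not len(sub):
            continue
        by = sub.groupby(["scene", "direction"])["delta_cci"].mean().round(1)
        label = "synthetic humans" if kind == "human" else "image agents"
        print(f"  {label}:")
        print(by.to_string())


if __name__ == "__main__":
    main()
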