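#!/usr/bin/env python
"""Train the 3-10-1 logistic network on the scored cohort.

Predicts the Power of Honey from free acidity and the L*, a* colour
coordinates, using a 60/20/20 split and BFGS sum-of-squares minimisation
(best of 10 restarts by validation SOS). Writes the model JSON and the
per-split fit report.
"""

import json
from pathlib import Path

import pandas as pd

import honeypower as hp

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    samples = pd.read_csv(OUT / "samples.csv")
    indices = pd.read_csv(OUT / "indices.csv")
    table = pd.DataFrame({
        "free_acidity": samples["free_acidity"],
        "colour_L": samples["colour_L"],
        "colour_a": samples["colour_a"],
        "power_of_honey": indices["power_of_honey"],
    })
    weights, norm, report = hp.train(table, split=hp.SplitSpec(seed=7), seed=11)
    hp.save_model(OUT / "model.json", weights, norm)
    (OUT / "fit_report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))

    print(f"trained 3-10-1 network ({hp.count_parameters(weights)} parameters)")
    for split in ("train", "validation", "test"):
        print(f"  {split:10s} r2 = {report.r2[split]:.3f}   SOS = {report.sos[split]:.4f}")
    print(f"wrote {OUT / 'model.json'}")


if __name__ == "__main__":
    main()
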