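#!/usr/bin/env python
"""Generate a synthetic imaging experiment and export one animal.

Eight synthetic animals, three odorants each, 25 glomeruli, 20 trials on
the 5 s ON / 25 s OFF schedule at 127 Hz.  Writes one animal's long-form
CSV (time-decimated for compactness) plus its JSON sidecar, and a summary
of the drawn response-group composition.
"""

import sys
from pathlib import Path

import dataclasses

import numpy as np
import pandas as pd

from beemb.io import RunConfig, write_dataset
from beemb.synthetic import GROUP_ORDER, GeneratorConfig, make_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    cfg = RunConfig(master_seed=seed)
    gen = GeneratorConfig(**{**cfg.generator.to_dict(),
                             "seed": cfg.seed_for("dataset")})
    bees = make_experiment(gen, cfg.protocol, n_bees=8)
    OUT.mkdir(exist_ok=True)
    # keep the checked-in example compact: 2 glomeruli, 2 trials, 40x
    # time decimation (the full dataset is regenerated from the seed)
    example = dataclasses.replace(
        bees[0], traces=bees[0].traces[:, :2, :2], mean=bees[0].mean[:, :2],
        groups=bees[0].groups[:, :2], onset_ms=bees[0].onset_ms[:, :2],
        termination_ms=bees[0].termination_ms[:, :2])
    write_dataset(example, OUT / "example_bee.csv",
                  OUT / "example_bee.json", decimate=40)
    rows = []
    for ds in bees:
        counts = {f"group_{g}": int((ds.groups == g).sum())
                  for g in GROUP_ORDER}
        rows.append({"bee": ds.bee, "n_profiles": ds.groups.size, **counts})
    comp = pd.DataFrame(rows)
    comp.to_csv(OUT / "dataset_composition.csv", index=False)
    total = comp["n_profiles"].sum()
    exc = comp[[f"group_{g}" for g in (4, 5, 6, 7, 8)]].to_numpy().sum()
    inh = comp[[f"group_{g}" for g in (1, 2, 3)]].to_numpy().sum()
    print(f"Simulated {len(bees)} animals, {total} glomerulus x odorant "
          f"profiles: {100 * exc / total:.0f}% excitatory, "
          f"{100 * inh / total:.0f}% inhibitory, "
          f"{100 * (total - exc - inh) / total:.0f}% non-responsive.")
    print(f"Example animal exported to {OUT / 'example_bee.csv'} "
          "(trimmed subset).")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
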