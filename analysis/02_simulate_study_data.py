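#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the study layout: a 70-compound training table with the five
descriptors and −log(IC50) responses generated from the one-descriptor
lipophilicity equation plus Gaussian noise (sd 0.4), and a 28-compound
external set carrying more/less-potent-than-reference labels.  Writes
results/training_synthetic.csv, results/external_synthetic.csv and a
manifest recording the configuration.
"""

import json
from pathlib import Path

import pandas as pd

from estroqsar.models import get_model
from estroqsar.simulate import GeneratorConfig, generate_external_set, generate_training_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2013


def main() -> None:
    OUT.mkdir(exist_ok=True)
    model = get_model("Eq4")
    cfg = GeneratorConfig(model=model, n_compounds=70, noise_sd=0.4, seed=SEED)

    table = generate_training_table(cfg)
    frame = table.descriptors.copy()
    frame.insert(0, "id", table.ids)
    frame["neglog_ic50"] = table.y
    frame.to_csv(OUT / "training_synthetic.csv", index=False)

    externals, reference = generate_external_set(cfg, label_noise=0.0)
    ext = pd.DataFrame(
        [{"id": c.id, **c.descriptors.as_dict(), "label": c.observed_label} for c in externals]
    )
    ext.to_csv(OUT / "external_synthetic.csv", index=False)

    manifest = {
        "generating_model": model.to_dict(),
        "n_compounds": cfg.n_compounds,
        "noise_sd": cfg.noise_sd,
        "ranges": cfg.ranges,
        "seed": SEED,
        "external_size": cfg.external_size,
        "reference": reference.as_dict(),
        "label_noise": 0.0,
    }
    (OUT / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    print(f"training table: {len(frame)} compounds -> results/training_synthetic.csv")
    print(f"  response range: {table.y.min():.2f} .. {table.y.max():.2f} (-log10 M)")
    labels = ext["label"].value_counts().to_dict()
    print(f"external set: {len(ext)} compounds -> results/external_synthetic.csv ({labels})")


if __name__ == "__main__":
    main()
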