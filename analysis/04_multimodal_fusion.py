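#!/usr/bin/env python
"""Multimodal fusion: does adding autofluorescence close the gap to
high-resolution FTIR?

Runs the full pipeline on 25 seeded 256×256 phantoms with default noise and
compares, per replicate, the against-truth ARI of (i) the fused
MIR + autofluorescence cube, (ii) the coarse 20 µm MIR scan and (iii) the
6.25 µm FTIR reference, plus the FTIR-vs-multimodal and FTIR-vs-MIR pairwise
ARIs.  The expected picture: fusion beats the coarse scan in essentially
every replicate and approaches the FTIR reference, mirroring the instrument
study's ordering of modality agreement.

Writes results/multimodal_fusion.csv and results/multimodal_fusion.json.
"""

import json
from pathlib import Path

import pandas as pd

from mirfluor.phantom import PhantomConfig
from mirfluor.pipeline import RunConfig, run_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
N_REPLICATES = 25


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for seed in range(N_REPLICATES):
        cfg = RunConfig(
            seed=seed,
            phantom=PhantomConfig(width=256, height=256),
            modalities=("mir20", "multimodal", "ftir6.25"),
        )
        rep = run_experiment(cfg)
        rows.append(
            {
                "seed": seed,
                "ari_truth_multimodal": rep.ari_truth["multimodal"],
                "ari_truth_mir20": rep.ari_truth["mir20"],
                "ari_truth_ftir625": rep.ari_truth["ftir6.25"],
                "ari_ftir_vs_multimodal": rep.ari_pairwise["ftir6.25"]["multimodal"],
                "ari_ftir_vs_mir20": rep.ari_pairwise["ftir6.25"]["mir20"],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "multimodal_fusion.csv", index=False)
    summary = {
        "n_replicates": N_REPLICATES,
        "mean_ari_truth": {
            "multimodal": df["ari_truth_multimodal"].mean(),
            "mir20": df["ari_truth_mir20"].mean(),
            "ftir6.25": df["ari_truth_ftir625"].mean(),
        },
        "mean_ari_ftir_vs_multimodal": df["ari_ftir_vs_multimodal"].mean(),
        "mean_ari_ftir_vs_mir20": df["ari_ftir_vs_mir20"].mean(),
        "fusion_beats_mir20_fraction": float(
            (df["ari_truth_multimodal"] > df["ari_truth_mir20"]).mean()
        ),
    }
    print(json.dumps(summary, indent=2))
    (OUT / "multimodal_fusion.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
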