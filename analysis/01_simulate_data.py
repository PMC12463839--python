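"""Simulate the synthetic screening study inputs.

Writes under results/synthetic/:
  sequences/   ASV + per-region reference FASTA and the planted-divergence
               truth table (which ASV came from which isolate, and at what
               percent identity);
  trial.csv    a 3 genotype x 5 treatment RCBD trial (9 blocks, ~8% plot
               dropout) with dry shoot weights in grams;
  trial_truth.csv  the generative decomposition of every plot;
  images/      8 views for each of the first 24 trial plants, silhouette
               area proportional to the plant's dry weight, with clutter
               and mild sensor noise, plus the exact foreground truth;
  weights.csv  the dry weights of the imaged plants.
"""

import argparse
from pathlib import Path

import numpy as np

from rhizoscreen.pipeline import default_trial_config
from rhizoscreen.simdata import (
    ImageSimConfig,
    SequenceSimConfig,
    simulate_plant_images,
    simulate_sequences,
    simulate_trial,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results") / "synthetic")
    ap.add_argument("--n-image-plants", type=int, default=24)
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    seqs = simulate_sequences(SequenceSimConfig(seed=args.seed))
    seqs.write_fasta(out / "sequences")
    seqs.truth.to_csv(out / "sequences" / "truth.csv", index=False)
    planted = (seqs.truth["source_isolate"] != "").sum()
    print(f"sequences: {len(seqs.asvs)} ASVs ({planted} planted from "
          f"{len(seqs.full_length)} isolates), identities "
          f"{seqs.truth['expected_percent_identity'].min():.3f}-"
          f"{seqs.truth['expected_percent_identity'].max():.3f}%")

    trial_cfg = default_trial_config(seed=args.seed + 2)
    trial = simulate_trial(trial_cfg)
    trial.data.to_csv(out / "trial.csv", index=False)
    trial.truth.to_csv(out / "trial_truth.csv", index=False)
    print(f"trial: {len(trial.data)} plants, "
          f"{trial.data['block'].nunique()} blocks, mean dry weight "
          f"{trial.data['response'].mean():.3f} g")

    sample = trial.data.iloc[:args.n_image_plants]
    weights = sample[["plant_id", "response"]].rename(
        columns={"response": "weight_g"})
    weights.to_csv(out / "weights.csv", index=False)
    scales = {r.plant_id: float(np.clip(r.weight_g / trial_cfg.mu, 0.05, 2.0))
              for r in weights.itertuples()}
    img_cfg = ImageSimConfig(seed=args.seed + 3, plant_area_px=600,
                             clutter_area_px=200, noise_sd=0.02)
    imgs = simulate_plant_images(img_cfg, scales)
    imgs.write_png(out / "images")
    imgs.truth.to_csv(out / "images" / "truth.csv", index=False)
    print(f"images: {len(scales)} plants x {img_cfg.n_views} views "
          f"-> {out / 'images'}")


if __name__ == "__main__":
    main()
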