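"""Extract shoot traits from the plant images and calibrate against weights.

Runs green-channel segmentation (Otsu threshold, 0.9 distance mask) on
every view, aggregates per plant, and correlates aggregated pixel biomass
with the destructive dry shoot weights.  Writes per-view and aggregate
trait tables, the calibration line, and a pixels-vs-weight scatter plot.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from rhizoscreen import phenotype


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results") / "synthetic")
    ap.add_argument("--out", type=Path,
                    default=Path("results") / "phenotyping")
    ap.add_argument("--mask-radius", type=float, default=0.9)
    ap.add_argument("--agg", choices=("mean", "sum"), default="mean")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    images = phenotype.load_view_images(args.data / "images")
    params = phenotype.SegmentationParams(
        mask_radius_fraction=args.mask_radius, min_object_px=8)
    per_view, aggregate = phenotype.phenotype_plants(images, params,
                                                     agg=args.agg)
    per_view.to_csv(args.out / "traits_per_view.csv", index=False)
    aggregate.to_csv(args.out / "traits_aggregate.csv", index=False)

    weights = pd.read_csv(args.data / "weights.csv")
    calib = phenotype.calibrate(aggregate, weights)
    (args.out / "calibration.json").write_text(json.dumps({
        "n_plants": calib.n_plants, "pearson_r": round(calib.pearson_r, 4),
        "slope_g_per_px": calib.slope, "intercept_g": calib.intercept,
    }, indent=2, sort_keys=True) + "\n")

    merged = aggregate.merge(weights, on="plant_id")
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(merged["pixel_biomass"], merged["weight_g"], s=18)
    xs = merged["pixel_biomass"].sort_values()
    ax.plot(xs, calib.predict(xs), lw=1)
    ax.set_xlabel("predicted biomass (pixels)")
    ax.set_ylabel("dry shoot weight (g)")
    ax.set_title(f"r = {calib.pearson_r:.3f} (n = {calib.n_plants})")
    fig.tight_layout()
    fig.savefig(args.out / "calibration.png", dpi=120)

    print(f"phenotyped {len(images)} plants "
          f"({len(per_view)} views); pixel biomass vs dry weight "
          f"r = {calib.pearson_r:.3f}")


if __name__ == "__main__":
    main()
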