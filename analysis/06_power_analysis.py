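"""Design power: how replication changes detection of interaction effects.

Simulates the study-like trial at several block counts, with and without
the planted genotype x isolate interaction, and tabulates the rejection
rate of the interaction F-test and of the isolate-vs-control contrasts.
"""

import argparse
import dataclasses
from pathlib import Path

from rhizoscreen import rcbd
from rhizoscreen.pipeline import default_trial_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--sims", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results") / "power")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    base = default_trial_config(seed=0)
    null = dataclasses.replace(base, interaction_effects={})
    grid = []
    for n_blocks in (3, 6, 9):
        grid.append(dataclasses.replace(null, n_blocks=n_blocks))
        grid.append(dataclasses.replace(base, n_blocks=n_blocks))
    table = rcbd.power_analysis(grid, n_sims=args.sims, seed=args.seed)
    table["interaction_planted"] = [False, True] * 3
    table.to_csv(args.out / "power.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    planted = table[table["interaction_planted"]]
    print(f"interaction power grows with blocks: "
          f"{planted['power_interaction'].tolist()} at 3/6/9 blocks")


if __name__ == "__main__":
    main()
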