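"""Randomized-complete-block factorial trial simulator.

Responses are generated additively,

    y_gib = mu + genotype_g + isolate_i + interaction_gi + block_b + e_gib,

with block effects drawn N(0, sigma_block^2), residuals N(0, sigma_e^2),
and one replicate of every genotype x isolate cell per block.  Independent
per-plot dropout emulates the uneven cell sizes (n = 4..9) a greenhouse
trial accumulates through poor emergence.  The returned table stores every
additive component alongside the response so the decomposition can be
re-assembled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TrialSimConfig:
    """Configuration for the RCBD trial simulator.

    Effects are mappings from level to additive effect (grams) and must sum
    to zero within each factor (identifiability under sum-to-zero coding);
    ``interaction_effects`` maps ``(genotype, isolate)`` pairs and must sum
    to zero across each row and column.  Omitted levels get effect 0 —
    in that case the stated levels' effects must themselves balance.
    """

    seed: int = 0
    genotypes: tuple[str, ...] = ("Mo17", "PI606768", "NSL30867")
    isolates: tuple[str, ...] = ("iso111", "iso730", "iso4589", "LNC", "HNC")
    n_blocks: int = 9
    mu: float = 1.0
    genotype_effects: dict[str, float] = field(default_factory=dict)
    isolate_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str], float] = field(
        default_factory=dict)
    sigma_block: float = 0.1
    sigma_e: float = 0.2
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if min(self.sigma_block, self.sigma_e) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.dropout_prob <= 0.5:
            raise ValueError("dropout_prob must be in [0, 0.5]")
        for name, eff, levels in (
            ("genotype_effects", self.genotype_effects, self.genotypes),
            ("isolate_effects", self.isolate_effects, self.isolates),
        ):
            unknown = set(eff) - set(levels)
            if unknown:
                raise ValueError(f"{name} references unknown levels {unknown}")
            if abs(sum(eff.values())) > _SUM_TOL:
                raise ValueError(f"{name} must sum to zero")
        unknown = {k for k in self.interaction_effects
                   if k[0] not in self.genotypes or k[1] not in self.isolates}
        if unknown:
            raise ValueError(f"interaction_effects references {unknown}")
        for g in self.genotypes:
            s = sum(v for (gg, _), v in self.interaction_effects.items()
                    if gg == g)
            if abs(s) > _SUM_TOL:
                raise ValueError(f"interaction effects do not sum to zero "
                                 f"within genotype {g}")
        for i in self.isolates:
            s = sum(v for (_, ii), v in self.interaction_effects.items()
                    if ii == i)
            if abs(s) > _SUM_TOL:
                raise ValueError(f"interaction effects do not sum to zero "
                                 f"within isolate {i}")


@dataclass
class TrialSimResult:
    """Simulated trial with its generative decomposition.

    ``data`` holds the analysis columns (``plant_id``, ``genotype``,
    ``isolate``, ``block``, ``response``); ``truth`` additionally stores
    ``mu``, ``genotype_effect``, ``isolate_effect``, ``interaction_effect``,
    ``block_effect`` and ``residual`` for every retained plot, plus a
    ``dropped`` flag for removed ones.
    """

    data: pd.DataFrame
    truth: pd.DataFrame
    block_effects: dict[str, float]


def simulate_trial(config: TrialSimConfig) -> TrialSimResult:
    """Draw one RCBD trial; raise if dropout empties any treatment cell."""
    rng = np.random.default_rng(config.seed)
    blocks = [f"B{b + 1}" for b in range(config.n_blocks)]
    block_eff = {b: rng.normal(0.0, config.sigma_block) for b in blocks}

    rows = []
    plant = 0
    for b in blocks:
        for g in config.genotypes:
            for iso in config.isolates:
                plant += 1
                ge = config.genotype_effects.get(g, 0.0)
                ie = config.isolate_effects.get(iso, 0.0)
                inte = config.interaction_effects.get((g, iso), 0.0)
                resid = rng.normal(0.0, config.sigma_e)
                dropped = rng.uniform() < config.dropout_prob
                rows.append({
                    "plant_id": f"p{plant:04d}", "genotype": g,
                    "isolate": iso, "block": b,
                    "mu": config.mu, "genotype_effect": ge,
                    "isolate_effect": ie, "interaction_effect": inte,
                    "block_effect": block_eff[b], "residual": resid,
                    "response": config.mu + ge + ie + inte
                    + block_eff[b] + resid,
                    "dropped": dropped,
                })
    truth = pd.DataFrame(rows)
    kept = truth[~truth["dropped"]]
    cell_n = kept.groupby(["genotype", "isolate"], sort=False).size()
    if len(cell_n) < len(config.genotypes) * len(config.isolates):
        raise ValueError(
            "dropout removed every replicate of at least one genotype x "
            "isolate cell; lower dropout_prob or change the seed"
        )
    data = kept[["plant_id", "genotype", "isolate", "block",
                 "response"]].reset_index(drop=True)
    return TrialSimResult(data=data, truth=truth, block_effects=block_eff)
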