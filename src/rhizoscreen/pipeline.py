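"""End-to-end screening pipeline over synthetic study data.

``run_pipeline`` chains the five stages — simulate, match, tree,
phenotype, trial statistics — from a single master seed and writes every
artifact (FASTA, TSV/CSV, Newick, PNG, text reports) under one output
directory.  All stage seeds derive deterministically from the master
seed, so two runs with the same seed produce byte-identical output trees.

The default simulation mirrors the screening study the pipeline is built
for: 63 culture-collection isolates, 100 ASVs of which 87% derive from an
isolate at 0-4.8% divergence (percent identities spanning ~95.2-100),
a 3 genotype x 5 treatment randomized complete block trial with 9 blocks,
and 8 views per plant on the imaging side.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from rhizoscreen import matching, phenotype, phylo, rcbd
from rhizoscreen.simdata import (
    ImageSimConfig,
    SequenceSimConfig,
    TrialSimConfig,
    simulate_plant_images,
    simulate_sequences,
    simulate_trial,
)


def default_trial_config(seed: int = 0) -> TrialSimConfig:
    """Study-like 3 x 5 factorial RCBD with one responsive cell.

    Effects are in grams around a 1.2 g grand mean; the interaction puts
    the growth benefit of one isolate (iso730) on one genotype (Mo17),
    the host-specificity pattern the screening design is meant to detect.
    """
    u = {"Mo17": 1.0, "PI606768": -0.5, "NSL30867": -0.5}
    v = {"iso730": 1.0, "iso111": -0.25, "iso4589": -0.25,
         "LNC": -0.25, "HNC": -0.25}
    delta = 0.18
    return TrialSimConfig(
        seed=seed,
        genotypes=("Mo17", "PI606768", "NSL30867"),
        isolates=("iso111", "iso730", "iso4589", "LNC", "HNC"),
        n_blocks=9,
        mu=1.2,
        genotype_effects={"Mo17": -0.15, "PI606768": 0.05, "NSL30867": 0.10},
        isolate_effects={"iso111": 0.0, "iso730": 0.05, "iso4589": -0.05,
                         "LNC": -0.10, "HNC": 0.10},
        interaction_effects={(g, i): delta * ug * vi
                             for g, ug in u.items()
                             for i, vi in v.items()},
        sigma_block=0.10,
        sigma_e=0.18,
        dropout_prob=0.08,
    )


@dataclass
class PipelineResult:
    """Key quantities computed by one pipeline run."""

    match_report: dict
    matched_identity_range: tuple[float, float]
    n_matched_isolates: int
    consensus_newick: str
    calibration: phenotype.CalibrationResult
    f_table: pd.DataFrame
    letters: dict[str, str]
    outdir: Path


def run_pipeline(seed: int, outdir: str | Path, *,
                 n_isolates: int = 63, n_asvs: int = 100,
                 bootstrap_reps: int = 100, tree_taxa: int = 16,
                 n_image_plants: int = 24,
                 image_size: tuple[int, int] = (160, 160),
                 min_identity: float = 95.0) -> PipelineResult:
    """Run simulate -> match -> tree -> pheno -> stats; write artifacts.

    ``tree_taxa`` caps the number of matched isolates carried into the
    bootstrap phylogeny and ``n_image_plants`` the number of plants that
    are imaged, keeping a full run inside interactive time.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: sequences ------------------------------------------------
    seq_cfg = SequenceSimConfig(seed=seed, n_isolates=n_isolates,
                                n_asvs=n_asvs)
    seqs = simulate_sequences(seq_cfg)
    seqs.write_fasta(outdir / "sequences")
    seqs.truth.to_csv(outdir / "sequences" / "truth.csv", index=False)

    # -- stage 2: matching -------------------------------------------------
    ref_records = [
        matching.SequenceRecord(id=f"{iso}|{region}", residues=seq,
                                region=region, isolate_id=iso)
        for region, entries in seqs.regions.items()
        for iso, seq in entries.items()
    ]
    index = matching.build_reference_index(ref_records)
    hits = matching.match_asvs(seqs.asvs, index)
    table = matching.collate_matches(
        hits, {a: len(s) for a, s in seqs.asvs.items()})
    table.to_tsv(outdir / "match_table.tsv")
    summaries, report = matching.summarize_isolates(
        table, min_identity=min_identity)
    matching.summaries_to_frame(summaries).to_csv(
        outdir / "isolate_summaries.tsv", sep="\t", index=False)
    (outdir / "match_report.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in sorted(report.items())) + "\n")
    identities = [s.best_percent_identity for s in summaries]
    id_range = ((min(identities), max(identities)) if identities
                else (float("nan"), float("nan")))

    # -- stage 3: phylogeny of matched isolates ----------------------------
    matched = sorted(s.isolate_id for s in summaries)[:tree_taxa]
    msa = phylo.MultipleAlignment(
        taxa=matched, rows=[seqs.regions["merged"][iso] for iso in matched])
    consensus = phylo.bootstrap_consensus(
        msa, n_reps=bootstrap_reps, collapse_threshold=0.5, seed=seed + 1)
    newick = consensus.newick()
    (outdir / "consensus_tree.nwk").write_text(newick + "\n")
    consensus.bipartition_table().to_csv(outdir / "bipartitions.tsv",
                                         sep="\t", index=False)

    # -- stage 4: trial simulation and mixed-model inference ---------------
    trial_cfg = default_trial_config(seed=seed + 2)
    trial = simulate_trial(trial_cfg)
    trial.data.to_csv(outdir / "trial.csv", index=False)
    fit = rcbd.fit_rcbd_lmm(trial.data)
    f_table = rcbd.anova_f_tests(fit)
    f_table.to_csv(outdir / "f_table.tsv", sep="\t", index=False)
    lsm = rcbd.ls_means(fit, "cell")
    lsm.to_csv(outdir / "ls_means.tsv", sep="\t", index=False)
    tukey = rcbd.tukey_hsd(fit, "cell")
    tukey.comparisons.to_csv(outdir / "tukey.tsv", sep="\t", index=False)
    (outdir / "trial_report.txt").write_text(rcbd.trial_report(fit) + "\n")

    # -- stage 5: imaging and calibration ----------------------------------
    sample = trial.data.iloc[:n_image_plants]
    weights = sample[["plant_id", "response"]].rename(
        columns={"response": "weight_g"}).reset_index(drop=True)
    scales = {row.plant_id: float(np.clip(row.weight_g / trial_cfg.mu,
                                          0.05, 2.0))
              for row in weights.itertuples()}
    # base silhouette area scales with the frame so every growth multiplier
    # stays inside the central disk
    area = int(600 * (min(image_size) / 160) ** 2)
    img_cfg = ImageSimConfig(seed=seed + 3, image_size=image_size,
                             plant_area_px=area,
                             clutter_area_px=200, noise_sd=0.02)
    imgs = simulate_plant_images(img_cfg, scales)
    imgs.write_png(outdir / "images")
    imgs.truth.to_csv(outdir / "images" / "truth.csv", index=False)
    per_view, aggregate = phenotype.phenotype_plants(imgs.images)
    per_view.to_csv(outdir / "traits_per_view.csv", index=False)
    aggregate.to_csv(outdir / "traits_aggregate.csv", index=False)
    calib = phenotype.calibrate(aggregate, weights)
    (outdir / "calibration.json").write_text(json.dumps({
        "n_plants": calib.n_plants, "pearson_r": round(calib.pearson_r, 6),
        "slope": calib.slope, "intercept": calib.intercept,
    }, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        match_report=report, matched_identity_range=id_range,
        n_matched_isolates=report["n_matched_isolates"],
        consensus_newick=newick, calibration=calib, f_table=f_table,
        letters=tukey.letters, outdir=outdir)


def calibration_regime(target_r: float, n_plants: int, seed: int,
                       image_config: ImageSimConfig | None = None,
                       ) -> float:
    """One calibration draw at an analytically fixed correlation.

    Plants with lognormal growth scales are imaged and phenotyped; dry
    weights are then generated as ``a * pixels + noise`` with the noise
    standard deviation chosen so the analytic correlation
    ``a * sd(pixels) / sqrt(a^2 var(pixels) + sigma^2)`` equals
    ``target_r``.  Returns the measured Pearson r.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    # modest base area + capped scale spread keep every silhouette inside
    # the frame across thousands of draws
    cfg = image_config or ImageSimConfig(seed=seed, n_views=2,
                                         image_size=(160, 160),
                                         plant_area_px=500)
    scales = np.exp(np.clip(rng.normal(0.0, 0.25, size=n_plants),
                            -1.0, 1.0))
    result = simulate_plant_images(cfg, list(scales))
    _, aggregate = phenotype.phenotype_plants(result.images)
    pixels = aggregate["pixel_biomass"].to_numpy(float)
    a = 1e-3  # grams per pixel
    sd_pix = pixels.std(ddof=1)
    sigma = a * sd_pix * np.sqrt(1.0 / target_r ** 2 - 1.0)
    weights = a * pixels + rng.normal(0.0, sigma, size=n_plants)
    calib = phenotype.calibrate(
        aggregate,
        pd.DataFrame({"plant_id": aggregate["plant_id"],
                      "weight_g": weights}))
    return calib.pearson_r
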