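"""Mixed-model fit, F tests, LS-means, Tukey-Kramer and letter display."""

import dataclasses
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import gls_lsmean
from rhizoscreen import rcbd
from rhizoscreen.rcbd import (
    anova_f_tests,
    compact_letter_display,
    fit_rcbd_lmm,
    ls_means,
    tukey_hsd,
)
from rhizoscreen.simdata import TrialSimConfig, simulate_trial

BALANCED = TrialSimConfig(
    seed=7, sigma_block=0.3, sigma_e=0.2, dropout_prob=0.0,
    genotype_effects={"Mo17": 0.2, "PI606768": -0.1, "NSL30867": -0.1},
    isolate_effects={"iso111": 0.1, "iso730": 0.05, "iso4589": -0.05,
                     "LNC": -0.2, "HNC": 0.1})


@pytest.fixture(scope="module")
def balanced_fit():
    sim = simulate_trial(BALANCED)
    return sim, fit_rcbd_lmm(sim.data, high_n_label=None)


class TestFit:
    def test_noiseless_data_fit_exactly(self):
        cfg = dataclasses.replace(BALANCED, sigma_block=0.0, sigma_e=0.0,
                                  seed=1)
        sim = simulate_trial(cfg)
        fit = fit_rcbd_lmm(sim.data, high_n_label=None)
        assert fit.sigma2_e < 1e-12
        assert np.allclose(fit.fitted_values,
                           sim.data.sort_values(
                               ["block", "genotype", "isolate", "plant_id"]
                           )["response"], atol=1e-6)

    def test_zero_block_variance_estimated_near_zero(self):
        rates = []
        for seed in range(30):
            cfg = dataclasses.replace(BALANCED, sigma_block=0.0, seed=seed)
            fit = fit_rcbd_lmm(simulate_trial(cfg).data, high_n_label=None)
            rates.append(fit.sigma2_block)
        # half the REML estimates truncate at the boundary under the null
        assert np.median(rates) < 0.005

    def test_variance_recovery_within_tolerance(self):
        s2b, s2e = [], []
        for seed in range(60):
            cfg = dataclasses.replace(BALANCED, sigma_block=0.5, sigma_e=1.0,
                                      seed=100 + seed)
            fit = fit_rcbd_lmm(simulate_trial(cfg).data, high_n_label=None)
            s2b.append(fit.sigma2_block)
            s2e.append(fit.sigma2_e)
        assert np.mean(s2b) == pytest.approx(0.25, rel=0.35)
        assert np.mean(s2e) == pytest.approx(1.0, rel=0.10)

    def test_matches_statsmodels_mixedlm(self, balanced_fit):
        smf = pytest.importorskip("statsmodels.formula.api")
        sim, fit = balanced_fit
        m = smf.mixedlm("response ~ C(genotype, Sum)*C(isolate, Sum)",
                        sim.data, groups=sim.data["block"]).fit(reml=True)
        assert fit.sigma2_block == pytest.approx(float(m.cov_re.iloc[0, 0]),
                                                 rel=1e-3)
        assert fit.sigma2_e == pytest.approx(float(m.scale), rel=1e-4)

    def test_row_order_and_block_label_invariance(self, balanced_fit):
        sim, fit = balanced_fit
        shuffled = sim.data.sample(frac=1.0, random_state=3)
        relabeled = shuffled.assign(
            block=shuffled["block"].map(lambda b: f"zone_{b[::-1]}"))
        fit2 = fit_rcbd_lmm(relabeled, high_n_label=None)
        assert fit2.sigma2_block == pytest.approx(fit.sigma2_block, abs=1e-10)
        assert np.allclose(fit2.beta, fit.beta, atol=1e-10)

    def test_high_n_rows_excluded_by_default(self):
        sim = simulate_trial(BALANCED)
        fit = fit_rcbd_lmm(sim.data)
        assert "HNC" not in fit.isolate_levels
        fit_all = fit_rcbd_lmm(sim.data, include_high_n=True)
        assert "HNC" in fit_all.isolate_levels

    def test_empty_cell_raises(self):
        sim = simulate_trial(BALANCED)
        broken = sim.data[~((sim.data["genotype"] == "Mo17")
                            & (sim.data["isolate"] == "LNC"))]
        with pytest.raises(ValueError, match="singular|cell"):
            fit_rcbd_lmm(broken, high_n_label=None)


class TestFTable:
    def test_balanced_f_equals_fixed_block_anova(self, balanced_fit):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        sim, fit = balanced_fit
        ours = anova_f_tests(fit).set_index("effect")
        ols = smf.ols("response ~ C(block) + C(genotype, Sum)"
                      "*C(isolate, Sum)", sim.data).fit()
        ref = anova_lm(ols, typ=3)
        assert ours.loc["genotype", "F"] == pytest.approx(
            ref.loc["C(genotype, Sum)", "F"], rel=1e-6)
        assert ours.loc["isolate", "F"] == pytest.approx(
            ref.loc["C(isolate, Sum)", "F"], rel=1e-6)
        assert ours.loc["genotype:isolate", "F"] == pytest.approx(
            ref.loc["C(genotype, Sum):C(isolate, Sum)", "F"], rel=1e-6)
        assert (ours["den_df"] == ref.loc["Residual", "df"]).all()

    def test_single_genotype_degenerates_to_one_way_rcbd(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        cfg = dataclasses.replace(BALANCED, genotypes=("Mo17",),
                                  genotype_effects={}, seed=5)
        sim = simulate_trial(cfg)
        fit = fit_rcbd_lmm(sim.data, high_n_label=None)
        table = anova_f_tests(fit).set_index("effect")
        assert "genotype" not in table.index
        ols = smf.ols("response ~ C(block) + C(isolate, Sum)",
                      sim.data).fit()
        ref = anova_lm(ols, typ=3)
        assert table.loc["isolate", "F"] == pytest.approx(
            ref.loc["C(isolate, Sum)", "F"], rel=1e-6)


class TestLSMeans:
    def test_balanced_lsmeans_equal_cell_means(self, balanced_fit):
        sim, fit = balanced_fit
        lsm = ls_means(fit, "cell").set_index("level")["lsmean"]
        cells = sim.data.groupby(["genotype", "isolate"])["response"].mean()
        for (g, i), mean in cells.items():
            assert lsm[f"{g}:{i}"] == pytest.approx(mean, abs=1e-9)

    def test_unbalanced_lsmean_matches_dense_gls_oracle(self):
        sim = simulate_trial(dataclasses.replace(BALANCED, seed=9))
        data = sim.data.drop(sim.data.index[0])  # delete one observation
        fit = fit_rcbd_lmm(data, high_n_label=None)
        cell = (sim.data.iloc[0]["genotype"], sim.data.iloc[0]["isolate"])
        expect_mean, expect_se = gls_lsmean(
            fit.data, cell, fit.sigma2_block, fit.sigma2_e)
        lsm = ls_means(fit, "cell").set_index("level")
        got = lsm.loc[f"{cell[0]}:{cell[1]}"]
        assert got["lsmean"] == pytest.approx(expect_mean, abs=1e-8)
        assert got["se"] == pytest.approx(expect_se, abs=1e-8)
        raw = data[(data["genotype"] == cell[0])
                   & (data["isolate"] == cell[1])]["response"].mean()
        assert got["lsmean"] != pytest.approx(raw, abs=1e-6)

    def test_overall_lsmean_is_grand_mean_in_balance(self, balanced_fit):
        sim, fit = balanced_fit
        overall = ls_means(fit, "overall")
        assert overall["lsmean"].iloc[0] == pytest.approx(
            sim.data["response"].mean(), abs=1e-9)


class TestTukey:
    def test_equal_means_share_a_letter(self):
        cfg = TrialSimConfig(seed=2, genotypes=("G",),
                             isolates=("A", "B"), n_blocks=6,
                             sigma_block=0.0, sigma_e=0.0, mu=1.0)
        sim = simulate_trial(cfg)
        data = sim.data.copy()
        rng = np.random.default_rng(0)
        data["response"] += rng.normal(0, 0.1, size=len(data))
        data.loc[data["isolate"] == "B", "response"] = \
            data.loc[data["isolate"] == "A", "response"].to_numpy()
        fit = fit_rcbd_lmm(data, high_n_label=None)
        res = tukey_hsd(fit, "isolate")
        assert res.comparisons["p_adj"].iloc[0] > 0.99
        assert res.letters["A"] == res.letters["B"]

    def test_letters_equivalent_to_significance_matrix(self, balanced_fit):
        _, fit = balanced_fit
        res = tukey_hsd(fit, "cell")
        sig = {(r["group_a"], r["group_b"])
               for _, r in res.comparisons.iterrows() if r["significant"]}
        names = sorted(res.letters)
        for a, b in combinations(names, 2):
            shares = bool(set(res.letters[a]) & set(res.letters[b]))
            significant = (a, b) in sig or (b, a) in sig
            assert shares != significant

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_cld_equivalence_on_random_patterns(self, data):
        k = data.draw(st.integers(3, 8))
        names = [f"g{i}" for i in range(k)]
        means = {n: float(i) for i, n in enumerate(names)}
        pairs = list(combinations(names, 2))
        sig = {p for p in pairs if data.draw(st.booleans())}
        letters = compact_letter_display(names, means, sig)
        for a, b in pairs:
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares == ((a, b) not in sig)


class TestPower:
    def test_null_power_near_alpha_and_replication_helps(self):
        null = TrialSimConfig(seed=0, genotypes=("A", "B"),
                              isolates=("X", "Y", "LNC"), n_blocks=9,
                              sigma_block=0.1, sigma_e=0.2)
        effect = {("A", "X"): 0.15, ("A", "Y"): -0.075, ("A", "LNC"): -0.075,
                  ("B", "X"): -0.15, ("B", "Y"): 0.075, ("B", "LNC"): 0.075}
        strong = dataclasses.replace(null, interaction_effects=effect)
        weak_design = dataclasses.replace(strong, n_blocks=3)
        table = rcbd.power_analysis([null, strong, weak_design],
                                    n_sims=60, seed=12)
        assert table.loc[0, "power_interaction"] < 0.2
        assert table.loc[1, "power_interaction"] > \
            table.loc[2, "power_interaction"]
        assert table.loc[1, "power_interaction"] > 0.7


@pytest.fixture(scope="module")
def r_results(tmp_path_factory):
    """lme4 + emmeans results on one balanced dataset (via Rscript)."""
    sim = simulate_trial(dataclasses.replace(BALANCED, seed=21))
    tmp = tmp_path_factory.mktemp("rcheck")
    csv = tmp / "trial.csv"
    sim.data.to_csv(csv, index=False)
    script = tmp / "check.R"
    script.write_text("""
suppressMessages({library(lme4); library(emmeans)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
m <- lmer(response ~ genotype * isolate + (1 | block), data = d, REML = TRUE)
vc <- as.data.frame(VarCorr(m))
emm <- emmeans(m, ~ genotype:isolate, lmer.df = "satterthwaite")
pr <- as.data.frame(pairs(emm, adjust = "tukey"))
cat(vc$vcov[1], vc$vcov[2], "\\n")
lsm <- as.data.frame(emm)
write.csv(lsm, file.path(dirname(args[1]), "lsmeans.csv"), row.names = FALSE)
write.csv(pr, file.path(dirname(args[1]), "pairs.csv"), row.names = FALSE)
""")
    proc = subprocess.run(["Rscript", str(script), str(csv)],
                          capture_output=True, text=True, timeout=300)
    if proc.returncode != 0:
        pytest.fail(f"Rscript failed: {proc.stderr[-800:]}")
    s2b, s2e = map(float, proc.stdout.split()[:2])
    return (sim, s2b, s2e, pd.read_csv(tmp / "lsmeans.csv"),
            pd.read_csv(tmp / "pairs.csv"))


class TestAgainstR:
    """Cross-check against lme4 + emmeans on one balanced dataset."""

    def test_variance_components_match_lme4(self, r_results):
        sim, s2b, s2e, _, _ = r_results
        fit = fit_rcbd_lmm(sim.data, high_n_label=None)
        assert fit.sigma2_block == pytest.approx(s2b, rel=1e-4)
        assert fit.sigma2_e == pytest.approx(s2e, rel=1e-4)

    def test_lsmeans_and_tukey_match_emmeans(self, r_results):
        sim, _, _, r_lsm, r_pairs = r_results
        fit = fit_rcbd_lmm(sim.data, high_n_label=None)
        lsm = ls_means(fit, "cell").set_index("level")
        for _, row in r_lsm.iterrows():
            ours = lsm.loc[f"{row['genotype']}:{row['isolate']}"]
            assert ours["lsmean"] == pytest.approx(row["emmean"], abs=1e-6)
            assert ours["se"] == pytest.approx(row["SE"], rel=1e-3)
        res = tukey_hsd(fit, "cell")
        ours_p = {}
        for _, r in res.comparisons.iterrows():
            key = frozenset((r["group_a"].replace(":", " "),
                             r["group_b"].replace(":", " ")))
            ours_p[key] = r["p_adj"]
        checked = 0
        for _, row in r_pairs.iterrows():
            a, b = row["contrast"].split(" - ")
            key = frozenset((a.strip("()"), b.strip("()")))
            if key in ours_p:
                assert ours_p[key] == pytest.approx(row["p.value"],
                                                    abs=2e-3)
                checked += 1
        assert checked >= 50
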