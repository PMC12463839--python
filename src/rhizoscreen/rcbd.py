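"""RCBD linear mixed model: REML fit, Type III F tests, LS-means, Tukey HSD.

The model for a randomized-complete-block genotype x isolate trial is

    y = mu + genotype + isolate + genotype:isolate + block + e,

with genotype, isolate and their interaction fixed (sum-to-zero coding)
and block random, ``block ~ N(0, sigma_b^2)``, ``e ~ N(0, sigma_e^2)``.
Because blocks partition the rows, the marginal covariance
``V = sigma_e^2 (I + lambda Z Z')`` with ``lambda = sigma_b^2/sigma_e^2``
inverts in closed form (Woodbury with diagonal ``Z'Z``), so REML reduces
to one-dimensional profiling of ``lambda``: a log-spaced grid bracket
followed by bounded scalar minimization.  Fixed effects are generalized
least squares at the REML estimate; Type III (marginal) F statistics use
the containment (between-within) denominator degrees of freedom
``n - rank(X) - (n_blocks - 1)``, which is exact for balanced designs.
Post-hoc inference is Tukey-Kramer on LS-means via the studentized-range
distribution, with a compact letter display assembled by insert-and-absorb.

High-nitrogen control rows (a benchmark condition, not a treatment
crossed with the low-N factor levels) are excluded from the factorial
fit by default and can be included with a flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rhizoscreen.simdata.trials import TrialSimConfig, simulate_trial

REQUIRED_COLUMNS = ("plant_id", "genotype", "isolate", "block", "response")
HIGH_N_LABEL = "HNC"

_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-8, 6, 57)])


def _sum_code(levels: Sequence[str], value: str) -> np.ndarray:
    """Sum-to-zero contrast row for one factor level (k-1 columns)."""
    k = len(levels)
    row = np.zeros(k - 1)
    if value == levels[-1]:
        row[:] = -1.0
    else:
        row[levels.index(value)] = 1.0
    return row


@dataclass
class ModelFit:
    """Fitted RCBD mixed model (see module docstring for the model)."""

    data: pd.DataFrame
    genotype_levels: list[str]
    isolate_levels: list[str]
    block_levels: list[str]
    terms: dict[str, slice]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_block: float
    sigma2_e: float
    var_ratio: float
    ddf: int
    n_obs: int
    converged: bool
    reml_criterion: float

    @property
    def fitted_values(self) -> np.ndarray:
        """Conditional fitted values: fixed part + BLUP of block effects."""
        X, Z, y = _matrices(self.data, self.genotype_levels,
                            self.isolate_levels, self.block_levels,
                            self.terms)
        r = y - X @ self.beta
        nj = Z.sum(axis=0)
        blup = self.var_ratio * (Z.T @ r) / (1.0 + self.var_ratio * nj)
        return X @ self.beta + Z @ blup

    def cell_row(self, genotype: str, isolate: str) -> np.ndarray:
        """Fixed-design row for one genotype x isolate cell."""
        p = self.beta.shape[0]
        row = np.zeros(p)
        row[0] = 1.0
        if "genotype" in self.terms:
            row[self.terms["genotype"]] = _sum_code(self.genotype_levels,
                                                    genotype)
        if "isolate" in self.terms:
            row[self.terms["isolate"]] = _sum_code(self.isolate_levels,
                                                   isolate)
        if "genotype:isolate" in self.terms:
            g = _sum_code(self.genotype_levels, genotype)
            i = _sum_code(self.isolate_levels, isolate)
            row[self.terms["genotype:isolate"]] = np.outer(g, i).ravel()
        return row


def _matrices(data: pd.DataFrame, g_levels: list[str], i_levels: list[str],
              b_levels: list[str], terms: dict[str, slice]):
    n = len(data)
    p = 1 + sum(s.stop - s.start for s in terms.values())
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    g_codes = {g: _sum_code(g_levels, g) for g in g_levels} \
        if len(g_levels) > 1 else {}
    i_codes = {i: _sum_code(i_levels, i) for i in i_levels} \
        if len(i_levels) > 1 else {}
    for r, (g, iso) in enumerate(zip(data["genotype"], data["isolate"])):
        if "genotype" in terms:
            X[r, terms["genotype"]] = g_codes[g]
        if "isolate" in terms:
            X[r, terms["isolate"]] = i_codes[iso]
        if "genotype:isolate" in terms:
            X[r, terms["genotype:isolate"]] = np.outer(g_codes[g],
                                                       i_codes[iso]).ravel()
    Z = np.zeros((n, len(b_levels)))
    b_index = {b: k for k, b in enumerate(b_levels)}
    for r, b in enumerate(data["block"]):
        Z[r, b_index[b]] = 1.0
    y = data["response"].to_numpy(float)
    return X, Z, y


def _term_layout(g_levels: list[str], i_levels: list[str]) -> dict[str, slice]:
    terms: dict[str, slice] = {}
    start = 1
    if len(g_levels) > 1:
        terms["genotype"] = slice(start, start + len(g_levels) - 1)
        start = terms["genotype"].stop
    if len(i_levels) > 1:
        terms["isolate"] = slice(start, start + len(i_levels) - 1)
        start = terms["isolate"].stop
    if len(g_levels) > 1 and len(i_levels) > 1:
        width = (len(g_levels) - 1) * (len(i_levels) - 1)
        terms["genotype:isolate"] = slice(start, start + width)
    return terms


def fit_rcbd_lmm(data: pd.DataFrame, *,
                 high_n_label: str | None = HIGH_N_LABEL,
                 include_high_n: bool = False,
                 var_ratio: float | None = None) -> ModelFit:
    """Fit the RCBD mixed model by REML.

    ``high_n_label`` rows are dropped unless ``include_high_n`` is set
    (pass ``high_n_label=None`` to disable the convention).  Passing
    ``var_ratio`` skips estimation and fits at that fixed
    ``sigma_b^2/sigma_e^2`` — useful for reduction-to-ANOVA checks.
    """
    missing = set(REQUIRED_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"trial data lacks columns {sorted(missing)}")
    if data[list(REQUIRED_COLUMNS)].isna().any().any():
        raise ValueError("trial data contains missing values")
    df = data
    if high_n_label is not None and not include_high_n:
        df = df[df["isolate"] != high_n_label]
    df = df.sort_values(["block", "genotype", "isolate", "plant_id"],
                        kind="mergesort").reset_index(drop=True)

    g_levels = sorted(df["genotype"].unique())
    i_levels = sorted(df["isolate"].unique())
    b_levels = sorted(df["block"].unique())
    if len(b_levels) < 2:
        raise ValueError("need at least 2 blocks")
    cells = df.groupby(["genotype", "isolate"]).size()
    if len(cells) < len(g_levels) * len(i_levels):
        raise ValueError("empty genotype x isolate cell: interaction "
                         "inestimable (singular design)")

    terms = _term_layout(g_levels, i_levels)
    X, Z, y = _matrices(df, g_levels, i_levels, b_levels, terms)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    q = Z.shape[1]
    ddf = n - p - (q - 1)
    if ddf <= 0:
        raise ValueError("no residual degrees of freedom")

    XtX = X.T @ X
    XtZ = X.T @ Z
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = float(y @ y)
    nj = Z.sum(axis=0)

    def profile(lam: float):
        w = lam / (1.0 + lam * nj)
        A = XtX - (XtZ * w) @ XtZ.T
        c = Xty - (XtZ * w) @ Zty
        yVy = yty - float(w @ (Zty ** 2))
        beta = np.linalg.solve(A, c)
        rss = max(yVy - float(beta @ c), 1e-300)
        sign, logdet_a = np.linalg.slogdet(A)
        crit = float(np.log1p(lam * nj).sum() + logdet_a
                     + (n - p) * np.log(rss))
        return crit, beta, A, rss

    converged = True
    if var_ratio is not None:
        lam_hat = float(var_ratio)
        if lam_hat < 0:
            raise ValueError("var_ratio must be >= 0")
    else:
        crits = np.array([profile(l)[0] for l in _LAMBDA_GRID])
        k = int(np.argmin(crits))
        lo = _LAMBDA_GRID[max(k - 1, 0)]
        hi = _LAMBDA_GRID[min(k + 1, len(_LAMBDA_GRID) - 1)]
        if lo == hi:
            lam_hat = lo
        else:
            res = optimize.minimize_scalar(
                lambda l: profile(l)[0], bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-9})
            lam_hat = float(res.x)
            converged = bool(res.success)
            if profile(0.0)[0] <= res.fun:  # boundary wins
                lam_hat = 0.0

    crit, beta, A, rss = profile(lam_hat)
    sigma2_e = rss / (n - p)
    cov_beta = sigma2_e * np.linalg.inv(A)
    return ModelFit(
        data=df, genotype_levels=g_levels, isolate_levels=i_levels,
        block_levels=b_levels, terms=terms, beta=beta, cov_beta=cov_beta,
        sigma2_block=lam_hat * sigma2_e, sigma2_e=sigma2_e,
        var_ratio=lam_hat, ddf=ddf, n_obs=n, converged=converged,
        reml_criterion=crit)


def anova_f_tests(fit: ModelFit) -> pd.DataFrame:
    """Type III F table (one row per fixed term) with containment df."""
    if not fit.converged:
        raise ValueError("model fit did not converge")
    rows = []
    for term, sl in fit.terms.items():
        b = fit.beta[sl]
        C = fit.cov_beta[sl, sl]
        num_df = sl.stop - sl.start
        F = float(b @ np.linalg.solve(C, b)) / num_df
        rows.append({
            "effect": term, "F": F, "num_df": num_df, "den_df": fit.ddf,
            "p": float(stats.f.sf(F, num_df, fit.ddf)),
        })
    return pd.DataFrame(rows, columns=["effect", "F", "num_df", "den_df",
                                       "p"])


Margin = Literal["cell", "genotype", "isolate", "overall"]


def ls_means(fit: ModelFit, margin: Margin = "cell") -> pd.DataFrame:
    """Model-adjusted means over an equally weighted factor grid.

    For the ``cell`` margin this is the fixed-effect prediction of every
    genotype x isolate cell; factor margins average the cell grid along
    the other factor.  Standard errors come from the GLS covariance of
    the fixed effects; df is the containment denominator df.
    """
    grid = [(g, i) for g in fit.genotype_levels for i in fit.isolate_levels]
    rows_x = {gi: fit.cell_row(*gi) for gi in grid}

    def emit(label: str, x: np.ndarray) -> dict:
        return {"level": label, "lsmean": float(x @ fit.beta),
                "se": float(np.sqrt(x @ fit.cov_beta @ x)), "df": fit.ddf}

    if margin == "cell":
        out = [emit(f"{g}:{i}", rows_x[(g, i)]) for g, i in grid]
    elif margin == "genotype":
        out = [emit(g, np.mean([rows_x[(g, i)] for i in fit.isolate_levels],
                               axis=0)) for g in fit.genotype_levels]
    elif margin == "isolate":
        out = [emit(i, np.mean([rows_x[(g, i)] for g in fit.genotype_levels],
                               axis=0)) for i in fit.isolate_levels]
    elif margin == "overall":
        out = [emit("overall", np.mean(list(rows_x.values()), axis=0))]
    else:
        raise ValueError(f"unknown margin {margin!r}")
    return pd.DataFrame(out, columns=["level", "lsmean", "se", "df"])


def _margin_rows(fit: ModelFit, margin: Margin) -> dict[str, np.ndarray]:
    table = {}
    if margin == "cell":
        for g in fit.genotype_levels:
            for i in fit.isolate_levels:
                table[f"{g}:{i}"] = fit.cell_row(g, i)
    elif margin == "genotype":
        for g in fit.genotype_levels:
            table[g] = np.mean([fit.cell_row(g, i)
                                for i in fit.isolate_levels], axis=0)
    elif margin == "isolate":
        for i in fit.isolate_levels:
            table[i] = np.mean([fit.cell_row(g, i)
                                for g in fit.genotype_levels], axis=0)
    else:
        raise ValueError(f"margin {margin!r} has no comparison family")
    return table


@dataclass
class TukeyResult:
    """All-pairs Tukey-Kramer comparisons plus compact letter display."""

    comparisons: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    n_groups: int
    df: int


def tukey_hsd(fit: ModelFit, margin: Margin = "cell",
              alpha: float = 0.05) -> TukeyResult:
    """Tukey-Kramer adjusted pairwise comparisons of LS-means.

    The studentized-range statistic for a pair is
    ``q = |diff| / (se_diff / sqrt(2))`` with the fit's containment df;
    unequal cell sizes enter through the GLS standard errors
    (Kramer's extension).  Letters come from insert-and-absorb with
    groups ordered by descending mean.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows_x = _margin_rows(fit, margin)
    if len(rows_x) < 2:
        raise ValueError("comparison family needs at least 2 groups")
    names = list(rows_x)
    means = {m: float(rows_x[m] @ fit.beta) for m in names}
    k = len(names)
    recs = []
    for a, b in combinations(names, 2):
        xd = rows_x[a] - rows_x[b]
        diff = float(xd @ fit.beta)
        se = float(np.sqrt(xd @ fit.cov_beta @ xd))
        q = abs(diff) / (se / np.sqrt(2.0))
        p_adj = float(np.clip(stats.studentized_range.sf(q, k, fit.ddf),
                              0.0, 1.0))
        recs.append({"group_a": a, "group_b": b, "difference": diff,
                     "se": se, "q": q, "p_adj": p_adj,
                     "significant": p_adj < alpha})
    comparisons = pd.DataFrame(recs)
    sig = {(r["group_a"], r["group_b"]) for _, r in comparisons.iterrows()
           if r["significant"]}
    letters = compact_letter_display(names, means, sig)
    return TukeyResult(comparisons=comparisons, letters=letters,
                       alpha=alpha, n_groups=k, df=fit.ddf)


def tukey_max_q(fit: ModelFit, margin: Margin = "cell",
                ) -> tuple[float, int, int]:
    """Maximum pairwise studentized-range statistic ``(max_q, k, df)``.

    ``max_q > studentized_range.ppf(1 - alpha, k, df)`` is exactly the
    event that the smallest Tukey-adjusted p-value is below ``alpha``
    (the survival function is monotone), which makes familywise-error
    simulations cheap.
    """
    rows_x = _margin_rows(fit, margin)
    names = list(rows_x)
    max_q = 0.0
    for a, b in combinations(names, 2):
        xd = rows_x[a] - rows_x[b]
        diff = float(xd @ fit.beta)
        se = float(np.sqrt(xd @ fit.cov_beta @ xd))
        max_q = max(max_q, abs(diff) / (se / np.sqrt(2.0)))
    return max_q, len(names), fit.ddf


def compact_letter_display(names: Sequence[str], means: dict[str, float],
                           significant: set[tuple[str, str]],
                           ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one group containing every level; each significant pair
    splits every group containing both; groups contained in another are
    absorbed.  Letters are assigned to groups ordered by the descending
    best mean of their members, so the display is deterministic.  Two
    levels share a letter iff they are not significantly different.
    """
    groups: list[set[str]] = [set(names)]
    order = sorted(significant)
    for a, b in order:
        new_groups: list[set[str]] = []
        for grp in groups:
            if a in grp and b in grp:
                new_groups.append(grp - {a})
                new_groups.append(grp - {b})
            else:
                new_groups.append(grp)
        groups = [g for g in new_groups if g]
        groups = [g for g in groups
                  if not any(g < h for h in groups)]
        # drop duplicates
        uniq: list[set[str]] = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    groups.sort(key=lambda g: (-max(means[m] for m in g),
                               sorted(g)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {m: [] for m in names}
    for idx, grp in enumerate(groups):
        letter = alphabet[idx % 26] * (idx // 26 + 1)
        for m in grp:
            assigned[m].append(letter)
    return {m: "".join(sorted(set(ls))) for m, ls in assigned.items()}


def trial_report(fit: ModelFit, alpha: float = 0.05) -> str:
    """Plain-text report: Effect / F-value / P-value table, LS-means and
    Tukey letters for the cell margin."""
    ftab = anova_f_tests(fit)
    lsm = ls_means(fit, "cell")
    tk = tukey_hsd(fit, "cell", alpha=alpha)
    lines = ["Effect\tF-value\tP-value"]
    for _, r in ftab.iterrows():
        lines.append(f"{r['effect']}\t{r['F']:.2f}\t{r['p']:.4f}")
    lines.append("")
    lines.append("Cell\tLS-mean (g)\tSE\tLetters")
    for _, r in lsm.iterrows():
        lines.append(f"{r['level']}\t{r['lsmean']:.4f}\t{r['se']:.4f}"
                     f"\t{tk.letters[r['level']]}")
    return "\n".join(lines)


def power_analysis(configs: Sequence[TrialSimConfig] | TrialSimConfig,
                   n_sims: int = 200, alpha: float = 0.05, seed: int = 0,
                   control: str = "LNC") -> pd.DataFrame:
    """Monte-Carlo power of the interaction F-test and of unadjusted
    isolate-vs-control LS-mean contrasts, per simulation configuration.

    Every simulated trial is refit from scratch; rejection rates are the
    fraction of ``n_sims`` replicates with p < ``alpha``.  The contrast
    power averages over all non-control isolate levels.
    """
    if isinstance(configs, TrialSimConfig):
        configs = [configs]
    rng = np.random.default_rng(seed)
    out = []
    for cfg in configs:
        n_int = 0
        n_contrast = 0
        n_contrast_tests = 0
        for _ in range(n_sims):
            # condition on estimable designs: redraw trials whose dropout
            # emptied a treatment cell
            for _attempt in range(100):
                sim_seed = int(rng.integers(0, 2 ** 31 - 1))
                try:
                    sim = simulate_trial(dataclasses.replace(cfg,
                                                             seed=sim_seed))
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not draw an estimable trial")
            fit = fit_rcbd_lmm(sim.data, high_n_label=None)
            ftab = anova_f_tests(fit).set_index("effect")
            if "genotype:isolate" in ftab.index and \
                    ftab.loc["genotype:isolate", "p"] < alpha:
                n_int += 1
            if control in fit.isolate_levels:
                rows_x = _margin_rows(fit, "isolate")
                for iso in fit.isolate_levels:
                    if iso == control:
                        continue
                    xd = rows_x[iso] - rows_x[control]
                    t = float(xd @ fit.beta) / float(
                        np.sqrt(xd @ fit.cov_beta @ xd))
                    n_contrast_tests += 1
                    if 2 * stats.t.sf(abs(t), fit.ddf) < alpha:
                        n_contrast += 1
        out.append({
            "n_blocks": cfg.n_blocks, "sigma_block": cfg.sigma_block,
            "sigma_e": cfg.sigma_e, "n_sims": n_sims,
            "power_interaction": n_int / n_sims,
            "power_isolate_vs_control":
                n_contrast / n_contrast_tests if n_contrast_tests else np.nan,
        })
    return pd.DataFrame(out)
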