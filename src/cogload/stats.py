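"""Statistical layer: nonparametric and parametric repeated-measures tests.

The pipeline mirrors a conventional within-subject analysis plan at
alpha = 0.05:

* assumption gates -- Shapiro-Wilk normality per condition, Levene variance
  homogeneity, Mauchly sphericity;
* if normality fails, a Friedman omnibus across the four task conditions
  with Kendall's W effect size and Wilcoxon signed-rank post hoc pairs under
  Bonferroni adjustment (descriptives: median and IQR);
* otherwise a repeated-measures ANOVA (Greenhouse-Geisser corrected when
  Mauchly rejects) with partial eta squared (descriptives: mean +/- SD);
* a mixed design (low/high vagal-tone group x task) handled by a
  two-factor split-plot ANOVA.

Omnibus and post hoc machinery delegates to scipy and pingouin; the
surrounding selection logic, effect sizes and reporting are this module's.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "StatResult",
    "friedman",
    "posthoc_pairwise",
    "mixed_rm_anova",
    "rm_anova",
    "assumption_gates",
    "omnibus_across_tasks",
]

ALPHA = 0.05


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple | float
    p_value: float
    effect_size: float
    effect_size_name: str = ""
    posthoc: list = field(default_factory=list)
    table: list = field(default_factory=list)  # full ANOVA rows when applicable
    descriptives: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "posthoc": self.posthoc,
            "table": self.table,
            "descriptives": self.descriptives,
        }


def _as_matrix(table) -> tuple[np.ndarray, list]:
    if isinstance(table, pd.DataFrame):
        mat = table.to_numpy(dtype=float)
        cols = list(table.columns)
    else:
        mat = np.asarray(table, dtype=float)
        cols = list(range(mat.shape[1]))
    return mat, cols


def friedman(table) -> StatResult:
    """Friedman rank test across k >= 3 dependent conditions.

    Rows are participants, columns conditions; the statistic uses
    within-row mid-ranks with tie correction and is referred to the
    chi-square distribution with k-1 df.  Effect size is Kendall's W.
    """
    mat, _cols = _as_matrix(table)
    if np.isnan(mat).any():
        raise ValueError("incomplete data: missing cells")
    n, k = mat.shape
    if n < 2 or k < 3:
        raise ValueError("need >= 2 participants and >= 3 conditions")
    if np.all(mat == mat[:, [0]]):
        # every row fully tied: no effect by definition (the tie-corrected
        # statistic is 0/0 here)
        return StatResult(test="friedman", statistic=0.0, df=float(k - 1),
                          p_value=1.0, effect_size=0.0,
                          effect_size_name="kendall_w")
    stat, p = sps.friedmanchisquare(*(mat[:, j] for j in range(k)))
    kendall_w = float(stat) / (n * (k - 1))
    return StatResult(
        test="friedman",
        statistic=float(stat),
        df=float(k - 1),
        p_value=float(p),
        effect_size=kendall_w,
        effect_size_name="kendall_w",
    )


def posthoc_pairwise(table, alpha: float = ALPHA) -> list[dict]:
    """All-pairs Wilcoxon signed-rank tests with Bonferroni adjustment.

    Adjusted p = min(1, raw p * number of pairs).  A pair whose paired
    differences are all zero is flagged degenerate and never significant.
    """
    mat, cols = _as_matrix(table)
    pairs = list(itertools.combinations(range(mat.shape[1]), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        d = mat[:, i] - mat[:, j]
        entry = {"pair": (str(cols[i]), str(cols[j]))}
        if np.all(d == 0):
            entry.update(p_raw=np.nan, p_adjusted=np.nan,
                         significant=False, degenerate=True)
        else:
            _w, p = sps.wilcoxon(mat[:, i], mat[:, j])
            p_adj = min(1.0, float(p) * m)
            entry.update(p_raw=float(p), p_adjusted=p_adj,
                         significant=p_adj < alpha, degenerate=False)
        out.append(entry)
    return out


def assumption_gates(table, groups=None) -> dict:
    """Shapiro-Wilk, Levene and Mauchly p-values for a within-subject table.

    ``normality_p`` is the smallest Shapiro-Wilk p across conditions (the
    gate rejects when any condition departs from normality).  Levene is run
    across groups when ``groups`` is given, else across conditions.
    """
    mat, cols = _as_matrix(table)
    n, k = mat.shape
    if n < 3:
        raise ValueError("need at least 3 observations per condition")

    normality_p = min(float(sps.shapiro(mat[:, j]).pvalue) for j in range(k))

    if groups is not None:
        groups = np.asarray(groups)
        samples = [mat[groups == g].ravel() for g in np.unique(groups)]
    else:
        samples = [mat[:, j] for j in range(k)]
    levene_p = float(sps.levene(*samples).pvalue)

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile([str(c) for c in cols], n),
            "y": mat.ravel(),
        }
    )
    spher = pg.sphericity(long, dv="y", within="cond", subject="subject")
    return {
        "normality_p": normality_p,
        "variance_homogeneity_p": levene_p,
        "sphericity_p": float(spher.pval),
    }


def rm_anova(table, alpha: float = ALPHA) -> StatResult:
    """One-way repeated-measures ANOVA across conditions, GG-corrected when
    Mauchly rejects sphericity."""
    mat, cols = _as_matrix(table)
    n, k = mat.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile([str(c) for c in cols], n),
            "y": mat.ravel(),
        }
    )
    aov = pg.rm_anova(long, dv="y", within="cond", subject="subject",
                      correction=True, detailed=True)
    row = aov.loc[aov["Source"] == "cond"].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    spher_p = float(row.get("p_spher", np.nan))
    use_gg = np.isfinite(spher_p) and spher_p < alpha
    p = float(row["p_GG_corr"]) if use_gg else float(row["p_unc"])
    partial_eta = float(row["SS"]) / (float(row["SS"]) + float(err["SS"]))
    return StatResult(
        test="rm_anova" + ("_gg" if use_gg else ""),
        statistic=float(row["F"]),
        df=(float(row["DF"]), float(err["DF"])),
        p_value=p,
        effect_size=partial_eta,
        effect_size_name="partial_eta_sq",
    )


def mixed_rm_anova(data: pd.DataFrame, dv: str = "value", within: str = "task",
                   between: str = "group", subject: str = "participant",
                   alpha: float = ALPHA) -> StatResult:
    """Split-plot ANOVA: one between factor (group) x one within factor (task).

    Returns the within-factor row as the headline result (Greenhouse-Geisser
    corrected when Mauchly rejects); the full decomposition -- group, task
    and interaction F, p and partial eta squared -- is in ``table``.
    """
    if data[[dv, within, between, subject]].isna().any().any():
        raise ValueError("incomplete data: missing cells")
    aov = pg.mixed_anova(data, dv=dv, within=within, subject=subject,
                         between=between, correction=True)
    task_row = aov.loc[aov["Source"] == within].iloc[0]
    spher_p = float(task_row.get("p_spher", np.nan))
    use_gg = np.isfinite(spher_p) and spher_p < alpha
    eps = float(task_row.get("eps", 1.0)) if use_gg else 1.0

    rows = []
    for _, r in aov.iterrows():
        p = float(r["p_unc"])
        df1, df2 = float(r["DF1"]), float(r["DF2"])
        if use_gg and r["Source"] in (within, "Interaction"):
            # GG: shrink both dfs by epsilon, F unchanged
            p = float(sps.f.sf(r["F"], eps * df1, eps * df2))
        rows.append(
            {
                "source": str(r["Source"]),
                "F": float(r["F"]),
                "df": (df1, df2),
                "p": p,
                "partial_eta_sq": float(r["np2"]),
            }
        )
    headline = next(r for r in rows if r["source"] == within)
    return StatResult(
        test="mixed_rm_anova" + ("_gg" if use_gg else ""),
        statistic=headline["F"],
        df=headline["df"],
        p_value=headline["p"],
        effect_size=headline["partial_eta_sq"],
        effect_size_name="partial_eta_sq",
        table=rows,
    )


def omnibus_across_tasks(wide: pd.DataFrame, alpha: float = ALPHA) -> StatResult:
    """Gate-then-test for one metric across the four task conditions.

    ``wide`` is participants x conditions.  Normality failing in any
    condition (Shapiro p < alpha) routes to Friedman with median (IQR)
    descriptives; otherwise repeated-measures ANOVA with mean +/- SD.
    Post hoc Wilcoxon pairs (Bonferroni) are attached either way.
    """
    gates = assumption_gates(wide)
    if gates["normality_p"] < alpha:
        result = friedman(wide)
        desc = {
            str(c): {"median": float(wide[c].median()),
                     "iqr": float(wide[c].quantile(0.75) - wide[c].quantile(0.25))}
            for c in wide.columns
        }
    else:
        result = rm_anova(wide, alpha=alpha)
        desc = {
            str(c): {"mean": float(wide[c].mean()), "sd": float(wide[c].std())}
            for c in wide.columns
        }
    result.posthoc = posthoc_pairwise(wide, alpha=alpha)
    result.descriptives = {"per_condition": desc, "gates": gates}
    return result
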