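"""Crossover treatment-effect statistics.

The analysis surface of a two-period crossover with pre/post measurements
per block: per-subject change scores, within-block paired t-tests ("effect
of time"), a baseline-adjusted treatment comparison (ANCOVA: post-test
regressed on treatment with the pre-test as covariate), and a one-way ANOVA
on change scores between treatments.  Missing data are handled complete-case
per outcome, so n can differ between outcomes and arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "EffectEstimate",
    "TABLE_COLUMNS",
    "validate_crossover_table",
    "change_scores",
    "summarize_changes",
    "paired_time_test",
    "ancova_treatment",
    "change_anova",
]

TREATMENTS = ("INCO", "AIR")

#: Canonical tidy layout: one row per participant x treatment x outcome.
TABLE_COLUMNS = ("participant", "treatment", "period", "outcome", "pre", "post")


@dataclass(frozen=True)
class EffectEstimate:
    outcome: str
    effect: float  # treatment effect (INCO - AIR), units of the outcome
    se: float
    p_treatment: float
    p_time_inco: float
    p_time_air: float
    n_inco: int
    n_air: int


def validate_crossover_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy crossover layout and key uniqueness."""
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"crossover table missing columns: {sorted(missing)}")
    bad = set(table["treatment"].unique()) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment labels: {sorted(bad)}")
    dup = table.duplicated(subset=["participant", "treatment", "outcome"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (participant, treatment, outcome) rows"
        )
    return table


def change_scores(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-subject absolute and percent change for one outcome.

    Returns rows (participant, treatment, pre, post, change, pct_change),
    complete cases only.  Percent change is 100 x (post - pre)/pre and
    requires pre != 0.
    """
    validate_crossover_table(table)
    sub = table[table["outcome"] == outcome].dropna(subset=["pre", "post"]).copy()
    if (sub["pre"] == 0).any():
        raise ValueError("percent change undefined at pre = 0")
    sub["change"] = sub["post"] - sub["pre"]
    sub["pct_change"] = 100.0 * sub["change"] / sub["pre"]
    return sub[["participant", "treatment", "pre", "post", "change", "pct_change"]]


def summarize_changes(changes: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD of change and percent change per treatment."""
    g = changes.groupby("treatment")
    out = g.agg(
        n=("change", "size"),
        mean_change=("change", "mean"),
        sd_change=("change", lambda x: x.std(ddof=1)),
        mean_pct=("pct_change", "mean"),
        sd_pct=("pct_change", lambda x: x.std(ddof=1)),
    )
    return out


def paired_time_test(changes: np.ndarray | pd.Series) -> tuple[float, float]:
    """Two-sided paired t-test on (post - pre) differences.

    Returns (t, p).  Zero-variance differences are degenerate: all-zero
    changes give (0, 1); identical nonzero changes give (inf, 0) with the
    sign of the common change — flagged rather than crashing.
    """
    d = np.asarray(changes, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if np.std(d, ddof=1) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def _outcome_frame(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    sub = table[table["outcome"] == outcome].dropna(subset=["pre", "post"]).copy()
    sub["treat"] = pd.Categorical(sub["treatment"], categories=["AIR", "INCO"])
    return sub


def ancova_treatment(
    table: pd.DataFrame,
    outcome: str,
    period_term: bool = False,
    subject_diff: bool = False,
    baseline_covariate: bool = True,
) -> EffectEstimate:
    """Baseline-adjusted treatment effect for one outcome.

    Fits post ~ intercept + beta * pre + tau * treatment by OLS and reports
    tau (INCO - AIR) with its SE and p-value.  ``period_term`` adds a
    period factor; ``subject_diff`` instead exploits the crossover pairing
    by differencing each subject's two periods (eliminating subject-level
    intercepts) and testing the within-subject INCO - AIR contrast of the
    baseline-adjusted residuals.  ``baseline_covariate=False`` drops the
    pre-test covariate (forcing a zero baseline slope).  Within-block
    paired t-tests ("effect of time") are reported per arm alongside.
    """
    validate_crossover_table(table)
    sub = _outcome_frame(table, outcome)
    present = set(sub["treatment"].unique())
    if present != set(TREATMENTS):
        raise ValueError(f"both treatments required; found {sorted(present)}")
    if np.std(sub["pre"].to_numpy(), ddof=0) == 0:
        raise ValueError("baseline has zero variance; ANCOVA covariate collinear")

    def time_p(arm: str) -> float:
        d = sub.loc[sub["treatment"] == arm, "post"] - sub.loc[sub["treatment"] == arm, "pre"]
        if d.size < 2:
            return math.nan
        return paired_time_test(d.to_numpy())[1]

    n_inco = int((sub["treatment"] == "INCO").sum())
    n_air = int((sub["treatment"] == "AIR").sum())

    if subject_diff:
        wide = sub.pivot(index="participant", columns="treatment",
                         values=["pre", "post"]).dropna()
        if len(wide) < 2:
            raise ValueError("need >= 2 complete crossover participants")
        d_post = wide[("post", "INCO")] - wide[("post", "AIR")]
        d_pre = wide[("pre", "INCO")] - wide[("pre", "AIR")]
        df = pd.DataFrame({"d_post": d_post, "d_pre": d_pre})
        fit = smf.ols("d_post ~ d_pre", data=df).fit()
        tau = float(fit.params["Intercept"])
        se = float(fit.bse["Intercept"])
        p = float(fit.pvalues["Intercept"])
    else:
        formula = "post ~ pre + treat" if baseline_covariate else "post ~ treat"
        if period_term:
            formula += " + C(period)"
        fit = smf.ols(formula, data=sub).fit()
        tau = float(fit.params["treat[T.INCO]"])
        se = float(fit.bse["treat[T.INCO]"])
        p = float(fit.pvalues["treat[T.INCO]"])

    return EffectEstimate(
        outcome=outcome,
        effect=tau,
        se=se,
        p_treatment=p,
        p_time_inco=time_p("INCO"),
        p_time_air=time_p("AIR"),
        n_inco=n_inco,
        n_air=n_air,
    )


def change_anova(table: pd.DataFrame, outcome: str) -> tuple[float, float]:
    """One-way ANOVA on change scores by treatment; returns (F, p).

    With two groups this equals the squared two-sample t-test.  Identical
    arms give F = 0, p = 1.
    """
    ch = change_scores(table, outcome)
    groups = [
        ch.loc[ch["treatment"] == t, "change"].to_numpy() for t in TREATMENTS
    ]
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 change scores in each arm")
    if all(np.var(g) == 0 for g in groups) and groups[0].mean() == groups[1].mean():
        return 0.0, 1.0
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
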