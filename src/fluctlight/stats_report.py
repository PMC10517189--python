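"""Factorial ANOVA tables and mean +/- SEM summaries.

Each phylogenetic pair is analysed as an independent experiment. Steady
state parameters get a two-way ANOVA (photosynthetic pathway x O2); the
fluctuating-light metrics get a three-way ANOVA (pathway x fluctuation
length x O2) in which fluctuation length enters as a 1-df continuous
covariate, so a balanced 2 x 3 x 2 design with n = 5 leaves 52 residual
degrees of freedom. Sums of squares are Type II (identical to Type I on
the balanced designs used here; a warning is emitted, and Type II kept,
when a design is unbalanced).

Report formatting mirrors the published convention: each effect is a
"df_num.df_den; F; P" triplet with two-decimal F, and P floored at
"<= 0.001".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

PATHWAY_EFFECT = "PP"
O2_EFFECT = "[O2]"
LENGTH_EFFECT = "fl"


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    df_num: int
    df_den: int
    f_value: float
    p_value: float

    def __post_init__(self) -> None:
        if self.df_num < 1 or self.df_den < 1:
            raise ValueError("degrees of freedom must be >= 1")


def _check_balance(df: pd.DataFrame, factors: list[str], min_n: int = 2) -> None:
    counts = df.groupby(factors, observed=True).size()
    if counts.min() < min_n:
        raise ValueError(f"need n >= {min_n} per cell, found {counts.min()}")
    if counts.nunique() > 1:
        warnings.warn("unbalanced design; Type-II sums of squares reported "
                      "anyway", stacklevel=3)


def _anova_rows(model, rename: dict[str, str]) -> list[AnovaRow]:
    table = sm.stats.anova_lm(model, typ=2)
    df_den = int(table.loc["Residual", "df"])
    rows = []
    for term, pretty in rename.items():
        rows.append(AnovaRow(
            effect=pretty,
            df_num=int(table.loc[term, "df"]),
            df_den=df_den,
            f_value=float(table.loc[term, "F"]),
            p_value=float(table.loc[term, "PR(>F)"]),
        ))
    return rows


def two_way_anova(df: pd.DataFrame, value: str = "value",
                  pathway: str = "pathway", o2: str = "o2") -> list[AnovaRow]:
    """Pathway x O2 ANOVA of one per-replicate parameter.

    ``df`` holds one row per replicate with the response and the two
    factor columns. Returns rows for PP, [O2] and PP:[O2].
    """
    _check_balance(df, [pathway, o2])
    data = df.rename(columns={value: "y"})
    model = smf.ols(f"y ~ C({pathway}) * C({o2})", data=data).fit()
    return _anova_rows(model, {
        f"C({pathway})": PATHWAY_EFFECT,
        f"C({o2})": O2_EFFECT,
        f"C({pathway}):C({o2})": f"{PATHWAY_EFFECT}:{O2_EFFECT}",
    })


def three_way_anova(df: pd.DataFrame, value: str = "value",
                    pathway: str = "pathway", duration: str = "duration",
                    o2: str = "o2",
                    duration_as: str = "continuous") -> list[AnovaRow]:
    """Pathway x fluctuation-length x O2 ANOVA of a fluctuating-light metric.

    With ``duration_as="continuous"`` (default) the step duration is a
    1-df covariate; ``"categorical"`` treats it as a factor instead.
    """
    if duration_as not in ("continuous", "categorical"):
        raise ValueError("duration_as must be 'continuous' or 'categorical'")
    _check_balance(df, [pathway, duration, o2])
    data = df.rename(columns={value: "y"})
    if duration_as == "continuous":
        data["_fl"] = data[duration].astype(float)
        fl_term = "_fl"
    else:
        fl_term = f"C({duration})"
    model = smf.ols(f"y ~ C({pathway}) * {fl_term} * C({o2})", data=data).fit()
    pp, fl, o2t = f"C({pathway})", fl_term, f"C({o2})"
    return _anova_rows(model, {
        pp: PATHWAY_EFFECT,
        fl: LENGTH_EFFECT,
        o2t: O2_EFFECT,
        f"{pp}:{fl}": f"{PATHWAY_EFFECT}:{LENGTH_EFFECT}",
        f"{pp}:{o2t}": f"{PATHWAY_EFFECT}:{O2_EFFECT}",
        f"{fl}:{o2t}": f"{LENGTH_EFFECT}:{O2_EFFECT}",
        f"{pp}:{fl}:{o2t}": f"{PATHWAY_EFFECT}:{LENGTH_EFFECT}:{O2_EFFECT}",
    })


def format_p(p: float) -> str:
    return "<= 0.001" if p <= 0.001 else f"{p:.2f}"


def format_anova_row(row: AnovaRow) -> str:
    """One "df_num.df_den; F; P" triplet, e.g. ``1.16; 0.35; 0.56``."""
    return f"{row.df_num}.{row.df_den}; {row.f_value:.2f}; {format_p(row.p_value)}"


def anova_table(rows: list[AnovaRow]) -> pd.DataFrame:
    """Tidy frame of ANOVA rows plus the formatted triplet per effect."""
    return pd.DataFrame({
        "effect": [r.effect for r in rows],
        "df_num": [r.df_num for r in rows],
        "df_den": [r.df_den for r in rows],
        "f_value": [r.f_value for r in rows],
        "p_value": [r.p_value for r in rows],
        "formatted": [format_anova_row(r) for r in rows],
    })


def summarize_mean_sem(df: pd.DataFrame, value: str,
                       group_cols: list[str]) -> pd.DataFrame:
    """Mean and standard error of the mean per group, plus "m +/- s" text.

    Groups with a single observation get a blank SEM and a warning.
    """
    def agg(values: pd.Series) -> pd.Series:
        n = values.count()
        mean = values.mean()
        sem = values.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan
        if n < 2:
            warnings.warn("group of size < 2: SEM undefined", stacklevel=4)
            text = f"{mean:.1f} ± "
        else:
            text = f"{mean:.1f} ± {sem:.1f}"
        return pd.Series({"n": n, "mean": mean, "sem": sem, "formatted": text})

    out = (df.groupby(group_cols, observed=True)[value].apply(agg)
             .unstack().reset_index())
    out["n"] = out["n"].astype(int)
    return out
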