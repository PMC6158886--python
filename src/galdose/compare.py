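"""Strain-vs-wild-type comparisons with Bonferroni multiplicity control.

Each non-wild-type strain's replicate-level metric (expression or fitness)
is compared to the wild type with a two-sample two-tailed t-test (Welch by
default, pooled-variance Student's test optional). Raw p-values are
Bonferroni-corrected by the family size — by default the 15 non-wild-type
strains within one environment and one metric — and annotated with the
conventional star levels (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001
on the corrected p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epistasis import stars
from .genotypes import WILD_TYPE, Genotype


@dataclass
class ComparisonResult:
    strain: str
    metric: Optional[str]
    t: float
    df: float
    p_raw: float
    p_corrected: float
    stars: str
    family_size: int


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    denom = va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    if denom == 0:
        return float(len(a) + len(b) - 2)
    return float((va + vb) ** 2 / denom)


def compare_to_wildtype(
    values: Sequence[float],
    wildtype_values: Sequence[float],
    family_size: int = 15,
    equal_var: bool = False,
    strain: str = "",
    metric: Optional[str] = None,
) -> ComparisonResult:
    """Two-tailed t-test against wild type with Bonferroni correction.

    With zero variance in both groups the statistic is undefined; equal
    means are reported as t = 0, p = 1 (no evidence of a difference).
    """
    a = np.asarray(values, dtype=float)
    b = np.asarray(wildtype_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    if family_size < 1:
        raise ValueError(f"family_size must be >= 1, got {family_size}")

    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
        df = float(len(a) + len(b) - 2)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        df = float(len(a) + len(b) - 2) if equal_var else _welch_df(a, b)
        t, p = float(t), float(p)

    p_corr = min(1.0, p * family_size)
    return ComparisonResult(
        strain=strain,
        metric=metric,
        t=t,
        df=df,
        p_raw=p,
        p_corrected=p_corr,
        stars=stars(p_corr),
        family_size=family_size,
    )


def comparison_table(
    replicates: pd.DataFrame,
    metric: str,
    wild_type: Genotype = WILD_TYPE,
    family_size: Optional[int] = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Compare every non-wild-type strain to wild type on ``metric``.

    ``replicates`` has columns ``genotype``, ``metric`` and optionally
    ``environment``; comparisons and the Bonferroni family are per
    environment. ``family_size`` defaults to the number of non-wild-type
    strains present.
    """
    if metric not in replicates.columns:
        raise ValueError(f"no column {metric!r} in table")
    env_col = "environment" in replicates.columns
    groups = replicates.groupby("environment", sort=False) if env_col else [(None, replicates)]
    rows = []
    for env, df in groups:
        wt = df.loc[df["genotype"] == wild_type.code, metric].to_numpy()
        if len(wt) < 2:
            raise ValueError(f"missing wild-type replicates in environment {env}")
        strains = [g for g in df["genotype"].unique() if g != wild_type.code]
        m = family_size if family_size is not None else len(strains)
        for code in strains:
            res = compare_to_wildtype(
                df.loc[df["genotype"] == code, metric].to_numpy(), wt,
                family_size=m, equal_var=equal_var, strain=code, metric=metric,
            )
            rows.append(
                {"environment": env, "genotype": code, "metric": metric,
                 "t": res.t, "df": res.df, "p": res.p_raw,
                 "p_bonferroni": res.p_corrected, "stars": res.stars}
            )
    out = pd.DataFrame(rows)
    if not env_col:
        out = out.drop(columns=["environment"])
    return out
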