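"""Relative fitness from population ratios.

Each replicate competes the query strain against the constitutive-mCherry
reference in one culture. With both strains growing exponentially, the
query:reference odds evolve as ``R(t) = R(0) * exp(ds * t)``, so the raw
fitness is defined as the per-24 h fold-change of the odds over the 48 h
competition period::

    w_raw = (R(end) / R(start)) ** (24 / duration)

This is 1 for neutral competition, multiplicative (so the epistasis product
null is dimensionally coherent), and independent of the initial mixing
ratio under exponential growth. The log-scale counterpart (the selection
coefficient per hour) is exposed as an alternative convention. Fitness is
then normalized per environment to the mean raw fitness of the wild-type
strain, making the wild-type mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import WILD_TYPE, Genotype


def raw_fitness(
    ratio_start: float,
    ratio_end: float,
    duration_hours: float,
    reference_interval_hours: float = 24.0,
) -> float:
    """Per-reference-interval fold-change of the query:reference odds."""
    if ratio_start <= 0 or ratio_end <= 0:
        raise ValueError(
            f"population ratios must be positive, got {ratio_start}, {ratio_end}"
        )
    if duration_hours <= 0:
        raise ValueError(f"duration must be positive, got {duration_hours}")
    return float((ratio_end / ratio_start) ** (reference_interval_hours / duration_hours))


def selection_coefficient(
    ratio_start: float, ratio_end: float, duration_hours: float
) -> float:
    """Per-hour log-ratio growth advantage (log-scale fitness convention)."""
    if ratio_start <= 0 or ratio_end <= 0:
        raise ValueError(
            f"population ratios must be positive, got {ratio_start}, {ratio_end}"
        )
    if duration_hours <= 0:
        raise ValueError(f"duration must be positive, got {duration_hours}")
    return float(np.log(ratio_end / ratio_start) / duration_hours)


class MissingWildTypeError(ValueError):
    pass


def normalize_fitness(
    table: pd.DataFrame, wild_type: Genotype = WILD_TYPE
) -> pd.DataFrame:
    """Add a ``fitness`` column: raw fitness over the wild-type mean raw fitness.

    ``table`` needs columns ``genotype`` (codes), ``raw_fitness`` and, if
    several environments are present, ``environment``; normalization is per
    environment. The wild-type normalized mean is exactly 1 by construction,
    and the operation is idempotent.
    """
    if "raw_fitness" not in table.columns:
        raise ValueError("table must have a 'raw_fitness' column")
    out = table.copy()
    group_cols = ["environment"] if "environment" in table.columns else []

    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        wt = df.loc[df["genotype"] == wild_type.code, "raw_fitness"]
        if wt.empty:
            env = df["environment"].iloc[0] if group_cols else "<single>"
            raise MissingWildTypeError(
                f"no wild-type ({wild_type.code}) replicates in environment {env}"
            )
        df = df.copy()
        df["fitness"] = df["raw_fitness"] / wt.mean()
        return df

    if group_cols:
        out = (
            out.groupby(group_cols, group_keys=False, sort=False)[out.columns]
            .apply(_norm)
            .reset_index(drop=True)
        )
    else:
        out = _norm(out)
    return out


@dataclass
class FitnessEstimate:
    """Strain-level normalized fitness with replicate s.e.m."""

    genotype: Genotype
    environment: Optional[str]
    mean: float
    sem: float
    n_replicates: int


def summarize_fitness(table: pd.DataFrame) -> pd.DataFrame:
    """Per genotype (x environment) mean, s.e.m. and replicate count of ``fitness``."""
    if "fitness" not in table.columns:
        raise ValueError("table must be normalized first (no 'fitness' column)")
    keys = [c for c in ("environment", "genotype") if c in table.columns]
    grouped = table.groupby(keys, sort=False)["fitness"]
    out = grouped.agg(
        fitness_mean="mean",
        fitness_sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="size",
    ).reset_index()
    return out


def mixing_ratio_invariance_test(
    table: pd.DataFrame, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Test that measured fitness is invariant to the initial mixing ratio.

    ``table`` has columns ``genotype``, ``condition`` (initial-fraction
    label) and ``fitness`` with replicate-level values. For each strain all
    pairwise two-sample two-tailed t-tests between conditions are computed;
    the Benjamini-Hochberg procedure is applied over the whole family of
    comparisons at FDR ``alpha``. Returns one row per comparison with the
    raw p, BH-adjusted p and discovery flag.
    """
    required = {"genotype", "condition", "fitness"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    conditions = sorted(table["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two mixing-fraction conditions")

    rows = []
    for genotype, df in table.groupby("genotype", sort=False):
        groups = {c: df.loc[df["condition"] == c, "fitness"].to_numpy() for c in conditions}
        for c1, c2 in combinations(conditions, 2):
            a, b = groups[c1], groups[c2]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"untestable design: strain {genotype} has < 2 replicates "
                    f"in condition {c1 if len(a) < 2 else c2}"
                )
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append(
                {"genotype": genotype, "condition_1": c1, "condition_2": c2,
                 "t": float(t), "p": float(p)}
            )
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_bh"] = p_adj
    out["discovery"] = reject
    return out
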