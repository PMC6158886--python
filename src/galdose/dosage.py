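"""Average effect of halving one gene's dosage on fitness.

For a gene g the 2^4 design contains 8 matched pairs of genotypes that are
identical except for g's copy number. The average dosage effect is the mean
over those pairs of (fitness of the halved member - fitness of the intact
member); its uncertainty propagates the strain-level s.e.m. values through
the average assuming independent strain means::

    u = sqrt( sum_pairs (sem_halved^2 + sem_intact^2) ) / 8
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .genotypes import GENES, Genotype, enumerate_genotypes


def matched_backgrounds(gene: str) -> List[Tuple[Genotype, Genotype]]:
    """The 8 (intact, halved) genotype pairs differing only in ``gene``."""
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {GENES}")
    pairs = []
    for g in enumerate_genotypes():
        if g.copy_of(gene) == 2:
            pairs.append((g, g.with_copy(gene, 1)))
    return pairs


@dataclass
class DosageEffect:
    gene: str
    environment: Optional[str]
    effect: float  # mean over the 8 pairs of (w_halved - w_intact)
    uncertainty: float


def average_dosage_effect(
    gene: str,
    fitness_mean: Mapping[Genotype, float],
    fitness_sem: Optional[Mapping[Genotype, float]] = None,
    environment: Optional[str] = None,
) -> DosageEffect:
    """Average fitness effect of halving ``gene`` across the 8 backgrounds."""
    pairs = matched_backgrounds(gene)
    diffs = []
    var_sum = 0.0
    for intact, halved in pairs:
        try:
            w_i = fitness_mean[intact]
            w_h = fitness_mean[halved]
        except KeyError as exc:
            raise KeyError(
                f"incomplete design: missing fitness for genotype {exc.args[0]}"
            ) from exc
        diffs.append(w_h - w_i)
        if fitness_sem is not None:
            var_sum += fitness_sem[halved] ** 2 + fitness_sem[intact] ** 2
    n = len(pairs)
    return DosageEffect(
        gene=gene,
        environment=environment,
        effect=float(np.mean(diffs)),
        uncertainty=float(np.sqrt(var_sum) / n),
    )


def dosage_effect_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Dosage effects for all four genes (and all environments present).

    ``summary`` is the per-strain fitness summary with columns ``genotype``,
    ``fitness_mean``, ``fitness_sem`` and optionally ``environment``.
    """
    env_col = "environment" in summary.columns
    groups = summary.groupby("environment", sort=False) if env_col else [(None, summary)]
    rows = []
    for env, df in groups:
        mean: Dict[Genotype, float] = {
            Genotype.from_code(code): m
            for code, m in zip(df["genotype"], df["fitness_mean"])
        }
        sem: Dict[Genotype, float] = {
            Genotype.from_code(code): s
            for code, s in zip(df["genotype"], df["fitness_sem"])
        }
        for gene in GENES:
            eff = average_dosage_effect(gene, mean, sem, environment=env)
            rows.append(
                {"gene": gene, "environment": env, "effect": eff.effect,
                 "uncertainty": eff.uncertainty}
            )
    out = pd.DataFrame(rows)
    if not env_col:
        out = out.drop(columns=["environment"])
    return out
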