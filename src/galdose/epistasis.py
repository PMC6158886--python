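"""Epistatic-deviation decomposition on the 2^4 fitness lattice.

For a set M of dosage-reduced genes (|M| >= 2) the *overall* epistatic
deviation compares the multi-reduced strain's relative fitness with the
multiplicative expectation from the single-reduction strains::

    eps_M = w_M - prod_{i in M} w_i

The *net* deviation removes the contributions of all lower-order
interactions recursively::

    eps'_M = eps_M - sum_{S subset M, |S| >= 2} eps'_S      (eps'_M = eps_M for |M| = 2)

Unrolling the recursion gives an inclusion-exclusion expansion in the
overall deviations with Moebius coefficients (-1)^(|M| - |S|); for the
four-gene set this is the familiar

    eps'_ABCD = eps_ABCD - eps_ABC - eps_ABD - eps_ACD - eps_BCD
              + eps_AB + eps_AC + eps_AD + eps_BC + eps_BD + eps_CD

Standard errors are first-order (delta-method) propagations of the strain
s.e.m. values treating strain means as independent. For the net deviation
the default mode sums the squared standard errors of the overall deviations
entering the expansion ("quadrature"); an optional "delta" mode
differentiates the expansion with respect to each strain mean, which
accounts for the single-gene fitness terms shared between overall
deviations.

Significance is a two-tailed Z-test of H0: eps = 0, with the family-wise
error rate controlled by the Holm-Bonferroni step-down, one family per
environment and per deviation kind (overall vs higher-order net).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import Genotype, gene_subsets, subset_label

#: Significance levels used for star annotations, strongest first.
ALPHA_LEVELS: Tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05)


def expansion_coefficients(genes: FrozenSet[str]) -> Dict[FrozenSet[str], int]:
    """Coefficients of eps'_M as a signed sum of overall deviations eps_S.

    ``{S: (-1)^(|M| - |S|) for S subset of M, |S| >= 2}``.
    """
    if len(genes) < 2:
        raise ValueError(f"net deviation undefined for |M| = {len(genes)} < 2")
    coeffs: Dict[FrozenSet[str], int] = {}
    for s in gene_subsets(min_size=2):
        if s <= genes:
            coeffs[s] = (-1) ** (len(genes) - len(s))
    return coeffs


def strains_in_net_deviation(genes: FrozenSet[str]) -> List[Genotype]:
    """Distinct strains whose fitness enters the eps'_M expansion.

    For a third-order set this is 7 strains (the triple, its three pairs and
    three singles), matching the count of fitness measurements feeding each
    higher-order deviation.
    """
    strains = set()
    for s in expansion_coefficients(genes):
        strains.add(Genotype.from_reduced(s))
        for gene in s:
            strains.add(Genotype.from_reduced([gene]))
    return sorted(strains)


def _lookup(
    mapping: Mapping[Genotype, float], genotype: Genotype, what: str
) -> float:
    try:
        return float(mapping[genotype])
    except KeyError:
        raise KeyError(f"incomplete lattice: missing {what} for {genotype.code}") from None


def overall_deviation(
    genes: FrozenSet[str],
    fitness_mean: Mapping[Genotype, float],
    fitness_sem: Optional[Mapping[Genotype, float]] = None,
) -> Tuple[float, float]:
    """eps_M = w_M - prod_{i in M} w_i with its propagated standard error.

    SE^2 = sem(w_M)^2 + sum_i (prod_{j != i} w_j)^2 sem(w_i)^2.
    """
    genes = frozenset(genes)
    if len(genes) < 2:
        raise ValueError(f"overall deviation undefined for |M| = {len(genes)} < 2")
    g_multi = Genotype.from_reduced(genes)
    w_multi = _lookup(fitness_mean, g_multi, "fitness")
    singles = {gene: _lookup(fitness_mean, Genotype.from_reduced([gene]), "fitness")
               for gene in genes}
    eps = w_multi - float(np.prod(list(singles.values())))
    if fitness_sem is None:
        return eps, float("nan")
    var = _lookup(fitness_sem, g_multi, "s.e.m.") ** 2
    for gene in genes:
        partial = np.prod([w for g2, w in singles.items() if g2 != gene])
        var += (partial * _lookup(fitness_sem, Genotype.from_reduced([gene]), "s.e.m.")) ** 2
    return eps, float(np.sqrt(var))


def net_deviation(
    genes: FrozenSet[str],
    fitness_mean: Mapping[Genotype, float],
    fitness_sem: Optional[Mapping[Genotype, float]] = None,
    se_mode: str = "quadrature",
) -> Tuple[float, float]:
    """eps'_M and its standard error.

    ``se_mode='quadrature'`` (default) adds the squared SEs of the overall
    deviations in the inclusion-exclusion expansion; ``'delta'`` propagates
    the strain s.e.m. values through the expansion's gradient, accounting
    for shared single-gene terms.
    """
    genes = frozenset(genes)
    coeffs = expansion_coefficients(genes)
    eps = 0.0
    var = 0.0
    grad: Dict[Genotype, float] = {}
    for s, c in coeffs.items():
        e_s, se_s = overall_deviation(s, fitness_mean, fitness_sem)
        eps += c * e_s
        if fitness_sem is None:
            continue
        if se_mode == "quadrature":
            var += se_s**2
        elif se_mode == "delta":
            g_s = Genotype.from_reduced(s)
            grad[g_s] = grad.get(g_s, 0.0) + c
            singles = {gene: fitness_mean[Genotype.from_reduced([gene])] for gene in s}
            for gene in s:
                partial = float(np.prod([w for g2, w in singles.items() if g2 != gene]))
                g_i = Genotype.from_reduced([gene])
                grad[g_i] = grad.get(g_i, 0.0) - c * partial
        else:
            raise ValueError(f"unknown se_mode {se_mode!r}")
    if fitness_sem is None:
        return float(eps), float("nan")
    if se_mode == "delta":
        var = sum((d * fitness_sem[g]) ** 2 for g, d in grad.items())
    return float(eps), float(np.sqrt(var))


def z_test(eps: float, se: float) -> Tuple[float, float]:
    """Two-tailed Z-test of H0: eps = 0. Returns (Z, p)."""
    if not (se > 0):
        raise ValueError(f"untestable deviation: standard error {se} is not positive")
    z = eps / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def stars(p_adjusted: float, alphas: Sequence[float] = ALPHA_LEVELS) -> str:
    """Star annotation: one star per significance level passed."""
    for i, a in enumerate(sorted(alphas)):
        if p_adjusted < a:
            return "*" * (len(alphas) - i)
    return ""


@dataclass
class EpistasisResult:
    genes: FrozenSet[str]
    kind: str  # "overall" or "net"
    value: float
    se: float
    z: float
    p: float
    p_holm: float

    @property
    def label(self) -> str:
        return subset_label(self.genes)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_holm < alpha


def epistasis_table(
    summary: pd.DataFrame,
    se_mode: str = "quadrature",
) -> pd.DataFrame:
    """All overall (11 per environment) and higher-order net (5) deviations.

    ``summary`` is the per-strain fitness summary (columns ``genotype``,
    ``fitness_mean``, ``fitness_sem``, optionally ``environment``). Holm
    correction is applied within one family per environment per kind,
    mirroring the per-panel presentation of the results. Pairwise sets
    appear only in the "overall" family (their net deviation is identical
    by definition).
    """
    env_col = "environment" in summary.columns
    groups = summary.groupby("environment", sort=False) if env_col else [(None, summary)]
    rows = []
    for env, df in groups:
        mean = {Genotype.from_code(c): m for c, m in zip(df["genotype"], df["fitness_mean"])}
        sem = {Genotype.from_code(c): s for c, s in zip(df["genotype"], df["fitness_sem"])}
        family: Dict[str, List[dict]] = {"overall": [], "net": []}
        for genes in gene_subsets(min_size=2):
            eps, se = overall_deviation(genes, mean, sem)
            z, p = z_test(eps, se)
            family["overall"].append(
                {"environment": env, "genes": subset_label(genes), "order": len(genes),
                 "kind": "overall", "value": eps, "se": se, "z": z, "p": p}
            )
            if len(genes) >= 3:
                eps_n, se_n = net_deviation(genes, mean, sem, se_mode=se_mode)
                z_n, p_n = z_test(eps_n, se_n)
                family["net"].append(
                    {"environment": env, "genes": subset_label(genes), "order": len(genes),
                     "kind": "net", "value": eps_n, "se": se_n, "z": z_n, "p": p_n}
                )
        for kind_rows in family.values():
            p_adj = holm_adjust([r["p"] for r in kind_rows])
            for r, pa in zip(kind_rows, p_adj):
                r["p_holm"] = float(pa)
                r["stars"] = stars(pa)
            rows.extend(kind_rows)
    out = pd.DataFrame(rows)
    if not env_col:
        out = out.drop(columns=["environment"])
    return out


# ---------------------------------------------------------------------------
# Parametric null calibration
# ---------------------------------------------------------------------------


def simulate_null_studies(
    n_studies: int,
    sem: float = 0.008,
    gene_factors: Optional[Mapping[str, float]] = None,
    n_replicates: int = 9,
    alpha: float = 0.05,
    seed: int = 0,
    se_mode: str = "quadrature",
    estimated_sem: bool = False,
) -> pd.DataFrame:
    """Family-wise error calibration under a multiplicative ground truth.

    Each simulated study draws the 16 strain fitness means from normal laws
    centered on an exactly multiplicative landscape (per-gene factors
    ``gene_factors``, default modest costs) with standard deviation ``sem``
    (the realistic strain-level s.e.m.), then runs the full deviation +
    Holm analysis. With ``estimated_sem=False`` (default) the known s.e.m.
    enters the propagation, so the Z statistics are calibrated; with
    ``estimated_sem=True`` the s.e.m. is re-estimated from simulated
    replicate scatter, reproducing the mild small-sample anticonservatism
    of plugging finite-replicate s.e.m. estimates into a Z-test. Returns
    one row per study with the number of flagged overall and net deviations
    at FWER ``alpha``.
    """
    from .genotypes import enumerate_genotypes

    if gene_factors is None:
        gene_factors = {"GAL2": 0.95, "GAL3": 1.02, "GAL4": 0.97, "GAL80": 0.92}
    genotypes = enumerate_genotypes()
    truth = np.array(
        [np.prod([gene_factors[g] for g in geno.reduced]) for geno in genotypes]
    )
    rep_sd = sem * np.sqrt(n_replicates)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_studies):
        if estimated_sem:
            reps = rng.normal(truth[:, None], rep_sd, size=(len(genotypes), n_replicates))
            means = reps.mean(axis=1)
            sems = reps.std(axis=1, ddof=1) / np.sqrt(n_replicates)
        else:
            means = rng.normal(truth, sem)
            sems = np.full(len(genotypes), sem)
        summary = pd.DataFrame(
            {"genotype": [g.code for g in genotypes],
             "fitness_mean": means, "fitness_sem": sems}
        )
        table = epistasis_table(summary, se_mode=se_mode)
        flagged = table["p_holm"] < alpha
        rows.append(
            {"study": i,
             "n_flagged_overall": int((flagged & (table["kind"] == "overall")).sum()),
             "n_flagged_net": int((flagged & (table["kind"] == "net")).sum())}
        )
    out = pd.DataFrame(rows)
    out["any_flagged"] = (out["n_flagged_overall"] + out["n_flagged_net"]) > 0
    return out
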