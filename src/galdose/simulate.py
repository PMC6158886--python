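"""Synthetic competition experiments with known ground truth.

This module generates flow-cytometry event tables with the statistical
structure the analysis assumes, standing in for the study's raw data (which
were never deposited):

* **Competition dynamics.** The query and reference strains grow
  exponentially, so the log-odds of query vs reference cells is linear in
  time with slope equal to the selection coefficient ``ds`` (per hour):
  ``R(t) = R(0) * exp(ds * t)``. Observed counts at each timepoint are a
  binomial draw at the corresponding query fraction, which is the only noise
  on the population ratio.
* **Fluorescence.** Channel intensities are log-normal with a configurable
  coefficient of variation (default 0.25). Query cells express YFP at the
  genotype's mean log-expression (optionally a two-component on/off mixture,
  emulating the multimodal distributions seen at minimal galactose);
  reference cells express mCherry from a well-separated constitutive law.
  Each population has only basal fluorescence in the other channel.
* **Contamination.** A configurable fraction of events (default 10%) is
  debris-like: diffuse uniform FSC-SSC over an enlarged box and dim
  fluorescence. The density gate exists to remove these.

The default ground truth encodes the qualitative structure of the measured
dosage-fitness landscape: halving GAL80 raises network expression; halving
GAL2 costs fitness only at low galactose; in the minimal-galactose
mixed-sugar environment fitness is a hockey-stick function of expression
(flat until expression exceeds a threshold, then costly); in pure-galactose
environments fitness is linear in expression with a slope increasing in
log-galactose that saturates above 1% galactose.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from math import log
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .environments import Environment, get_environment
from .events import TIMEPOINTS, CompetitionExperiment, EventTable
from .genotypes import Genotype, enumerate_genotypes

# -- default generator constants -------------------------------------------

#: Additive per-gene effects of dosage halving on mean log YFP expression.
#: GAL80 (the inhibitor) raises expression when halved; the activator GAL4,
#: transducer GAL3 and permease GAL2 lower it by decreasing amounts.
LOG_EXPRESSION_EFFECTS: Dict[str, float] = {
    "GAL2": -0.06,
    "GAL3": -0.12,
    "GAL4": -0.25,
    "GAL80": +0.60,
}

#: Wild-type mean log YFP per environment (arbitrary fluorescence units).
_BASE_LOG_EXPRESSION = {"A": log(400.0), "B": log(800.0)}
_BASE_LOG_EXPRESSION_DEFAULT = log(1000.0)

#: Slope of the selection coefficient in relative expression per unit
#: ln(galactose) for pure-galactose environments (per hour); zero crossing
#: at 0.2% galactose, saturating above 1%.
_PURE_GAL_SLOPE_PER_LOG = 0.009
_PURE_GAL_NEUTRAL_CONC = 0.2
_SATURATION_CONC = 1.0

#: Selection cost per unit relative expression in the mirror environment (B).
_MIXED_SUGAR_COST = 0.006

#: Hockey-stick parameters for the minimal-galactose environment (A):
#: cost per unit log-expression above threshold, and the threshold itself.
_HOCKEY_COST = 0.012
_HOCKEY_THRESHOLD = 0.15
_GAL3_BONUS_ENV_A = 0.0015

#: GAL2-halving selection terms by regime (per hour).
_GAL2_LOW_GAL_MIXED = -0.008  # environment B
_GAL2_LOW_GAL_PURE = -0.006  # pure galactose <= 0.15%
_GAL2_HIGH_GAL = +0.002  # pure galactose > 0.5%


@dataclass
class GroundTruth:
    """Generator parameters for one environment, keyed by genotype."""

    environment: Environment
    mean_log_expression: Dict[Genotype, float]
    selection_coefficient: Dict[Genotype, float]  # per hour, query vs reference
    contamination_fraction: float = 0.10
    fluorescence_cv: float = 0.25
    bimodal: bool = False
    induced_fraction: float = 0.6  # on-fraction of the mixture when bimodal
    ref_mcherry_log_mean: float = log(1500.0)
    query_mcherry_log_mean: float = log(30.0)
    ref_yfp_log_mean: float = log(30.0)
    basal_yfp_log_mean: float = log(50.0)
    fsc_log_mean: float = log(5.0e4)
    fsc_log_sd: float = 0.15
    ssc_log_mean: float = log(3.0e4)
    ssc_log_sd: float = 0.18

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_fraction <= 0.3):
            raise ValueError(
                f"contamination_fraction must be in [0, 0.3], "
                f"got {self.contamination_fraction}"
            )
        for g, s in self.selection_coefficient.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite selection coefficient for {g.code}")

    @property
    def log_sd(self) -> float:
        """Log-scale s.d. corresponding to the configured linear-scale CV."""
        return float(np.sqrt(np.log1p(self.fluorescence_cv**2)))


def default_ground_truth(
    environment: Union[str, Environment],
    *,
    expression_effects: Optional[Dict[str, float]] = None,
    neutral: bool = False,
    saturating: bool = True,
    contamination_fraction: float = 0.10,
    bimodal: Optional[bool] = None,
    genotypes: Optional[Sequence[Genotype]] = None,
) -> GroundTruth:
    """Build the default ground truth for an environment.

    Parameters
    ----------
    neutral
        Zero every selection coefficient (all genotypes competitively
        identical to the reference) while keeping expression structure.
    saturating
        Cap the expression-fitness slope at its 1%-galactose value for
        higher concentrations, producing the saturation regime the
        dose-response model is meant to diagnose.
    expression_effects
        Override the per-gene additive log-expression effects.
    """
    env = get_environment(environment)
    if genotypes is None:
        genotypes = enumerate_genotypes()
    effects = dict(LOG_EXPRESSION_EFFECTS if expression_effects is None else expression_effects)

    base_mu = _BASE_LOG_EXPRESSION.get(env.name, _BASE_LOG_EXPRESSION_DEFAULT)
    mu: Dict[Genotype, float] = {}
    for g in genotypes:
        mu[g] = base_mu + sum(effects[gene] for gene in g.reduced)

    mu_wt = base_mu  # wild type carries no reductions
    s: Dict[Genotype, float] = {}
    for g in genotypes:
        if neutral:
            s[g] = 0.0
            continue
        dmu = mu[g] - mu_wt
        rel = float(np.exp(dmu))  # relative expression, WT = 1
        if env.mannose > 0 and env.galactose <= 0.05:
            # minimal galactose + neutral sugar: hockey-stick cost of induction
            val = -_HOCKEY_COST * max(0.0, dmu - _HOCKEY_THRESHOLD)
            if "GAL3" in g.reduced:
                val += _GAL3_BONUS_ENV_A
        elif env.mannose > 0:
            # moderate galactose + minimal neutral sugar: expression is costly
            val = -_MIXED_SUGAR_COST * (rel - 1.0)
            if "GAL2" in g.reduced:
                val += _GAL2_LOW_GAL_MIXED
        else:
            # pure galactose: linear in expression, slope grows with ln(gal)
            conc = min(env.galactose, _SATURATION_CONC) if saturating else env.galactose
            slope = _PURE_GAL_SLOPE_PER_LOG * (log(conc) - log(_PURE_GAL_NEUTRAL_CONC))
            val = slope * (rel - 1.0)
            if "GAL2" in g.reduced:
                if env.galactose <= 0.15:
                    val += _GAL2_LOW_GAL_PURE
                elif env.galactose > 0.5:
                    val += _GAL2_HIGH_GAL
        s[g] = val

    if bimodal is None:
        bimodal = env.name == "A"
    return GroundTruth(
        environment=env,
        mean_log_expression=mu,
        selection_coefficient=s,
        contamination_fraction=contamination_fraction,
        bimodal=bimodal,
    )


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def sample_seed(
    master_seed: int,
    genotype: Genotype,
    environment: Union[str, Environment],
    replicate: int,
    label: str = "",
) -> np.random.SeedSequence:
    """Derive a per-sample seed by stable hashing of the sample key.

    The hash depends only on (genotype code, environment name, replicate,
    label), so any subset of the study can be regenerated identically.
    """
    env = get_environment(environment)
    key = f"{genotype.code}|{env.name}|{replicate}|{label}".encode()
    digest = hashlib.sha256(key).digest()
    salt = int.from_bytes(digest[:8], "big")
    return np.random.SeedSequence([int(master_seed), salt])


# ---------------------------------------------------------------------------
# Event sampling
# ---------------------------------------------------------------------------


def _sample_events(
    rng: np.random.Generator,
    truth: GroundTruth,
    genotype: Genotype,
    query_fraction: float,
    n_events: int,
) -> pd.DataFrame:
    """Draw one timepoint's event table at the given true query fraction."""
    sd = truth.log_sd
    n_contam = rng.binomial(n_events, truth.contamination_fraction)
    n_clean = n_events - n_contam
    n_query = rng.binomial(n_clean, query_fraction)
    n_ref = n_clean - n_query

    fsc = np.empty(n_events)
    ssc = np.empty(n_events)
    yfp = np.empty(n_events)
    mch = np.empty(n_events)

    # healthy cells: shared tight FSC-SSC cluster
    fsc[:n_clean] = rng.lognormal(truth.fsc_log_mean, truth.fsc_log_sd, n_clean)
    ssc[:n_clean] = rng.lognormal(truth.ssc_log_mean, truth.ssc_log_sd, n_clean)

    mu_q = truth.mean_log_expression[genotype]
    if truth.bimodal and n_query:
        n_on = rng.binomial(n_query, truth.induced_fraction)
        yfp_q = np.concatenate(
            [
                rng.lognormal(mu_q, sd, n_on),
                rng.lognormal(truth.basal_yfp_log_mean, sd, n_query - n_on),
            ]
        )
        yfp_q = rng.permutation(yfp_q)
    else:
        yfp_q = rng.lognormal(mu_q, sd, n_query)
    yfp[:n_query] = yfp_q
    mch[:n_query] = rng.lognormal(truth.query_mcherry_log_mean, sd, n_query)

    yfp[n_query:n_clean] = rng.lognormal(truth.ref_yfp_log_mean, sd, n_ref)
    mch[n_query:n_clean] = rng.lognormal(truth.ref_mcherry_log_mean, sd, n_ref)

    # debris: diffuse scatter over an enlarged box, dim fluorescence
    fsc_hi = 4.0 * np.exp(truth.fsc_log_mean)
    ssc_hi = 4.0 * np.exp(truth.ssc_log_mean)
    fsc[n_clean:] = rng.uniform(0.0, fsc_hi, n_contam)
    ssc[n_clean:] = rng.uniform(0.0, ssc_hi, n_contam)
    yfp[n_clean:] = rng.uniform(0.0, 100.0, n_contam)
    mch[n_clean:] = rng.uniform(0.0, 100.0, n_contam)

    perm = rng.permutation(n_events)
    return pd.DataFrame(
        {"FSC": fsc[perm], "SSC": ssc[perm], "YFP": yfp[perm], "mCherry": mch[perm]}
    )


def simulate_competition(
    genotype: Genotype,
    environment: Union[str, Environment],
    truth: GroundTruth,
    init_fraction: float = 0.5,
    n_events: int = 25_000,
    seed: Union[int, np.random.SeedSequence, np.random.Generator] = 0,
    timepoints: Sequence[float] = TIMEPOINTS,
    replicate: int = 0,
) -> CompetitionExperiment:
    """Simulate one competition experiment (three timepoints, one replicate).

    The query fraction at time ``t`` is the logistic transform of
    ``logit(init_fraction) + ds * t`` where ``ds`` is the genotype's
    selection coefficient per hour; event counts are binomial at that
    fraction.
    """
    env = get_environment(environment)
    if not (0.0 < init_fraction < 1.0):
        raise ValueError(f"init_fraction must be in (0, 1), got {init_fraction}")
    if n_events < 1000:
        raise ValueError(f"n_events must be >= 1000, got {n_events}")
    ds = truth.selection_coefficient[genotype]
    if not np.isfinite(ds):
        raise ValueError(f"non-finite selection coefficient for {genotype.code}")

    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    logit0 = logit(init_fraction)
    tables: Dict[float, EventTable] = {}
    for t in timepoints:
        f_t = float(expit(logit0 + ds * t))
        data = _sample_events(rng, truth, genotype, f_t, n_events)
        tables[float(t)] = EventTable(
            data=data,
            genotype=genotype,
            environment=env.name,
            replicate=replicate,
            timepoint=float(t),
        )
    return CompetitionExperiment(
        genotype=genotype,
        environment=env.name,
        replicate=replicate,
        init_fraction=init_fraction,
        tables=tables,
    )
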