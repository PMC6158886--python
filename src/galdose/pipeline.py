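"""End-to-end study orchestration: simulate -> gate -> quantify -> analyze.

:func:`run_study` reproduces the complete analysis on a synthetic study:
for every genotype x environment x replicate it simulates (or loads) the
three-timepoint competition experiment, density-gates each sample,
classifies query vs reference cells, computes population ratios and
normalized expression, derives replicate fitness from the 0 h and 48 h
ratios, normalizes to wild type, and then produces the strain summaries,
per-gene dosage effects, the epistasis decomposition with Holm-corrected
Z-tests, strain-vs-wild-type comparisons, and the expression-fitness
dose-response model trained on the 0.3% and 1% pure-galactose
environments.

All randomness flows from a single master seed expanded to per-sample seeds
by stable hashing, so results are fully deterministic and any sample can be
regenerated in isolation. A study can also be materialized to disk as CSV
event tables plus a YAML manifest (:func:`simulate_study_to_dir`) and
re-analyzed from those files with identical results.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import dose_response as dr
from .compare import comparison_table
from .dosage import dosage_effect_table
from .environments import ENVIRONMENTS, get_environment
from .epistasis import epistasis_table
from .events import TIMEPOINTS, CompetitionExperiment, read_events, write_events
from .fitness import (
    mixing_ratio_invariance_test,
    normalize_fitness,
    raw_fitness,
    selection_coefficient,
    summarize_fitness,
)
from .gating import DEFAULT_GATE_FRACTION, GATE_BAND, density_gate
from .genotypes import enumerate_genotypes
from .quantify import classify_events, normalized_expression, population_ratio
from .simulate import GroundTruth, default_ground_truth, sample_seed, simulate_competition

CONFIG_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """Design and analysis options; defaults reproduce the study layout.

    16 genotypes x 6 environments x 9 replicates, ~25,000 events per sample,
    density gate at the midpoint of the 30-40% band, 1:1 initial mixing
    (3:7 query:reference in environment A).
    """

    environments: Tuple[str, ...] = tuple(ENVIRONMENTS)
    n_replicates: int = 9
    n_events: int = 25_000
    gate_target_fraction: float = DEFAULT_GATE_FRACTION
    init_fraction: float = 0.5
    init_fraction_env_a: float = 0.3
    fitness_convention: str = "fold"  # or "log"
    reference_interval_hours: float = 24.0
    contamination_fraction: float = 0.10
    neutral: bool = False
    saturating: bool = True
    mcherry_threshold: Optional[float] = None
    se_mode: str = "quadrature"
    equal_var_ttests: bool = False
    dose_response_train: Tuple[str, ...] = ("E", "D")
    dose_response_form: str = "log"
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self) -> None:
        for env in self.environments:
            get_environment(env)
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for s.e.m. columns")
        if self.n_events < 1000:
            raise ValueError("need at least 1000 events per sample")
        lo, hi = GATE_BAND
        if not (0.0 < self.gate_target_fraction <= 1.0):
            raise ValueError("gate_target_fraction must be in (0, 1]")
        for f in (self.init_fraction, self.init_fraction_env_a):
            if not (0.0 < f < 1.0):
                raise ValueError("initial fractions must be in (0, 1)")
        if self.fitness_convention not in ("fold", "log"):
            raise ValueError("fitness_convention must be 'fold' or 'log'")

    def init_fraction_for(self, env_name: str) -> float:
        return self.init_fraction_env_a if env_name == "A" else self.init_fraction

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["environments"] = list(self.environments)
        data["dose_response_train"] = list(self.dose_response_train)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        version = data.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        for key in ("environments", "dose_response_train"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class StudyResult:
    """All tables produced by one study run."""

    config: StudyConfig
    truths: Dict[str, GroundTruth]
    samples: pd.DataFrame  # per sample x timepoint quantification
    gate_summary: pd.DataFrame
    fitness: pd.DataFrame  # replicate-level raw + normalized fitness
    fitness_summary: pd.DataFrame
    expression: pd.DataFrame  # replicate-level expression (3-timepoint mean)
    expression_summary: pd.DataFrame
    dosage_effects: pd.DataFrame
    epistasis: pd.DataFrame
    comparisons: pd.DataFrame
    dose_response: Optional[dr.DoseResponseModel]
    dose_response_points: pd.DataFrame

    def save(self, outdir: Union[str, Path]) -> None:
        """Write every table as TSV (deterministic float formatting)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "samples": self.samples,
            "gate_summary": self.gate_summary,
            "fitness": self.fitness,
            "fitness_summary": self.fitness_summary,
            "expression": self.expression,
            "expression_summary": self.expression_summary,
            "dosage_effects": self.dosage_effects,
            "epistasis": self.epistasis,
            "comparisons": self.comparisons,
            "dose_response_points": self.dose_response_points,
        }
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                         float_format="%.12g")
        if self.dose_response is not None:
            model = self.dose_response
            (outdir / "dose_response_model.yaml").write_text(
                yaml.safe_dump(
                    {
                        "form": model.form,
                        "intercept": model.intercept,
                        "expression_slope": model.expression_slope,
                        "interaction": model.interaction,
                        "se": list(model.se),
                        "resid_sd": model.resid_sd,
                        "n_points": model.n_points,
                        "galactose_levels": list(model.galactose_levels),
                    },
                    sort_keys=False,
                )
            )
        self.config.to_yaml(outdir / "config.yaml")


def _truth_for(config: StudyConfig, env_name: str) -> GroundTruth:
    return default_ground_truth(
        env_name,
        neutral=config.neutral,
        saturating=config.saturating,
        contamination_fraction=config.contamination_fraction,
    )


def _process_experiment(
    exp: CompetitionExperiment, config: StudyConfig
) -> Tuple[List[dict], List[dict], dict, dict]:
    """Gate + classify the three timepoints; derive replicate fitness/expression."""
    sample_rows = []
    gate_rows = []
    ratios: Dict[float, float] = {}
    expr_values: Dict[float, float] = {}
    for t in sorted(exp.tables):
        table = exp.tables[t]
        gate = density_gate(table, target_fraction=config.gate_target_fraction)
        gated = gate.apply(table)
        quant = classify_events(gated, mcherry_threshold=config.mcherry_threshold)
        ratio = population_ratio(quant)
        expr = normalized_expression(quant)
        ratios[t] = ratio
        expr_values[t] = expr
        base = {
            "environment": exp.environment,
            "genotype": exp.genotype.code,
            "replicate": exp.replicate,
            "timepoint": t,
        }
        gate_rows.append(
            {**base, "n_total": gate.n_total, "n_retained": gate.n_retained,
             "gate_fraction": gate.fraction}
        )
        sample_rows.append(
            {**base, "n_gated": gate.n_retained, "n_query": quant.n_query,
             "n_reference": quant.n_reference,
             "query_fraction": quant.query_fraction, "ratio": ratio,
             "normalized_expression": expr}
        )
    t0, t_end = min(ratios), max(ratios)
    duration = t_end - t0
    if config.fitness_convention == "log":
        raw = selection_coefficient(ratios[t0], ratios[t_end], duration)
    else:
        raw = raw_fitness(
            ratios[t0], ratios[t_end], duration,
            reference_interval_hours=config.reference_interval_hours,
        )
    fitness_row = {
        "environment": exp.environment,
        "genotype": exp.genotype.code,
        "replicate": exp.replicate,
        "init_fraction": exp.init_fraction,
        "ratio_start": ratios[t0],
        "ratio_end": ratios[t_end],
        "raw_fitness": raw,
    }
    expr_row = {
        "environment": exp.environment,
        "genotype": exp.genotype.code,
        "replicate": exp.replicate,
        "expression": float(np.mean(list(expr_values.values()))),
    }
    return sample_rows, gate_rows, fitness_row, expr_row


def _iter_experiments(config: StudyConfig, events_dir: Optional[Path] = None):
    """Yield every experiment of the design, simulated or loaded from disk."""
    genotypes = enumerate_genotypes()
    manifest = None
    if events_dir is not None:
        manifest = yaml.safe_load((Path(events_dir) / "manifest.yaml").read_text())
    for env_name in config.environments:
        truth = _truth_for(config, env_name)
        for genotype in genotypes:
            for rep in range(config.n_replicates):
                if events_dir is None:
                    exp = simulate_competition(
                        genotype,
                        env_name,
                        truth,
                        init_fraction=config.init_fraction_for(env_name),
                        n_events=config.n_events,
                        seed=sample_seed(config.seed, genotype, env_name, rep),
                        replicate=rep,
                    )
                else:
                    key = f"{env_name}/{genotype.code}/{rep}"
                    tables = {}
                    for t in TIMEPOINTS:
                        rel = manifest["samples"][key][str(int(t))]
                        tables[t] = read_events(Path(events_dir) / rel)
                    exp = CompetitionExperiment(
                        genotype=genotype,
                        environment=env_name,
                        replicate=rep,
                        init_fraction=config.init_fraction_for(env_name),
                        tables=tables,
                    )
                yield exp


def simulate_study_to_dir(config: StudyConfig, outdir: Union[str, Path]) -> Path:
    """Materialize every event table as CSV plus a ``manifest.yaml``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Dict[str, str]] = {}
    for exp in _iter_experiments(config):
        key = f"{exp.environment}/{exp.genotype.code}/{exp.replicate}"
        entry = {}
        for t, table in exp.tables.items():
            rel = f"events/{exp.environment}/{exp.genotype.code}_r{exp.replicate}_t{int(t)}.csv"
            path = outdir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            write_events(path, table)
            entry[str(int(t))] = rel
        manifest[key] = entry
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump({"samples": manifest}, sort_keys=True)
    )
    config.to_yaml(outdir / "config.yaml")
    return outdir


def run_study(
    config: Optional[StudyConfig] = None,
    events_dir: Optional[Union[str, Path]] = None,
) -> StudyResult:
    """Run the full pipeline; see the module docstring for the stages."""
    if config is None:
        config = StudyConfig()
    config.validate()
    events_dir = Path(events_dir) if events_dir is not None else None

    sample_rows: List[dict] = []
    gate_rows: List[dict] = []
    fitness_rows: List[dict] = []
    expr_rows: List[dict] = []
    for exp in _iter_experiments(config, events_dir):
        s_rows, g_rows, f_row, e_row = _process_experiment(exp, config)
        sample_rows.extend(s_rows)
        gate_rows.extend(g_rows)
        fitness_rows.append(f_row)
        expr_rows.append(e_row)

    samples = pd.DataFrame(sample_rows)
    gate_summary = pd.DataFrame(gate_rows)
    fitness = normalize_fitness(pd.DataFrame(fitness_rows))
    fitness_summary = summarize_fitness(fitness)

    expression = pd.DataFrame(expr_rows)
    expr_grouped = expression.groupby(["environment", "genotype"], sort=False)["expression"]
    expression_summary = expr_grouped.agg(
        expression_mean="mean",
        expression_sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
        n="size",
    ).reset_index()

    dosage = dosage_effect_table(fitness_summary)
    epi = epistasis_table(fitness_summary, se_mode=config.se_mode)

    comp_fitness = comparison_table(fitness, "fitness", equal_var=config.equal_var_ttests)
    comp_expr = comparison_table(expression, "expression", equal_var=config.equal_var_ttests)
    comparisons = pd.concat([comp_fitness, comp_expr], ignore_index=True)

    points = expression_summary.merge(
        fitness_summary, on=["environment", "genotype"]
    )
    points["galactose"] = [get_environment(e).galactose for e in points["environment"]]
    points["mannose"] = [get_environment(e).mannose for e in points["environment"]]
    train_envs = [e for e in config.dose_response_train if e in config.environments]
    model = None
    if len(train_envs) >= 2:
        train = points[points["environment"].isin(train_envs)]
        model = dr.fit_dose_response(
            train["expression_mean"], train["fitness_mean"], train["galactose"],
            form=config.dose_response_form,
        )

    return StudyResult(
        config=config,
        truths={env: _truth_for(config, env) for env in config.environments},
        samples=samples,
        gate_summary=gate_summary,
        fitness=fitness,
        fitness_summary=fitness_summary,
        expression=expression,
        expression_summary=expression_summary,
        dosage_effects=dosage,
        epistasis=epi,
        comparisons=comparisons,
        dose_response=model,
        dose_response_points=points,
    )


def run_mixing_invariance(
    config: Optional[StudyConfig] = None,
    environment: str = "D",
    fractions: Sequence[float] = (0.27, 0.54, 0.67),
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the initial-mixing-ratio invariance control.

    Runs the single-environment competition at several initial query
    fractions, quantifies fitness as usual, and tests per-strain pairwise
    differences between fraction conditions with Benjamini-Hochberg FDR
    control. Returns (replicate fitness table, test table).
    """
    if config is None:
        config = StudyConfig()
    config.validate()
    truth = _truth_for(config, environment)
    rows = []
    for frac in fractions:
        for genotype in enumerate_genotypes():
            for rep in range(config.n_replicates):
                exp = simulate_competition(
                    genotype,
                    environment,
                    truth,
                    init_fraction=frac,
                    n_events=config.n_events,
                    seed=sample_seed(
                        config.seed, genotype, environment, rep, label=f"mix{frac}"
                    ),
                    replicate=rep,
                )
                _, _, f_row, _ = _process_experiment(exp, config)
                f_row["condition"] = frac
                rows.append(f_row)
    table = normalize_fitness(pd.DataFrame(rows))
    tests = mixing_ratio_invariance_test(table, alpha=alpha,
                                         equal_var=config.equal_var_ttests)
    return table, tests
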