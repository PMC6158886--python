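# galdose

Quantitative analysis of combinatorial gene-dosage perturbation in the
yeast galactose-utilization (GAL) network: from single-cell flow-cytometry
events to relative fitness, per-gene dosage effects, an epistasis
decomposition on the 2⁴ fitness lattice, and an expression–fitness
dose–response model — together with a synthetic-data generator that
emulates the underlying competition experiments with known ground truth.

## The scientific problem

Genes interact with the environment through networks. In diploid
*Saccharomyces cerevisiae*, halving the copy number of each of the four
GAL regulatory genes — *GAL2* (permease), *GAL3* (signal transducer),
*GAL4* (activator), *GAL80* (inhibitor) — in every combination gives 16
genotypes indexed by the set *M* of dosage-reduced genes. Competing each
genotype against a constitutively mCherry-marked reference strain in six
sugar environments (galactose from 0.03% to 2%, with or without the
neutral sugar mannose), and reading network activity through a
P<sub>GAL1</sub>-YFP reporter, links dosage → network activity → fitness.

The core quantities:

- **Relative fitness.** With exponential growth the query:reference odds
  follow *R(t) = R(0)·e^{Δs·t}*; raw fitness is the per-24 h odds
  fold-change *w* = (*R*₄₈/*R*₀)^{24/48}, normalized per environment so the
  wild-type mean is exactly 1. Each replicate uses ~25,000 recorded events
  per timepoint, density-gated on FSC–SSC to the densest 30–40%.
- **Average dosage effect.** For gene *g*, the mean of
  *w*(halved) − *w*(intact) over the 8 genetic backgrounds differing only
  in *g*, with uncertainty propagated from the strain s.e.m. values
  (N = 9 replicates).
- **Epistatic deviations.** Overall: ε*₍M₎* = *w₍M₎* − Π*₍i∈M₎ wᵢ*
  (multiplicative null). Net: ε′*₍M₎* = ε*₍M₎* − Σ ε′*₍S₎* over proper
  subsets *S* ⊂ *M* with |*S*| ≥ 2, equivalently an inclusion–exclusion
  expansion with coefficients (−1)^{|M|−|S|}. Significance by two-tailed
  Z-test with Holm–Bonferroni FWER control.
- **Dose–response model.** *w* = β₀ + (β₁ + β₂ ln *g*)·*E* fitted by OLS
  to strain means from the 0.3% and 1% pure-galactose environments, with a
  saturation diagnostic for the 2% environment.

## Worked example

```python
import galdose as gd

result = gd.run_study(gd.StudyConfig(seed=1))   # full 16 x 6 x 9 study
print(result.fitness_summary.head(3))
```

```
  environment genotype  fitness_mean  fitness_sem  n
0           A     2222      1.000000     0.004012  9
1           A     1222      0.990911     0.006703  9
2           A     2122      1.027486     0.007166  9
```

Each row is one strain in one environment: mean normalized fitness over
nine replicates with its s.e.m. (`2222` is the wild type, `1222` carries a
single *GAL2* copy). Downstream tables live on the same result object:
`result.dosage_effects`, `result.epistasis` (11 overall + 5 net deviations
per environment with Holm-corrected p-values and star levels),
`result.comparisons` (Bonferroni-corrected strain-vs-wild-type t-tests)
and `result.dose_response`. From the same run, the fitted model is

```
w = 0.781 + (0.419 + 0.109 ln g) E      residual s.d. 0.047
```

so the fitness benefit per unit expression grows with log-galactose; held
out at 2% galactose, the observed strains fall below this line (mean
residual −0.069) but close to the 1% line (−0.011), the signature of
saturated galactose import.

The `examples/` directory has one short narrative script per capability
(simulation + gating, fitness estimation, epistasis decomposition,
dose–response), and the `galdose` command exposes `run`, `simulate` and
`mixing-test` subcommands for shell use.

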