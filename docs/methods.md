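# Methods

This note documents the models, estimators and numerical choices behind
`galdose`, and what its synthetic study does and does not establish about
real data.

## Study design

The design is the full factorial of 16 copy-number genotypes (each of
*GAL2*, *GAL3*, *GAL4*, *GAL80* at 1 or 2 copies in a diploid) × 6
environments × 9 biological replicates, with flow-cytometry samples at
0, 24 and 48 h of a competition against a constitutively mCherry-marked
wild-type reference. The six environments (galactose %, mannose %):
A (0.03, 0.1), B (0.1, 0.03), C (0.1, 0), D (1, 0), E (0.3, 0),
F (2, 0). Each sample records ~25,000 events with FSC, SSC, YFP and
mCherry channels. The query strain is mixed 1:1 with the reference
(3:7 in environment A, where the query grows markedly slower).

## Synthetic-data generator

The generator produces event tables with the statistical structure the
analysis assumes; its defaults are the study conditions.

**Competition dynamics.** Both strains grow exponentially, so the
query:reference log-odds is linear in time with slope Δs (the selection
coefficient, per hour): logit f(t) = logit f₀ + Δs·t. Observed counts are
binomial draws at f(t); there is no other noise on the population ratio —
no lag or diauxic phase is modelled, because the protocol equilibrates the
mixture in the competition environment before t = 0.

**Fluorescence.** Channels are log-normal with linear-scale CV 0.25
(log-sd √ln(1 + CV²) ≈ 0.246). Query cells draw YFP at the genotype's
mean log-expression; reference cells draw mCherry at ln 1500, with basal
levels (ln 30–ln 50) in the opposite channels, giving ≫ 6σ mode
separation. In environment A the query YFP is a two-component on/off
mixture (on-fraction 0.6, off component at the basal level), emulating
the multimodal activity distributions seen at minimal galactose.

**Scatter and contamination.** Healthy cells share one tight log-normal
FSC–SSC cluster; a contamination fraction (default 10%, valid range
0–30%) of debris-like events is uniform over a 4× enlarged scatter box
with dim fluorescence. This is what the density gate removes.

**Ground-truth landscape.** Mean log-expression is additive in per-gene
effects (GAL80 +0.60, GAL4 −0.25, GAL3 −0.12, GAL2 −0.06 on the log
scale), sized so all 16 subset sums are distinct (min gap ≈ 0.04) and the
inhibitor's effect dominates. Selection coefficients derive from relative
expression x = e^{Δμ} through environment-specific maps chosen to encode
the qualitative landscape the analysis must resolve:

- environment A: hockey stick, Δs = −0.012·max(0, Δμ − 0.15), plus a
  +0.0015 bonus for halved GAL3 (cost attaches to activating the network
  at all, not to expression magnitude);
- environment B: Δs = −0.006·(x − 1) (expression is costly when the
  neutral sugar can carry growth);
- pure galactose: Δs = 0.009·(ln g* − ln 0.2)·(x − 1) with
  g* = min(g, 1): the slope crosses zero at 0.2% galactose and saturates
  above 1%, which is what the dose–response module must diagnose;
- GAL2-specific permease term: −0.008 (B), −0.006 (pure galactose
  ≤ 0.15%), +0.002 (pure galactose > 0.5%), 0 otherwise.

Magnitudes give per-24 h fitness effects of roughly ±3–30%, comfortably
above the counting noise of a 25,000-event sample (s.e.m. of normalized
fitness ≈ 0.5% at N = 9) but not so large that logistic saturation of the
query fraction matters over 48 h. The generator does not model cell-cycle
or volume effects, spectral spillover, instrument drift, day effects, or
any mechanistic GAL kinetics: passing recovery tests shows the estimators
are correct under the stated noise model, not that the biology is.

**Seeding.** One master seed plus a SHA-256 hash of (genotype code,
environment, replicate, label) feeds a `numpy` `SeedSequence` per sample,
so any sample can be regenerated in isolation and the full study is
deterministic.

## Gating

Density is a 2-D histogram on a 64×64 grid over the robust (1st–99th
percentile) FSC–SSC ranges; out-of-range events fall into edge bins.
Events are ranked by their bin count with ties broken by original index,
and the top ⌈target·n⌉ are retained (target 0.35, the midpoint of the
30–40% band; the band endpoints are configuration, not hard-coded).
This equals a brute-force density sort, is deterministic, and is nested
in the target fraction. Zero-variance scatter degenerates to one bin,
retaining a stable index prefix. Samples under 100 events are rejected.

## Quantification

Classification is on mCherry only: the threshold is the minimum of the
Gaussian-smoothed (σ = 2 bins, 128 bins) log-mCherry histogram between
its two largest modes, falling back to the log-range midpoint if modes
cannot be separated; a fixed threshold can be configured. Expression is
the arithmetic mean YFP of query cells divided by the arithmetic mean
mCherry of reference cells in the same sample (linear-scale means;
reference normalization controls density/drift). A replicate's expression
is the mean of its three timepoint values; the strain estimate is the
replicate mean with s.e.m. = sd/√N.

## Fitness

Raw fitness is (R₄₈/R₀)^{24/48}, the per-24 h odds fold-change — strictly
positive, multiplicative, equal to e^{24Δs} under the growth model, and
independent of the initial mixing fraction. The per-24 h exponent and a
log-scale (selection-coefficient) convention are configuration options;
each replicate pairs its own start and end ratios. Normalization divides
every replicate by the mean wild-type raw fitness of the same
environment, making the wild-type mean exactly 1 and the operation
idempotent. The mixing-ratio control re-runs one environment at initial
fractions 0.27/0.54/0.67 and applies per-strain pairwise Welch t-tests
with Benjamini–Hochberg FDR control at 0.05 over all comparisons.

## Dosage effects and epistasis

The average dosage effect of gene *g* is the mean of
w(halved) − w(intact) over the 8 matched background pairs; uncertainty is
√Σ(sem²ₕ + sem²ᵢ)/8, treating the 16 strain means as independent — an
approximation, since wild-type normalization induces a weak common
factor. Strain means (not replicate-level differences) enter the average.

Overall deviation: ε_M = w_M − Π wᵢ, with first-order SE
√(sem_M² + Σᵢ (Π_{j≠i} wⱼ)²·semᵢ²). Net deviation: the subset recursion,
implemented through its closed-form Möbius expansion
ε′_M = Σ_{S⊆M,|S|≥2} (−1)^{|M|−|S|} ε_S; the reconstruction identity
Σ_{S⊆M} ε′_S = ε_M holds exactly by construction and is verified to
1e-12 on random lattices. The default SE for ε′ sums the squared SEs of
the ε_S in the expansion; a covariance-aware "delta" mode differentiates
the expansion with respect to each strain mean instead, capturing the
cancellation of shared single-gene terms (it is never larger in
practice). Significance: Z = ε/SE against the standard normal,
two-tailed, Holm–Bonferroni per environment and per panel (11 overall
tests; 5 higher-order net tests), with stars at α = 0.05/0.01/0.001/0.0001
on the Holm-adjusted p. A study-wide family is a configuration choice.

The parametric null calibration (`simulate_null_studies`) draws strain
means around an exactly multiplicative landscape with realistic s.e.m.
(0.008) and runs the full decomposition; with the s.e.m. known the Z
statistics are exact and the any-flag rate over 500 studies sits below
5%. An `estimated_sem` mode re-estimates s.e.m. from 9 simulated
replicates and shows the mild anticonservatism (~6–7%) of plugging
finite-replicate s.e.m. into a Z-test — the same caveat applies to real
N = 9 data.

## Dose–response model

w = β₀ + (β₁ + β₂ ln g)·E, unweighted OLS on strain means pooled from the
0.3% and 1% pure-galactose environments (16 + 16 points). The ln g slope
term is the simplest form that yields one line per concentration;
a slope-linear-in-g form and inverse-variance weighting are options.
`saturation_gap` reports the mean signed residual of held-out strains at
one concentration under the model's own line and under a substitute
concentration's line; evaluating the 2% environment against the 1% line
quantifies saturation. Predictions at 0.1% galactose are meaningful for
GAL2-intact strains; the permease-specific fitness term is outside the
expression-mediated model, so GAL2-halved strains can be excluded from
evaluation there via the points table.

## Wild-type comparisons

Welch two-sample two-tailed t-tests per strain against the wild type
(pooled-variance Student's test optional), Bonferroni-corrected by the
family size — default the 15 non-wild-type strains per environment per
metric; expression and fitness form separate families. Zero variance in
both groups with equal means reports t = 0, p = 1.

## Problem sizes and determinism

The default study (2,592 samples × 25,000 events) runs in well under a
minute on one core; the test suite uses scaled configurations (2–3
replicates, 1,500–5,000 events) for structural checks and the full-size
study for the recovery suite. All pipeline outputs are deterministic
given the master seed, and a study materialized to CSV event tables and
re-analyzed from disk reproduces the in-memory results bit-for-bit
(floats are serialized at 17 significant digits and parsed in
round-trip mode).

## Known limitations

- Error propagation ignores covariances induced by wild-type
  normalization and shared single-gene terms (except in the optional
  delta mode); both are small at the study's s.e.m. scale.
- The Z-test treats s.e.m. values as known; at N = 9 this is mildly
  anticonservative (quantified above).
- The generator's expression–fitness maps are smooth and noiseless at the
  population level; real biological replicate variance (day effects,
  micro-environment) would inflate s.e.m. values beyond counting noise.
- The hockey-stick regime of environment A is represented in the ground
  truth but deliberately not fitted by the dose–response module, which is
  linear by design.
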