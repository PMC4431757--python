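# Methods

## Efficiency scores: the input-oriented CCR model

Each subject is a decision-making unit converting two inputs — total
physical expenditure (METs-h/day) and the inverse of food intake
(day/kcal) — into one output, the inverse of BMI (m²/kg).  The inverses
place all three quantities on a "more is better for thinness" orientation:
efficient subjects keep BMI low (high 1/BMI) while using little of the
inputs, i.e. while exercising little and eating much.  The efficiency score
is therefore a radial measure of everything *other than* measured diet and
exercise — genetics, metabolism, unmeasured behaviour — that keeps a person
thin.

The score solves the envelopment form of the constant-returns-to-scale
Charnes–Cooper–Rhodes program, one LP per subject (variables θ and the n
peer weights λ, m+s inequality rows).  The production implementation is
the envelopment form because n ≫ m+s in cohort data and the peer weights
fall out directly; the multiplier (dual) form is implemented as a
verification oracle and must agree by strong duality (tested to 1e-6).

Numerical choices:

- **Column rescaling.** The raw inputs differ by ~5 orders of magnitude
  (≈36 METs-h/day vs ≈4.4e-4 day/kcal).  Every input/output column is
  divided by its sample mean before the solve; CCR scores are units
  invariant, so the scores are unchanged (tested to 1e-8) while the LP is
  far better conditioned.
- **Solver.** `scipy.optimize.linprog` with the HiGHS backend, feasibility
  tolerance 1e-9.
- **Reporting.** Raw θ is kept internally (`theta_raw`); the reported score
  is clipped to (0, 1] and scores within 1e-6 of 1 are reported as exactly
  efficient.  Peer (reference) sets use λ > 1e-7.  Only θ is contractual:
  the optimal λ need not be unique and is informational.
- **Degenerate input.** A single-DMU set returns θ = 1 without a solver
  call; a lone unit envelops itself.
- **Scope.** Radial θ only: no second-phase slack maximisation, no BCC /
  super-efficiency / SBM / output orientation.  For m = s = 1 the score has
  the closed form θⱼ = (yⱼ/xⱼ)/maxₖ(yₖ/xₖ), used as an independent oracle.

## Genetic predisposition score

GPS = L · Σ aₗβₗ / Σ βₗ with dosages aₗ ∈ [0, 2] (fractional dosages from
imputation are accepted) and GWAS effect sizes βₗ > 0.  The normalising
constant is the maximum attainable weighted sum (2Σβ, every locus
homozygous for the effect allele), and the 2L factor restores the
allele-count scale, so GPS ∈ [0, 2L] and equals the plain allele count when
all weights are equal.  With the reference configuration L = 29 the range
is [0, 58] and realistic panels put the mean near 26.

Missing dosages are handled by per-subject renormalisation over the
observed loci (GPS = L · Σ_obs aβ / Σ_obs β), which keeps the [0, 2L]
scale; a `missing="fail"` policy raises instead.  QC precedes scoring:
loci with MAF < 0.5% or call rate < 95% are dropped, applied to whatever
dosage matrix is supplied (pre- or post-imputation).  VCF ingestion counts
effect alleles from GT (honouring DS when present) and flips orientation
when the effect allele is the REF allele.

## Robust regression: MM estimator

The model comparison requires a high-breakdown robust fit.  No installed
Python library provides an MM estimator, so `dearisk.robust` implements
one:

1. **S-step** — fast-S search (seeded elemental subsamples, default 20,
   each refined by 2 IRLS steps; the full-data least-squares fit is always
   included as a candidate; the best 2 candidates are iterated to
   convergence) for the bisquare M-scale with c = 1.54764 and consistency
   constant b = 0.5 (50% breakdown).
2. **M-step** — IRLS with the bisquare ψ at c = 4.685 (95% asymptotic
   Gaussian efficiency), holding the S-scale fixed and starting from the
   S coefficients; the step is rejected if it worsens the M-objective, so
   the MM contract holds.
3. **Standard errors** — the standard asymptotic covariance
   s²·E[ψ²]/E[ψ′]²·(XᵀX)⁻¹ with an n/(n−p) small-sample factor; p-values by
   normal approximation, no multiple-testing correction.

The reported R² is the final-IRLS-weight weighted squared correlation
between observed and fitted values (Renaud & Victoria-Feser), which reduces
exactly to the classical R² under unit weights; the adjusted version
applies the usual (n−1)/(n−p−1) penalty.  OLS (via statsmodels) is a flag
for oracle testing: in that mode coefficients match the normal equations to
1e-10 and the adjusted R² matches the textbook formula.

Noise-free designs (S-scale 0) return the exact interpolating fit with zero
standard errors.  Rank-deficient designs raise an error naming the
collinear columns.  Listwise deletion handles missing covariates; the n
actually used is reported with every fit.

Model specifications (women = 1, men = 0; all adjusted for age and sex):
M1 sex+age+expenditure+intake; M2 sex+age+efficiency; M3 sex+age+GPS;
M4 sex+age+expenditure+intake+GPS; M5 sex+age+GPS+efficiency.  The
yearly-change outcome (follow-up BMI − baseline BMI)/interval is fitted
only on subjects with normal *baseline* BMI (18.5 ≤ BMI < 25) — the only
measure available at cohort entry — who completed follow-up.

## Synthetic cohort generator

The generator emulates the baseline survey of a Japanese cohort of adults
aged 40–84 and is the test bed for the whole pipeline.  Defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| n_subjects | 1,620 | — | reference cohort size |
| age | discrete U(40, 84) | years | reference range |
| P(woman) | 894/1620 | — | reference sex ratio |
| intake | N(2257, 673²) trunc > 300 | kcal/day | reference marginal |
| expenditure | N(36.2, 5.8²) trunc > 20 | METs-h/day | reference marginal |
| loci | L = 29, EAF linspace(0.2, 0.7), β linspace(0.05, 0.35) permuted | — | fixed panel; mean GPS ≈ 26 |
| b_sex, b_age | 0.25, 0.01 | kg/m², kg/m²/yr | small demographic effects |
| γ_gps | 0.10 | kg/m² per GPS unit | genetic effect |
| δ_intake, δ_expenditure | +0.002, −0.12 | kg/m² per unit | eat more → heavier, move more → lighter |
| σ_noise | 2.5 | kg/m² | residual scale so SD(BMI) ≈ 3.1 |
| b0 | derived | kg/m² | solves E[BMI] = 23.4 given everything above |
| BMI truncation | [15, 36] | kg/m² | observed range |
| follow-up | fraction 1079/1620, interval U(5, 7) yr, drift N(−0.02, 0.22²)/yr | — | reference follow-up design |

Genotypes are Binomial(2, pₗ) per locus — Hardy–Weinberg by construction
(verified against (1−p)², 2pq, p² at n = 10,000).  Loci are parameterised
by the *effect*-allele frequency, which (as in real GWAS panels) may exceed
0.5; the MAF used by QC is min(p, 1−p).  The panel is a fixed deterministic
function of its ranges, not redrawn per cohort seed: a study has one SNP
panel, and a fixed panel keeps the marginal calibration stable across
seeds.  The intercept b0 is derived analytically from the configured
marginal targets (closed-form truncated-normal means, exact GPS
expectation) and can be overridden.

BMI truncation is applied to BMI itself (per-subject truncated-normal
noise), which introduces a small (<0.05 kg/m²) compression relative to the
untruncated affine model; parameter-recovery tests show the induced
coefficient bias is well inside 2 robust SEs at n = 2,000.

**What the generator does not emulate:** linkage disequilibrium between
loci, population stratification, measurement error in the questionnaires,
intake–expenditure–genotype dependence, interventions between baseline and
follow-up, and age-dependent BMI trajectories.  Passing tests therefore
demonstrate the *machinery* (LP correctness, estimator calibration,
pipeline determinism) and the qualitative gene-vs-environment ordering, not
agreement with any real cohort's coefficients — which is also why the
motivating study's exact numbers (e.g. r = −0.78, adjusted R² = 0.66) are
direction/ordering targets here, not point targets.

An optional structural drift (`drift_gps`, `drift_efficiency`) lets power
studies couple the yearly BMI change to genetics or efficiency; by default
the drift is pure noise and all five change-outcome models correctly show
adjusted R² ≈ 0.

## Design choices on genuinely open points

- **Input/output orientation conflict.** The methodological source text
  describes the DEA setup twice, once listing inverse intake as an input
  and once as an output.  The explicit list (inputs = expenditure +
  inverse intake; output = inverse BMI) is implemented; with it the
  observed negative BMI–efficiency correlation arises mechanically, as in
  the motivating analysis.
- **Efficiency-quartile direction.** Expenditure is an input, so by
  dominance monotonicity higher expenditure can only lower θ; the quartile
  summary accordingly shows mean expenditure and mean inverse intake
  *decreasing* from the least to the most efficient quartile, and the tests
  assert that direction.
- **BMI category boundary.** "18.5–24.99" is read as the half-open interval
  [18.5, 25): 25.0 is overweight.
- **Quartile ties.** Rank-based assignment with a stable subject-id
  tie-break; group sizes differ by at most one.
- **Determinism.** Every stochastic component (simulator, fast-S
  subsampling) takes an explicit seed; result tables carry the seed in a
  metadata header, artifacts are written atomically (temp + rename), and
  identical seeds reproduce artifacts byte for byte.

## Problem sizes in the shipped tests

Property tests use 100–240 random LP instances (n ≤ 50); parameter
recovery uses 200 replicate cohorts of n = 2,000; marginal calibration
checks use n = 5,000 and HWE checks n = 10,000; the qualitative
model-ordering check uses one cohort of n = 1,620.  The whole suite runs in
about two minutes on one CPU.
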