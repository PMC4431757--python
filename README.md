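# dearisk

**Data envelopment analysis (DEA) for personal obesity-risk modelling.**

`dearisk` asks how efficiently an individual converts diet and exercise into
a low body-mass index, and whether that per-person *efficiency score* is a
better predictor of BMI than a weighted genetic risk score.  It is aimed at
epidemiologists and biostatisticians studying gene–environment contributions
to obesity in adult cohort data.

## The method

**Efficiency scores.** Each subject is a decision-making unit (DMU) with two
inputs — physical-activity energy expenditure (METs-h/day) and the inverse
of caloric intake (day/kcal) — and one output, the inverse of BMI (m²/kg).
The input-oriented Charnes–Cooper–Rhodes (CCR) model under constant returns
to scale solves, for each subject *o* among *n* subjects,

```
min θ   s.t.   Σⱼ λⱼ xᵢⱼ ≤ θ xᵢₒ  (each input i),
               Σⱼ λⱼ yᵣⱼ ≥ yᵣₒ  (each output r),   λ ≥ 0,
```

one linear program per subject.  θ\* ∈ (0, 1]; θ\* = 1 means the subject
lies on the empirical frontier — maximally "efficient at burning calories"
given what they eat and how much they move.  A thin person who eats a lot
and exercises little is efficient; a person with the same BMI achieved by
eating little and exercising hard is not, and the gap is the part of
adiposity the environment does *not* explain.

**Genetic predisposition score.** For L loci with GWAS effect sizes βₗ and
effect-allele dosages aₗ ∈ [0, 2],

```
GPS = [Σₗ aₗ βₗ / (2 Σₗ βₗ)] · 2L  =  L · Σₗ aₗ βₗ / Σₗ βₗ  ∈ [0, 2L],
```

the weighted allele count rescaled to the allele-count scale (58 for the
reference panel of L = 29 loci).  Loci with minor-allele frequency < 0.5%
or call rate < 95% are excluded first.

**Model comparison.** Five MM-type robust linear regressions of BMI
(baseline, or yearly change restricted to normal-baseline subjects) — M1
environment, M2 efficiency, M3 GPS, M4 environment+GPS, M5 GPS+efficiency,
all adjusted for age and sex — are compared by adjusted R².

Because no individual-level data from the motivating cohort are deposited,
the package includes a first-class synthetic cohort generator calibrated to
that study's published marginals (BMI 23.4 ± 3.1 kg/m², intake 2,257 ± 673
kcal/day, expenditure 36.2 ± 5.8 METs-h/day, GPS mean 26.1, ages 40–84,
Hardy–Weinberg genotypes).  See `docs/methods.md` for the generative model.

## Worked example

```python
import dearisk as d

cfg = d.SimConfig(n_subjects=300, seed=11)
cohort, genotypes, weights, truth = d.simulate_cohort(cfg)

results = d.CCREfficiency(d.build_dea_frame(cohort)).fit()
print(results.summary())

cohort["efficiency"] = cohort["subject_id"].map(results.scores)
corr = d.pearson_correlation(cohort.bmi_baseline, cohort.efficiency)
fits = d.model_comparison(cohort, "baseline_bmi", seed=0)
print(fits["M5"].results.summary())
```

prints

```
Input-oriented CCR efficiency (constant returns to scale)
  DMUs: 300   inputs: 2   outputs: 1
  efficient (theta = 1): 4
  mean theta: 0.6938   sd: 0.1084
  min theta: 0.4254   median: 0.6865

MM robust linear regression   n = 300   scale = 2.696   adj R2 = 0.3223
-----------------------------------------------------------------------
const                         29.6373  (se 1.8765, p 3.43e-56)
sex                          -0.3184  (se 0.3387, p 0.347)
age                          -0.0031  (se 0.0124, p 0.805)
gps                           0.1690  (se 0.0422, p 6.29e-05)
efficiency                   -14.4601  (se 1.5363, p 4.86e-21)
```

Four subjects span the frontier; everyone else scores below 1.  The M5 fit
shows the expected structure: the efficiency score carries a large negative
coefficient (more efficient ⇒ lower BMI; here r = −0.48, p ≈ 9e-19) and a
far larger share of the variance than the genetic score, while the GPS
coefficient stays positive and significant — the qualitative pattern the
method is designed to expose.  On this synthetic cohort the efficiency
models reach adjusted R² ≈ 0.27–0.32 against ≈ 0.07 for the GPS-only model.

The same pipeline runs from the shell:

```bash
dearisk all --seed 123 --n 1620 --out-dir out/
# out/: cohort_scored.csv, correlations.csv, models_baseline.csv,
#       models_change.csv, models_age_subgroups.csv, quartiles.csv, ...
```

Identical seeds give byte-identical artifacts.

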