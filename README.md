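# discnet

A tested, fully synthetic re-implementation of a preclinical analysis
pipeline for the rat **annular-puncture model of discogenic back pain**:
from raw biomechanical traces, von Frey filament responses, qPCR Ct values,
radiographic disc heights and histology subscores, down to sex-stratified
trait–trait correlation networks.

The scientific question the pipeline serves: *which measures of
intervertebral disc (IVD) degeneration travel with measures of pain, and do
males and females differ?* In the modelled study design, 48 Sprague–Dawley
rats (24/sex) receive sham surgery or L3/4–L5/6 annular puncture
(n = 12/group, two animals lost to attrition). Six weeks later every animal
carries a full panel of structural (radiographic height, histology grade),
functional (axial/torsional/creep biomechanics) and nociceptive (paw
withdrawal thresholds, DRG *Calca*/*Tac1* expression) endpoints, which are
correlated within each sex.

The package is aimed at researchers who want a reproducible, end-to-end
testable version of this analysis — with a seeded generator standing in for
animal data — and an import path (long-format CSV) for real measurements in
the same schemas.

## The models at the core

**Viscoelastic creep.** One hour of compressive creep at F = −8 N is fit
with a 5-parameter viscoelastic solid (elastic + fast + slow exponential
phases), parameterised in stiffnesses:

```
d(t) = F · [ 1/k_e + (1/k_f)(1 − e^(−t/τ_f)) + (1/k_s)(1 − e^(−t/τ_s)) ],   τ_f < τ_s
```

fit by multi-start nonlinear least squares in log-parameters. Axial
(±8 N, 1 Hz) and torsional (±10°, 1 Hz) cyclic properties are reduced from
the 20th loading cycle: end-range stiffnesses from least-squares slopes over
the outer 20% of the loading branch, range of motion / torque range from the
channel extremes, hysteresis as the shoelace loop area.

**Behavior.** The paw withdrawal threshold is the lowest filament force
(ascending 0.4–26 g set) eliciting nocifensive responses in ≥3 of 5
applications, censored at 26 g, averaged over hindpaws.

**Expression.** Relative expression is `2^−(Ct_gene − Ct_Gapdh)`; fold
change is taken against the same-sex sham mean after 1% ROUT outlier
removal (robust median/RSDR scale + FDR-style outside-in t-tests).

**Group statistics.** Two-way fixed-effects ANOVA (Type III sums of squares
on sum-to-zero contrasts) with Tukey–Kramer post-hoc tests.

**Networks.** For each sex, all traits (≈50 by default: design, weights, von
Frey raw/normalised, per-level height changes, histology subscores, 13
biomechanical properties, 12 expression fold changes, estrous stage in
females) are correlated pairwise with tie-corrected Spearman ρ on
pairwise-complete observations. Tie-free pairs are referred to the exact
permutation null of ρ (fixed-seed table); tied pairs use the
t-approximation, `t = ρ√((n−2)/(1−ρ²))`. Benjamini–Hochberg's step-up
adjustment runs once per sex network, and edges are kept at q ≤ 0.05 with
sign(ρ). Power of the correlation test is computed via the Fisher
z-transformation; at n = 24/sex the design has ≈73% power for large effects
(ρ = 0.5, α = 0.05).

## Worked example

The numbered scripts under `analysis/` run the whole study; each stage can
also be driven from the `discnet` CLI (`simulate`, `reduce`, `stats`,
`network`, `run-all`) or the library API.

```bash
$ python analysis/01_simulate_study.py
simulated 46 animals (excluded: ['F100', 'M110'])
sex     injury_group
female  injury          11
        sham            12
male    injury          11
        sham            12

$ python analysis/03_group_differences.py
injury main effect p-values:
  vf_w6                    p = 2.03e-06 ***
  height_pct_punctured     p = 1.78e-23 ***
  grade_total              p = 3.21e-28 ***
  tensile_stiffness        p = 0.168
  ...
  torsional_stiffness      p = 0.0611

$ python analysis/04_correlation_networks.py
female: 65 edges over 49 traits; injury degree 10
male: 182 edges over 48 traits; injury degree 18
edge overlap (Jaccard over shared traits): 0.323
  injury--vf_w6: male=True female=False
  injury--grade_total: male=True female=True
  injury--height_pct_punctured: male=True female=True
```

Reading the output: injury produces strong structural degeneration in both
sexes (height loss, histology grade), leaves functional biomechanics
unchanged, and lowers the week-6 withdrawal threshold. The network stage
shows the sex dissociation: the male network links injury to the von Frey
thresholds, the female network links injury only to the structural
endpoints — while both link injury to height change and degeneration grade.

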