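# Methods

This note documents the models, parameter choices and numerical decisions
behind `discnet`, in the order the pipeline runs them.

## Study design emulated by the generator

A 2×2 (sex × injury) design: 24 female and 24 male rats, 12 per
sex × surgery group, lumbar IVDs L3/4–L5/6 punctured in the injury groups.
Attrition is modelled by removing one male-injury and one female-injury
animal after generation (seeded choice), leaving 46. Measurements: von Frey
sessions at weeks 0/2/4/6 (week 0 pre-operative); radiographic heights of
L1/2–L5/6 at baseline and 6 weeks; endpoint histology (L3/4), biomechanics
(L5/6), DRG qPCR (T13–L5), estrous stage (females), body weight, and a
surgery cohort index (4 batches, round-robin).

Two per-animal latents drive the signals:

* `latent_degeneration = injury × (1 + ε)`, ε ~ N(0, 0.15) — drives
  histology subscores and punctured-level height loss;
* `latent_sensitivity` — a log paw-withdrawal threshold with sex-specific
  structure (below).

## Effect structure (generator defaults)

Defaults encode the direction and rough magnitude of the modelled study's
findings; every one sits in `EffectConfig`/`NoiseConfig` so tests can scale
or disable it.

| quantity | default | notes |
|---|---|---|
| male baseline threshold | 15 g | latent lognormal centre |
| male injury threshold drop | ÷4 from week 2 on | large, persistent allodynia |
| female baseline threshold | 10 g | |
| female injury threshold drop | ÷1 (none) | no mean effect |
| animal-level log-threshold SD | 0.15 (M), 0.60 (F) | inflated female variability, both groups |
| week / paw log SD | 0.10 / 0.08 | session and side scatter |
| response curve | logistic in log-force, slope 8 | per-application probability |
| baseline IVD height | 0.95 mm (M), 0.90 mm (F) | per level |
| height loss | 25% × latent, punctured levels only | injury effect |
| height measurement SD | 0.03 mm | X-ray tracing error |
| subscore model | clip(0.2 + 1.5·latent + N(0, 0.3)) rounded to {0,1,2} | per rater × category |
| Calca fold (male injury, L2) | ×2 | −1 Ct shift |
| Tac1 fold (male injury, L5) | ×2 | −1 Ct shift |
| Ct noise / outlier rate / shift | 0.3 cycles / 2% / ±4 cycles | outliers on target genes |
| tensile / compressive stiffness | 80 / 150 N/mm | no injury effect |
| torsional stiffness | 3.0 (M) / 2.4 (F) N·mm/deg | sex effect, males greater |
| creep parameters | k_e=100, k_f=50, k_s=25 N/mm; τ_f=10 s, τ_s=600 s | no injury effect |
| biomech between-animal CV | 5% lognormal | all properties |

The injury assignment of thresholds uses a step at week 2 (weeks ≥ 2 get
the full drop), matching a post-surgical onset. Estrous stage is uniform
over the four stages and independent of everything else, consistent with
the modelled study's negative finding. Surgery cohort is metadata only — no
cohort effect is injected.

## Raw-signal models

**Creep.** `d(t) = F·[1/k_e + (1/k_f)(1−e^(−t/τ_f)) + (1/k_s)(1−e^(−t/τ_s))]`
sampled at 1 Hz for 3600 s at F = −8 N, plus Gaussian noise (default SD
0.005 mm ≈ 1% of the ≈0.56 mm total displacement).

**Cyclic loops.** The controlled channel is a sinusoid (force ±8 N axial,
rotation ±10° torsional; 20 cycles at 1 Hz, 100 Hz sampling → 2000 samples
per channel). The passive channel follows the branch stiffnesses
(tension/compression for axial). Loop area is inserted by one of two shapes:

* `bump` (default): a quartic opening `w(u) = w0(1−u²)²` confined to the
  central 80% of the controlled range, subtracted on the loading branch and
  added on unloading. `w` and `w'` vanish at ±80%, so the outer-20% windows
  used for stiffness extraction are *exactly* linear and the enclosed area
  has the closed form `2∫w = 32·w0·c/15`. This makes the zero-noise
  generate→reduce round trip exact, which the validation suite exploits.
* `ellipse`: the classical elliptic phase lag (`+δ·cos ωt` on the passive
  channel, area πδ·amplitude). Physically the more familiar picture, but it
  perturbs the end-range slope at first order in the area, so it is kept as
  an option rather than the default.

A decaying transient over the first cycles is available
(`transient_amplitude`, default 0, settled well before cycle 20).

**Filament responses.** Per application, response probability is logistic
in log force centred on the paw's latent threshold; counts are
Binomial(5, p) per filament. An infinite slope gives the deterministic
step-function limit, which is also what the all-zero noise configuration
uses.

## Reductions

**Cycle extraction.** Cycle *c* of a nominal-frequency trace is the window
[(c−1)/f, c/f) from the first sample; properties use cycle 20.

**End-range stiffness.** Least-squares slope of conjugate on primary over
the loading-branch samples in the outer 20% of the relevant extreme
(`F ≥ 0.8·Fmax` for tension, mirrored for compression; outer 20% of each
rotation extreme for torsion, averaged over directions). Loading branch =
samples whose controlled channel moves toward that extreme (sign of the
numerical derivative). The 20% window is a convention (configurable
`fit_window_fraction`); the cited prior tooling for this style of reduction
does not publish formulas. Fewer than 3 samples in a window is an error.

**Hysteresis.** Shoelace area of the (virtually closed) sampled loop,
orientation-independent. Discretisation error is O(N⁻²): ≈0.07% at 100
samples/cycle, ≈7×10⁻⁶ at 1000.

**Creep fit.** Nonlinear least squares in log-parameters
(positivity by construction), Levenberg–Marquardt, multi-start over
(τ_f, τ_s) ∈ {(2,100), (10,600), (50,3000)} s plus a data-driven stiffness
start (elastic from the first sample, the remaining compliance split
evenly). The best-RMSE solution is relabelled so τ_f < τ_s.
`total_displacement` is |model| at the last sample and *includes* the
instantaneous elastic jump (documented choice; the alternative — creep-only
displacement — would subtract F/k_e). A fit failing from every start
returns NaN parameters with `converged=False`, which downstream code
propagates as missing traits rather than an exception. With τ_s far beyond
the test duration the slow branch is weakly identified; the fit still
returns, with honesty left to the RMSE/converged flags.

**Thresholds.** Lowest filament with ≥3/5 responses; non-responders
censored at 26 g; left/right averaged; normalised threshold is the *ratio*
to the week-0 value (the alternative reading — a difference — is rejected
because ratios keep the trait positive and scale-free).

**Heights.** Disc height from two traced borders is the symmetrised mean
point-to-polyline distance (100 evenly spaced arclength samples per border,
configurable). Percent change per level is 100·(h6−h0)/h0; the
punctured-level summary is the percent change *of the mean* across
L3/4–L5/6, not the mean of per-level changes.

**Expression.** 2^−ΔCt against Gapdh; ROUT outlier flags within each
sex × injury × gene × level group (constant model: median centre, RSDR =
68.27th percentile of |residuals| × n/(n−1), outside-in t-tests with
df = n−1 against the step-up thresholds i·Q/n, at most 30% flagged, groups
under 4 skipped). Flagged values keep their record but contribute neither
to the sham reference mean nor a fold-change trait. Fold change is against
the same-sex sham mean for the same gene and level.

**Histology.** Per-category mean over the three raters, total grade = sum
of the five category means (0–10).

## Group statistics

Two-way fixed-effects ANOVA with interaction, Type III sums of squares on
sum-to-zero contrasts (statsmodels OLS + anova_lm; Type II available). Type
III is the convention of the commercial statistics packages common in this
field and behaves sensibly for the mildly unbalanced n = 11–12 cells
attrition produces. The von Frey week factor is treated as crossed (not
repeated-measures), matching the modelled design's stated analysis.
Tukey–Kramer adjusted p-values come from the studentized-range distribution
with `q = |mᵢ−mⱼ|/√(MSE/2·(1/nᵢ+1/nⱼ))`.

## Correlation networks

One trait table per sex (one row per animal, ~50 columns; estrous stage,
ordinally coded proestrus→estrus→metestrus→diestrus = 0..3, only in the
female table; injury coded 0/1 and correlated like any other trait).
Missing values stay missing — correlations use pairwise-complete
observations, pairs with fewer than 4 complete pairs (configurable) are
untested and excluded from the FDR family.

p-values follow the convention of R's `cor.test`, the reference tool for
this analysis style: tie-free pairs are referred to the exact permutation
null of ρ, realised as a fixed-seed 10⁶-draw sorted table per sample size
(deterministic across runs; add-one correction keeps p > 0); tied pairs use
the t-approximation with df = n−2. The plain t-approximation is available
via `p_method="t"` but is anti-conservative around p ≈ 10⁻⁴ at n ≈ 24 —
exactly where the BH step-up threshold for the smallest of ~10³ pair
p-values sits — and measurably inflates the null network's false-discovery
rate (≈0.09 vs the nominal 0.05; the permutation null restores ≈0.04).

BH adjustment is applied once across all testable pairs within one sex
(families are not pooled across sexes); edges require q ≤ 0.05. Network
comparison reports shared/unique edges over the shared trait set, per-node
degrees, a Jaccard index, and presence flags for named edges of interest
(injury–week-6 threshold, injury–grade, injury–height).

**Power.** Two-sided correlation test power via Fisher z with the usual
bias term r/(2(n−1)) and the critical correlation from the t quantile;
both rejection regions are summed so the null limit is exactly α. At
n = 24, ρ = 0.5, α = 0.05 this gives 0.726.

## Validation suite (problem sizes)

The validation routines (`discnet.validation`, also driven by
`scripts/acceptance.py`) use: 20 replicate creep fits at 1% noise; a
zero-noise round-trip study at 1000 samples/cycle; 50 null studies of 30
independent Gaussian traits at n = 24 for FDR control; 100 random p-vectors
against a brute-force BH oracle; and 20 replicate full default studies for
the sex-dissociation edge rates. These sizes give stable rates while
keeping a full run to a couple of minutes.

## What the generator does and does not emulate

It emulates the design's group structure, effect directions and plausible
magnitudes, measurement noise, attrition, censoring, and expression
outliers. It does **not** emulate: images of any kind (radiographs are
reduced to heights, histology to subscores — the border-tracing geometry is
exercised only through `ivd_height_from_borders`); cohort/batch effects
(surgery date is inert metadata); estrous dependence of any trait;
within-day or circadian structure; correlated noise across endpoints beyond
what the two latents induce; or pharmacology of the inflammatory injection.
Passing tests therefore demonstrate that the *pipeline* recovers known
structure from signals of this shape — not that real tissue behaves like
the generator.

## Known limitations

* The third torsional output (`torsional_hysteresis`) is the loop area; if
  a user's convention for the third torsional panel differs (e.g.
  normalised energy), it must be post-processed.
* The trait dictionary is a documented default (~50 traits), not a claim to
  reproduce any particular published variable count; it accepts extensions.
* ROUT here is the published robust-FDR outlier procedure on a constant
  model; proprietary implementations may differ in small-sample details.
* The permutation-null p-value table is shared per sample size and capped
  at n ≤ 64; larger tables fall back to the t-approximation, which is
  adequate at those sizes.
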