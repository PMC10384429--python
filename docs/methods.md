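# Methods

This note documents the models, conventions and design choices behind
`lycosense`, in the order the pipeline runs.

## Color conventions

All conversions assume an sRGB camera (the actual device profile of such
low-cost sensors is rarely characterized; sRGB is the consumer default).
HSV components are unit-scaled to [0, 1] — the hue thresholds the
segmentation stage uses are stated on that scale — and CIE-L\*a\*b\* is
computed for the D65 illuminant, 2° observer, via scikit-image. 16-bit
inputs are rescaled to 8-bit on load; grayscale inputs are replicated to
three channels.

## Segmentation

A pixel is fruit iff its hue lies *outside* the background band
[0.466, 0.842] and its saturation/value lie inside their configured ranges
(full [0, 1] by default, i.e. no-ops kept configurable so near-black shadow
pixels can be excluded). The band covers cyan through magenta and contains
no tomato hue: green fruit (H ≈ 0.33) and red fruit (H ≈ 0 or ≈ 1) both
survive, which is the property that fixes the interpretation of the band as
background rather than foreground. Connected components smaller than 400 px
are then removed — the rule is strictly "smaller than", so a 400-px blob is
kept. Component labeling uses 8-connectivity by default (standard for blob
filtering; 4-connectivity is available). The filter is idempotent and
anti-extensive, and its areas are tested against an exhaustive flood-fill
oracle.

## Color features

"Red/green/blue pixel areas" are realized as dominant-channel counts: a
pixel is RED if its R channel exceeds both G and B by a margin δ = 10
(configurable), etc., and unclassified otherwise. The margin suppresses
near-achromatic pixels flapping between classes.

The fuzzy engine's input domains — L ∈ (0, 2558.3], a ∈ (0, 1736],
b ∈ (−210, 358] — are not standard L\*a\*b\* ranges, and no unique mapping
from image statistics into them exists. The package therefore isolates the
choice behind one explicit affine seam (`FeatureScaling`): by default the
masked-pixel means are mapped L\* ∈ [0,100] → [0, 2558.3],
a\* ∈ [−128,127] → [0, 1736], b\* ∈ [−128,127] → [−210, 358]. Identity
scaling is available, and the synthetic feature generator emits values
directly in fuzzy-domain units so the engine is testable independently of
this choice. Areas are raw pixel counts (not normalized by fruit size);
callers can normalize downstream.

## The Takagi–Sugeno estimator

Three linguistic variables with 8 triangular membership functions:

| variable | MF | feet/peak | notes |
|---|---|---|---|
| L | Low | shoulder, 1 at 0 → 0 at 1285 | |
| L | Medium | 10.7 / 1285 / 2558.3 | triangle |
| L | High | shoulder, 0 at 1285 → 1 at 2558.3 | |
| a | Low | shoulder, 1 at 0 → 0 at 753 | (753 − a)/753 |
| a | Medium | 0 / 753 / 1736 | a/753 rising, (1736 − a)/983 falling |
| a | High | shoulder, 0 at 753 → 1 at 1736 | (a − 753)/983 |
| b | Low | shoulder, (358 − b)/148, clipped to 1 below 210 | |
| b | High | shoulder, (b − 210)/148 | |

Degrees are always clipped to [0, 1]; values outside a variable's domain get
degree 0. The a-variable breakpoints make Low+Medium and Medium+High exact
partitions of unity on (0, 753] and (753, 1736], as do Low_b+High_b on
[210, 358]; the tests assert these identities to 1e-12. The L-variable
slopes are derived from the breakpoints (feet 10.7 / peak 1285 / foot
2558.3); the Medium/High pair is therefore consistent with the Low/Medium/
High pattern of the a variable but does not form an exact partition, which
is why only the a and b identities are asserted.

The rule base is the full 3×3×2 antecedent grid — 18 rules — with product
t-norm by default (min available). Consequents are first-order by default
(Z_i = p_i·x + r_i; zero-order constants by config). Defuzzification is the
weighted average Σw_iZ_i / Σw_i; an input firing no rule raises an explicit
`RuleCoverageError` rather than returning NaN.

**Fitting.** With fixed premises the output is linear in the 18×4 = 72
consequent parameters, so fitting is one least-squares solve on the design
matrix whose row j concatenates w̄_ij·[x_j, 1] over rules (w̄ = normalized
firing strengths). `numpy.linalg.lstsq` returns the minimum-norm solution;
the tensor-product structure of the rule grid plus the partition-of-unity
identities make the design rank-deficient in general (a logged warning, not
an error) — predictions are unique on the fitted surface even where
individual coefficients are not. Samples firing no rule are rejected with a
warning. An optional premise-tuning pass (`fit_anfis(learn_premises=True)`,
default 10 epochs) performs accepted-only coordinate descent on MF
breakpoints with the consequent solve re-run per candidate; candidates that
reduce rule coverage are rejected. It is off by default because the
estimator's premises are fixed by formula.

## Baselines

**LR** — ordinary least squares of ppm on the a/b chromaticity ratio.

**MNNR** — a feed-forward net with 10 sigmoid hidden units and a linear
output, trained by Levenberg–Marquardt (damped Gauss–Newton, analytic
Jacobian). Inputs and target are z-scored internally; weights initialize
uniform [−0.5, 0.5] from the seeded generator, making training
bit-reproducible. One epoch is one accepted LM step; λ starts at 1e-3,
×10 on rejection, ÷10 on acceptance, and a step is accepted only if it
lowers the MSE, so the accepted-loss trace is non-increasing by
construction. Because the output layer is linear in its weights, each
candidate step is followed by an exact least-squares re-solve of the output
layer (the separable / variable-projection refinement); without it,
convergence within a 10-epoch budget from uniform random initialization is
unreliable, with it the trainer reaches ~1e-7 MSE on noiseless linear
targets for every seed tested. Epoch budget 10 by default.

## Evaluation

The headline "R²" is the **squared Pearson correlation** between observed
and predicted ppm (affine-invariant, bounded by 1); the coefficient of
determination 1 − SSE/SST is reported alongside. "Error mean" is the signed
mean residual mean(pred − obs). Metrics are computed on the training set by
default — the calibration protocol of a small-sample sensor study —
with optional leave-one-out cross-validation, which is the honest
generalization measure at n = 18.

## Synthetic study generator

The generator emulates the bench conditions: one fruit per frame on a
uniform blue backdrop (hue 0.65, inside the background band), default frame
768×1366, class design 5 G / 3 T / 3 P / 2 LR / 5 R (18 fruits). A fruit is
an ellipse (semi-axes ~0.28–0.34 of frame height, 0.20–0.26 of width) whose
pixels draw a red base color (185, 40, 35) with class-specific probability
(G 0.02, T 0.30, P 0.55, LR 0.75, R 0.95) and a green base (70, 150, 60)
otherwise, plus Gaussian jitter (sd 8). The two-base mixture is what makes
the red-pixel fraction r grade smoothly across maturity classes, as on a
real part-ripe epicarp. Up to 6 fruit-hued speckles (radius ≤ 10 px, hence
area < 400 px) are scattered clear of the fruit to exercise the blob filter;
they are *not* part of the emitted true mask.

Ground truth follows `ppm = 90 · r^1.5 + N(0, 2)`, truncated at 0, anchored
to the ~0–90 ppm HPLC scale of real assays. λ_max = 90, γ = 1.5 and the
2-ppm noise are configurable and are synthetic stand-ins chosen to
reproduce the qualitative behavior of real data (lycopene rising with red
and falling with green pixel area), not measured values. The feature-table
generator (`generate_feature_table`) bypasses imaging, sampling (L, a, b)
uniformly over the fuzzy domains with a smooth default surface
`90 · (a/1736)^1.5 · (0.6 + 0.4·(b + 210)/568)`; a custom law (e.g. a
planted Takagi–Sugeno model) is used verbatim, without truncation.

**What passing tests show — and don't.** The generator's images have flat
backdrops, no shading, no specular highlights, no touching fruit and no
hue overlap between fruit and backdrop, so segmentation recovery at
Jaccard ≈ 1 is a correctness check of the thresholding/filtering logic,
not a field-accuracy claim. Likewise the fuzzy model's training R² = 1 on
18 samples reflects 72 parameters interpolating 18 points; it validates
the ANFIS algebra, not predictive skill on real fruit.

## Numerical choices and degenerate inputs

- Membership evaluation clips to [0, 1]; domain bounds are open below,
  closed above.
- Σw = 0 at predict time is an explicit error; at fit time such samples are
  dropped with a warning.
- The a/b ratio is undefined at b = 0 (explicit `ZeroDivisionError`).
- Negative model outputs are clamped to 0 ppm at the pipeline boundary
  (concentration cannot be negative); the raw value is kept in the record.
- All model serialization is JSON with exact float round-trip.
- Problem sizes in tests and the acceptance script: 10⁴-point grids for the
  membership identities, 100 samples for consequent recovery, the full
  18-image study at 768×1366 for the end-to-end run — sizes at which every
  check is exact or statistically stable.

## Known limitations

- The mapping from image statistics to the fuzzy input domains is a
  documented convention, not a calibrated one; real deployments must fit
  `FeatureScaling` (or the rule consequents) against reference assays.
- The default fuzzy rule base covers only (L, a, b); models on other input
  sets (RGB areas, a/b alone) require user-supplied membership breakpoints.
- With 72 consequent parameters and small calibration sets the fitted
  surface interpolates; use leave-one-out scores for honest accuracy
  estimates, and zero-order consequents when data are scarce.
- Single-fruit scenes only; no illumination correction, multi-fruit
  separation, or optical-filter fusion.
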