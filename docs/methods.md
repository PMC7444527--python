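# Methods

This note documents the statistical model behind `labelbias`, the design
choices that were genuinely open, the synthetic generator's assumptions,
and the numerical conventions used throughout. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Rating-task SDT model

Responses are 7-point certainty ratings R ∈ {−3,…,+3} about whether two
face photographs show the same person. The analysis assumes the
equal-variance Gaussian observer: latent similarity evidence is
N(d′, 1) for mated pairs and N(0, 1) for non-mated pairs, and an observer
reports a rating according to where the evidence falls among six ordered
category boundaries. Binarizing at a sliding threshold θ (decision "same"
iff R > θ) yields one operating point per threshold. Thresholds live at the
scale mid-points (−2.5 … +2.5) and are required to be non-integral so a tie
with an integer rating is impossible by construction (strict inequality in
the rate definitions is therefore unambiguous).

At a single threshold, sensitivity and criterion are
d′ = z(TPR) − z(FPR) and c = −(z(TPR) + z(FPR))/2. The criterion formula is
the standard equal-variance one; it is validated against the published
pooled-rate table it is meant to reproduce (see
`tests/test_acceptance.py`). Both quantities are undefined when either rate
touches 0 or 1; the package's default follows the pooled-rates route
(rates aggregated over volunteers within a condition) precisely because
individual volunteers with 6 mated + 6 non-mated items routinely produce
boundary rates. Per-volunteer SDT is available behind a flag and uses the
log-linear correction (x + 0.5)/(n + 1).

### ROC and Az

The Gaussian model implies a linear relationship between z(TPR) and
z(FPR). We fit z(TPR) = I + S·z(FPR) by unweighted ordinary least squares
over the non-degenerate operating points (points with a rate at 0 or 1 are
dropped, not corrected — correction would distort interior points the fit
also uses) and report Az = Φ(I/√(1+S²)). Regression direction (z(TPR) on
z(FPR)) and the unweighted fit are deliberate: they match the conventional
presentation of rating-task ROC fits, and no errors-in-variables fit is
attempted. A non-positive fitted slope is flagged as an improper ROC
(warning + flag) rather than an error. The "overall" ROC is fitted to data
collapsed across all conditions, control included (configurable).

A consequence worth knowing: operating points from one rating data set are
*cumulative* counts and therefore positively correlated across thresholds.
The sampling standard deviation of the fitted Az is ~0.008–0.011 at
120–223 raters × 12 items (measured in `labelbias.experiments` and
cross-checked against a cumulative-multinomial oracle in development), i.e.
noticeably larger than if the six points were independent. The neutrality
experiment's median maximum pairwise Az gap across common-d′ conditions is
~0.013 at these sizes; individual replicates exceed 0.02 regularly even
though the conditions share a single true ROC. Az comparisons at this scale
are honest only as medians over replicates or with explicit uncertainty.

## Screening

Celebrity catch pairs exist to detect non-compliance, not to measure
discrimination. The default correctness rule is: the rating's sign must
match the ground truth and express at least "somewhat certain"
(|R| ≥ 1); "not sure" (0) counts as a failure because these pairs are
chosen to be easy — an unsure answer signals a perception or compliance
problem. The rule is configurable (`CatchRule(fail_on_unsure=False)`
accepts unsure answers). Exclusion is volunteer-level and idempotent, and
catch responses never enter any analysis table. Volunteers with no catch
trials cannot be screened; they are retained and reported in a warnings
channel.

## Inference layer

* **Bootstrap.** Percentile intervals at 95%, B = 2000 by default,
  resampling volunteers with replacement (a volunteer's responses move as a
  block) stratified by survey variant so per-condition sample sizes are
  preserved. Replicates on which a statistic is undefined (e.g. a resample
  drives a pooled rate to 0/1) are dropped; more than 50% failures is an
  error. B and the stratification are package choices made for stable
  intervals at n ≈ 100–240 volunteers per condition.
* **Per-item tests.** The told-same and told-different rating samples for
  an item come from disjoint volunteer groups (version counterbalancing),
  so the primary test is the two-sample Mann–Whitney with mid-ranks:
  exact permutation enumeration when both samples have ≤ 8 observations
  (exact even under ties), otherwise the tie-corrected normal approximation
  without continuity correction. A Wilcoxon signed-rank variant is provided
  for genuinely paired inputs. Per-item p-values are reported unadjusted
  (matching the headline significance flags); a Holm-adjusted column is
  emitted alongside for readers who want family-wise control.
* **Item shift.** Per item, the difference of mean ratings under the two
  labels; across items, a one-sample two-sided t test of the differences
  against zero with items − 1 degrees of freedom. Zero variance with a
  non-zero mean is reported as an infinite statistic with a degenerate
  flag rather than an exception.
* **χ².** Pearson statistic without continuity correction, expected counts
  from the margins; zero margins are named errors.
* **ANOVA.** One-way fixed effects on per-volunteer proportions
  (ACC/TPR/FPR at the headline threshold), computed on raw proportions —
  no arcsine/logit transform, matching how such rates are conventionally
  analysed in this literature. The label (within-subject) effect uses the
  split-plot layout with weighted-means sums of squares; with every subject
  observed at both within levels the cell frequencies are proportional, so
  the decomposition is exactly orthogonal even with unequal group sizes.
  Two layouts are exposed because both are defensible for the nested
  design: subjects pooled across sourced variants (F with N−1 error df for
  the two-level within factor) and the full split-plot with source as the
  between factor. The two-level within factor makes sphericity corrections
  moot, and none are applied.

## Synthetic generator

The generator emulates the survey design — three variants, two
counterbalanced versions, 6 mated + 6 non-mated experimental pairs, 2
celebrity catch pairs, ~120 volunteers per variant — under the same SDT
model the analysis assumes:

| parameter | default | meaning |
| --- | --- | --- |
| `mu_dprime` | 1.4 | population mean sensitivity (z-units); the ballpark for unfamiliar-face matching on deliberately hard pairs |
| `sigma_dprime` | 0.3 | between-rater sd of d′, truncated at 0 (screened population) |
| `boundary_spacing` | 0.5 | latent units between adjacent category boundaries |
| boundaries | symmetric | six boundaries centred on mu_dprime/2 (override with `boundaries` or `boundaries_for_criterion`) |
| `delta` | 0.22 | label-induced rigid boundary shift; told-same moves all boundaries by −δ/2, told-different by +δ/2 |
| `catch_separation` | 6.0 | latent separation of celebrity pairs; compliant raters pass screening essentially always |
| `catch_fail_rate` | 0.0 | fraction of volunteers planted with one wrong-direction catch response |

The shift is applied to the boundaries rather than to the evidence — the
two are mathematically equivalent, but shifting boundaries keeps d′
manifestly untouched, which is exactly the hypothesis the generator is
meant to realise. `delta = 0.22` is calibrated to the criterion gap the
pooled analysis should detect between the two label conditions (a
criterion-gap scale, not a value printed anywhere). The spacing 0.5 was
chosen once so that study-sized samples use the full scale with
extreme-threshold rates around 0.03–0.97; it is the single most
consequential free choice, since wider spacing pushes the extreme operating
points into noisier z-space territory.

With heterogeneous raters the *pooled* rates are a mixture: pooled TPR is
E[Φ(d′_v − t)] = Φ((μ − t)/√(1+σ²)) at latent cut t, while pooled FPR is
exactly Φ(−t). Pooled d′ therefore targets (μ − t)/√(1+σ²) + t ≈ 1.38 at
the defaults rather than μ = 1.4, and the recovered criterion gap is
≈ 0.98·δ. The recovery tests assert the stated bands with this mild
attenuation inside them.

What the generator does **not** model: item-level difficulty heterogeneity
by default (the analysis pools items; per-item variation in the study's
stimuli is visible in its per-item tests but has no generative counterpart
here), demographic effects on performance (profiles are drawn exchangeably;
only trust-question proportions differ by variant), sequence/order effects,
and any unequal-variance or dual-process evidence structure. Passing tests
therefore validate the pipeline's arithmetic and its behaviour under the
stated SDT model — they do not certify the model against real raters.

## Determinism and numerics

One integer seed drives everything: `SimConfig.seed` spawns independent
child streams for rater draws, response draws, and profiles, so
(config → CSV) is byte-identical; `AnalysisConfig.seed` spawns one child
per bootstrap cell in a fixed order, so an entire rendered report directory
is byte-identical across runs. Presentation tables round half-even at two
decimals (via `decimal.Decimal` on the shortest float repr, so 0.0458 →
"0.05" without binary-representation surprises); full-precision CSVs
(`%.17g`) and JSON (15 significant digits) are the canonical outputs.

Problem sizes used by the shipped simulation studies — 120–223 raters per
condition, 12 items, 20–40 replicates for the neutrality study, 250
replications × B = 320 for the bootstrap-coverage check, 30 replicates for
parameter recovery — are the package's desk-scale defaults; they keep every
study a few minutes at most while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

* Pooled-rate SDT treats volunteers as exchangeable within a condition;
  between-rater spread attenuates pooled d′ (see above) and is not
  corrected for.
* The z-space OLS ignores the correlation and heteroscedasticity of the
  cumulative operating points; Az point estimates are fine, but its
  single-replicate comparisons are noisy (quantified above).
* The exact rank-test path enumerates C(n₁+n₂, n₁) assignments and is
  limited to 8+8 observations; beyond that the tie-corrected normal
  approximation is used.
* The mixed ANOVA supports one between factor and one complete within
  factor — the survey's design — and nothing more general.
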