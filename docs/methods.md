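# Methods

## Scope and model

The package analyzes three-task reader studies of synthetic WCE imagery
and provides the latent-space operations of an attribute-controlled
generator. Generator *training* is out of scope: the latent toolkit
operates on affine style maps `(A, b)` supplied by the user or planted by
the toy generator, and the feature extractor behind the Fréchet distance
is a pluggable preprocessing step (any map from images to vectors).

## Detection tests (visual Turing task)

Correct-judgment counts are tested against H₀: p = 0.5.

* **Default method `exact_binomial`.** Two-sided p = `min(1, 2·single
  tail)` of Binomial(n, 0.5). Doubling one tail is exact here because the
  null is symmetric. The published worked examples for unambiguous counts
  round to this test's values, not to the plain z statistic, so it is the
  default; `z_no_continuity` (2·Φ(−|p̂−0.5|/√(0.25/n))) is provided and
  the method is recorded in every `TestResult`.
* **Interval.** Wald with z = 1.96, unclipped. Display rounding is
  half-up to 2 decimals and happens only at report rendering; stored
  values keep full precision.
* The pooled row sums (k, n) across raters; no multiple-testing
  correction is applied across raters.

## Krippendorff's alpha

`α = 1 − D_o/D_e` from the coincidence matrix: each item with `m_u ≥ 2`
ratings contributes its ordered rating pairs with weight `1/(m_u − 1)`;
items with fewer ratings are dropped. Difference functions: nominal 0/1,
interval `(c−k)²`, ordinal squared between-category marginal mass. This
item-weighted form tolerates missing data, which the unequal per-rater
image counts require. Degenerate cases: no pairable item raises an
undefined-alpha error; zero expected disagreement (all ratings identical)
returns 1.0 with a warning. Judged labels use the nominal level;
difficulty ratings, when analyzed, use ordinal. Pairwise matrices default
to the block of images common to all raters so entries are comparable.

## Ranking percentages

Per-rater percentages are computed per set and averaged across raters
*unweighted* (the arithmetic used in the published tables, where every
rater ranked 37 sets); with unequal set counts the per-rater percentages
are still averaged, not pooled. Ties are rejected as malformed — the
response format is a forced ranking. Null values are exact by
enumeration: 1/2 for a generate ranking first, 1/6 for both generates on
top.

## Severity slopes and rolling curves

Severities are coded 1–4 and positions as 1-based consecutive integers;
the OLS slope is multiplied by 100. This coding is the package's
convention: published per-rater slope values in the 26–46 range are
consistent with per-position increments of 0.26–0.46 on the 4-level
scale. The slope is invariant to adding a constant to all scores and
scales linearly with the scores. Rolling curves use a trailing mean
(window default 5) with partial leading windows, so curves start at the
first sequence; a window longer than the series degrades to the running
full-series mean with a warning.

## Rater simulator

The simulator's defaults are the study layout: 100 Turing images per
rater of which the first 50 form the common block, 37 ranking sets, 22
progressions of 5 images, 8-rater default panel. Response model choices
were made for analytic tractability, not realism of mechanism:

* **Turing.** Correct with probability `sigmoid(logit(skill) +
  loading·tell)`, tell ~ N(0,1) shared per image. At `loading = 0` the
  marginal is exactly `skill` and raters are conditionally independent
  (pairwise α → 0); increasing the loading raises agreement
  monotonically. True labels are balanced 50/50 per rater (odd counts:
  generated gets the extra).
* **Difficulty.** Rounded, clipped draw from N(6 − 5·|2·skill − 1|, 1):
  the rating mean decreases with the rater's distance from chance.
* **Ranking.** Perceived realism = `realism_bias_real·is_real + N(0,1)`.
  Zero bias makes labels exchangeable, giving the exact 1/2 and 1/6
  nulls; large bias is a dominance limit.
* **Progression.** Latent severity `trend·position + bias + noise`,
  binned at thresholds (1.5, 2.5, 3.5). With unit trend and no noise this
  yields [1,2,3,4,4] — a 4-level scale over 5 images necessarily repeats
  one level. The default plausibility tendency (0, .08, .30, .45, .17)
  has mean ≈ 3.7 with no "very unlikely" mass, mirroring the study-level
  profile.
* **Streams.** One global seed; per-task, per-rater substreams via
  `SeedSequence` spawn keys, so appending raters never perturbs existing
  raters' responses.

What the simulator does **not** emulate: image content (judgments are
label flips, not perception of pixels), viewing time, screen conditions,
learning effects across trials, and missing responses beyond the
common-block structure. Passing parameter-recovery tests therefore shows
the *analysis* code is correct under the stated response model, not that
real experts behave like the model.

## Latent toolkit numerics

* **Factorization.** Eigen-decomposition of `M = Σ AᵢᵀAᵢ` (multi-layer
  maps combine by stacking rows). Sign convention: each direction's
  largest-magnitude component is made positive, so walk orientations are
  reproducible. Eigenvalues are clamped at 0 against floating-point
  residue.
* **Walks.** `wᵢ = w_base − αᵢ·a`, α from `lo` in steps of `alpha_step`
  up to and including every value ≤ `hi` (a zero-length interval yields
  the single base code). Reversing a walk is the caller's negation of
  `a`. Default step 2, intervals within [0, 50].
* **Fréchet distance.** The cross term uses
  `Tr √(Σ_p^{1/2} Σ_q Σ_p^{1/2})` — a symmetric PSD reformulation —
  computed by eigen-decomposition with eigenvalues clamped at 0;
  covariances failing PSD beyond 1e−6 are rejected, and a numerically
  negative total is clamped to 0 (warning beyond tolerance).
* **Prototype labeling.** An attribute is pathology-relevant iff any
  walk sample lies within Euclidean radius of any prototype in the
  *injected* embedding (the package does not compute t-SNE; identity
  embedding of 2-D points is the test fixture).
* **Planted generator.** `A = U·diag(spectrum)·Vᵀ` with seeded
  orthonormal factors (QR with sign fixing for determinism); the
  rasterizer draws a disk whose radius, intensity and ring texture are
  monotone (sigmoid) in the first three style coordinates, so walks along
  planted directions are visibly monotone image sequences.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks use 10 000 trials for binomial/ranking nulls and
agreement nulls (assertions at 3 standard errors), 2000 simulated chance
raters at n = 100 for type-I calibration (compared to the exact test's
attainable size ≈ 0.0352 at n = 100, not nominal 0.05, since the discrete
test cannot reject at exactly 5%), and exhaustive enumeration for small
binary alpha matrices and ranking label placements. Exact arithmetic
identities (slopes, closed-form Fréchet values, the −0.75 hand case) are
asserted to 1e−12 or machine-level `approx`.

## Known limitations

* Wald intervals are used for comparability with the published tables;
  they can extend outside [0, 1] at extreme p̂ and are not recommended
  for very small n.
* Alpha has no bootstrap CI here; values from ~50-item blocks carry
  substantial sampling noise.
* The ×100 slope scale and the severity thresholds are conventions;
  comparisons across studies require the same coding.
* The exact binomial p-value uses tail doubling; other two-sided
  definitions (minimum-likelihood) differ for asymmetric nulls, which do
  not arise here.
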