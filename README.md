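# capsule-eval

Evaluation statistics and latent-space tooling for studies of **synthetic
wireless capsule endoscopy (WCE) images**.

## The problem

Generative models (style-based GANs) can synthesize WCE frames realistic
enough to build training atlases and simulated disease progressions. But
"realistic enough" is a claim about expert perception, and it is tested
with reader studies: panels of gastroenterologists judge images as real
or generated, rank mixed image sets by realism, and grade the severity of
synthetic progression sequences. This package implements the complete
statistical machinery for such studies — plus the latent-space operations
used to *produce* attribute-controlled images — for researchers running
or re-analyzing subjective evaluations of generative medical imaging.

## What it computes

**Visual Turing test** (`turing_stats`). Each rater's correct-judgment
count `k` of `n` is tested against chance: H₀: p = 0.5. The default test
is the exact binomial with two-sided p-value `min(1, 2·tail)` (valid by
the symmetry of the 0.5 null); a plain one-proportion z-test is also
available. Confidence intervals are Wald: `p̂ ± 1.96·√(p̂(1−p̂)/n)`.
Difficulty ratings (1 very difficult … 5 very easy) are summarized
overall, per rater, and per generate category (vascular, anatomical,
debris, abnormal); consensus errors — images misjudged by a supermajority
of raters — are mined directly.

**Inter-rater agreement** (`agreement`). Krippendorff's
`α = 1 − D_o/D_e` in the coincidence-matrix formulation with nominal,
ordinal and interval difference functions, tolerating missing data by
item weighting `1/(m_u − 1)` — necessary because raters judge unequal
image counts. Pairwise α matrices are computed over the block of images
common to all raters.

**Realism ranking** (`ranking_stats`). For 4-image sets (2 real, 2
generated) ranked by decreasing realness: the percentage of sets where a
generate ranks first (null 50%) and where both generates occupy the top
two ranks (null 1/6, by enumeration of the C(4,2) = 6 label placements).

**Disease progression** (`progression_stats`). Monotonicity of perceived
severity (1 normal … 4 severe) along each sequence, measured as the OLS
slope of score vs image position (×100 scale; the ideal 5-image pattern
[1,2,3,4,4] scores 80.0); plausibility summaries on the 5-point Likert
scale; trailing rolling-mean curves per image position that expose
rater-specific severity biases.

**Latent toolkit** (`latent_toolkit`). The style transform `y = Aw + b`;
closed-form semantic factorization (top eigenvectors of `AᵀA` are the
directions of largest generator variation); latent walks
`wᵢ = w_base − αᵢ·a` with α on a linear grid; the Fréchet distance
`‖μ_p−μ_q‖² + Tr(Σ_p + Σ_q − 2(Σ_pΣ_q)^{1/2})` between Gaussian feature
fits; prototype-neighborhood labeling of pathology-relevant attributes;
and a planted-factor toy generator for end-to-end testing without a
trained model.

**Rater simulator** (`rater_sim`). A parametric response model for all
three tasks (detection skill, shared-tell coupling, severity bias and
noise, plausibility tendencies) so every analysis has a
parameter-recovery test against known ground truth.

## Worked example

```python
from capsule_eval import detection_test, severity_slope

r = detection_test(43, 100)           # 43 of 100 images judged correctly
print(f"p_hat={r.p_hat:.2f}  CI=({r.ci_low:.2f}, {r.ci_high:.2f})  "
      f"p={r.p_value:.2f}")
print(severity_slope([1, 2, 3, 4, 4]))
```

prints

```
p_hat=0.43  CI=(0.33, 0.53)  p=0.19
80.0
```

— the reader cannot be distinguished from a coin-flipper (p = 0.19, CI
spanning 0.5), and the ideal monotone severity pattern scores the maximal
5-image slope of 80 on the ×100 scale.

A full simulated study from the command line:

```bash
capsule-eval run-all --seed 1 --out results/run1
```

writes the four response tables, per-rater detection tests, the pairwise
α matrix, ranking and progression summaries, `report.json` and a
human-readable `summary.md`. Individual stages are available as
`capsule-eval simulate | analyze-turing | analyze-agreement |
analyze-ranking | analyze-progression | sefa | walk | fid`.

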