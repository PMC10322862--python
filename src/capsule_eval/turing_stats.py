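"""Visual Turing test analysis.

The scientific question: can expert readers tell synthetic WCE frames
from real ones better than chance?  Each rater's correct-judgment count
``k`` out of ``n`` trials is tested against the chance proportion 0.5.

Two test methods are provided and recorded in the result:

* ``exact_binomial`` (default) — two-sided exact binomial p-value,
  ``min(1, 2 * single-tail)``, valid by the symmetry of the p = 0.5 null.
* ``z_no_continuity`` — plain one-proportion z-test,
  ``2 * Phi(-|p_hat - 0.5| / sqrt(0.25 / n))``.

The 95% confidence interval is the Wald interval
``p_hat +/- 1.96 * sqrt(p_hat (1 - p_hat) / n)``, unclipped.

Beyond the proportion tests the module summarises the 1-5 difficulty
ratings (overall, per rater, and stratified by the four generate
categories: vascular, anatomical, debris, abnormal) and mines consensus
errors — images that a supermajority of raters judged wrongly, the
most diagnostically interesting failures of a synthetic atlas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .rater_sim import GENERATED, REAL, TuringResponse

EXACT_BINOMIAL = "exact_binomial"
Z_NO_CONTINUITY = "z_no_continuity"
_Z_95 = 1.959963984540054  # two-sided 95% normal quantile

DIFFICULTY_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one chance-level detection test."""

    n: int
    k: int
    p_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def detection_test(k: int, n: int, method: str = EXACT_BINOMIAL) -> TestResult:
    """Test a correct-judgment count ``k`` of ``n`` against chance (0.5).

    Returns the proportion estimate, the unclipped 95% Wald interval and
    the two-sided p-value under the stated method.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValidationError(f"k must lie in [0, n] = [0, {n}], got {k}")
    if method not in (EXACT_BINOMIAL, Z_NO_CONTINUITY):
        raise ValidationError(f"unknown method {method!r}")

    p_hat = k / n
    half_width = _Z_95 * np.sqrt(p_hat * (1.0 - p_hat) / n)

    if method == EXACT_BINOMIAL:
        dist = stats.binom(n, 0.5)
        if k < n / 2:
            p_value = 2.0 * dist.cdf(k)
        elif k > n / 2:
            p_value = 2.0 * dist.sf(k - 1)
        else:
            p_value = 1.0
        p_value = min(1.0, float(p_value))
    else:
        z = abs(p_hat - 0.5) / np.sqrt(0.25 / n)
        p_value = float(2.0 * stats.norm.cdf(-z))

    return TestResult(
        n=n,
        k=k,
        p_hat=p_hat,
        ci_low=float(p_hat - half_width),
        ci_high=float(p_hat + half_width),
        p_value=p_value,
        method=method,
    )


def _validate_responses(responses: Sequence[TuringResponse]) -> None:
    for i, r in enumerate(responses):
        if r.true_label not in (REAL, GENERATED):
            raise ValidationError(
                f"row {i}: unknown true_label {r.true_label!r}"
            )
        if r.judged_label not in (REAL, GENERATED):
            raise ValidationError(
                f"row {i}: unknown judged_label {r.judged_label!r}"
            )
        if r.difficulty not in DIFFICULTY_LEVELS:
            raise ValidationError(
                f"row {i}: difficulty must be in 1..5, got {r.difficulty}"
            )


def per_rater_table(
    responses: Sequence[TuringResponse], method: str = EXACT_BINOMIAL
) -> pd.DataFrame:
    """Per-rater detection tests plus a pooled row.

    The pooled row sums (k, n) over all raters — detection counts are
    additive — and applies the same test.  Columns:
    rater_id, n, k, p_hat, ci_low, ci_high, p_value, method.
    """
    if not responses:
        raise ValidationError("responses must be non-empty")
    _validate_responses(responses)

    rows = []
    seen: dict[str, tuple[int, int]] = {}
    for r in responses:
        k, n = seen.get(r.rater_id, (0, 0))
        seen[r.rater_id] = (k + (r.judged_label == r.true_label), n + 1)
    for rater_id, (k, n) in seen.items():
        res = detection_test(k, n, method)
        rows.append({"rater_id": rater_id, **res.__dict__})
    pooled = detection_test(
        sum(k for k, _ in seen.values()), sum(n for _, n in seen.values()), method
    )
    rows.append({"rater_id": "pooled", **pooled.__dict__})
    return pd.DataFrame(rows)[
        ["rater_id", "n", "k", "p_hat", "ci_low", "ci_high", "p_value", "method"]
    ]


def _group_stats(values: np.ndarray) -> dict:
    """Level counts, quartiles and 1.5-IQR outlier flags for one group of
    difficulty ratings."""
    counts = {lvl: int(np.sum(values == lvl)) for lvl in DIFFICULTY_LEVELS}
    q1, med, q3 = (
        np.percentile(values, [25, 50, 75]) if len(values) else (np.nan,) * 3
    )
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted({int(v) for v in values[(values < lo) | (values > hi)]})
    return {
        "n": int(len(values)),
        "counts": counts,
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "iqr": float(iqr),
        "outliers": outliers,
    }


def difficulty_summary(
    responses: Sequence[TuringResponse], stratify_by_category: bool = False
) -> dict:
    """Histogram and boxplot-style summaries of the difficulty ratings.

    Returns ``overall`` and ``per_rater`` summaries always, and when
    ``stratify_by_category`` is set also ``per_category`` restricted to
    generated images (a dataset with no generates yields empty category
    tables, not an error).  Each summary carries level counts 1-5,
    quartiles, IQR and the values flagged as 1.5-IQR outliers.
    """
    if not responses:
        raise ValidationError("responses must be non-empty")
    _validate_responses(responses)

    diffs = np.array([r.difficulty for r in responses])
    out = {"overall": _group_stats(diffs), "per_rater": {}}
    for rid in sorted({r.rater_id for r in responses}):
        vals = np.array([r.difficulty for r in responses if r.rater_id == rid])
        out["per_rater"][rid] = _group_stats(vals)
    if stratify_by_category:
        out["per_category"] = {}
        gen = [r for r in responses if r.true_label == GENERATED]
        for cat in sorted({r.category for r in gen if r.category}):
            vals = np.array([r.difficulty for r in gen if r.category == cat])
            out["per_category"][cat] = _group_stats(vals)
    return out


def consensus_errors(
    responses: Sequence[TuringResponse], min_wrong_fraction: float
) -> list[tuple[str, int, int]]:
    """Images misjudged by a supermajority of the raters who saw them.

    Returns ``(image_id, n_wrong, n_raters)`` for every image judged by
    at least two raters whose wrong-judgment fraction meets the
    threshold, sorted by fraction descending then image_id.  With
    threshold 7/8 this reproduces the "7 of 8 experts wrong" mining of
    atlas failure cases.
    """
    if not 0.0 < min_wrong_fraction <= 1.0:
        raise ValidationError(
            f"min_wrong_fraction must lie in (0, 1], got {min_wrong_fraction}"
        )
    _validate_responses(responses)

    per_image: dict[str, list[bool]] = {}
    for r in responses:
        per_image.setdefault(r.image_id, []).append(r.judged_label != r.true_label)
    hits = []
    for image_id, wrong in per_image.items():
        n = len(wrong)
        if n < 2:
            continue
        n_wrong = sum(wrong)
        if n_wrong / n >= min_wrong_fraction:
            hits.append((image_id, n_wrong, n))
    hits.sort(key=lambda t: (-(t[1] / t[2]), t[0]))
    return hits
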