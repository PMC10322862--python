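"""Disease-progression scoring analysis.

Synthetic progressions are judged useful when perceived severity rises
monotonically along the sequence and the scenario is clinically
plausible.  Monotonicity is measured as the ordinary least-squares slope
of the ordinal severity score (1 normal .. 4 severe) against 1-based
image position, reported on a x100 scale: a sequence rated
[1, 2, 3, 4, 4] over five images has slope 80.0, the steepest pattern a
4-level scale permits over five images without skipping a level.

Plausibility is a 5-point Likert rating per sequence (1 very unlikely ..
5 very likely); the report aggregates per-sequence histograms, per-rater
and overall means, and the counts of extreme ratings.

Rolling position-wise curves expose rater subjectivity: for each image
position, the sequence-ordered series of one rater's severities is
smoothed with a trailing mean (partial leading windows), so a rater with
a positive severity bias sits above the panel at every position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rater_sim import ProgressionResponse

PLAUSIBILITY_LEVELS = (1, 2, 3, 4, 5)


def severity_slope(severities: Sequence[float]) -> float:
    """OLS slope of severity against image position, x100.

    Positions are the 1-based consecutive integers 1..len(severities).
    """
    y = np.asarray(severities, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValidationError(
            f"severity_slope needs at least 2 scores, got {len(np.atleast_1d(y))}"
        )
    x = np.arange(1, len(y) + 1, dtype=float)
    xc = x - x.mean()
    return float(100.0 * (xc @ (y - y.mean())) / (xc @ xc))


@dataclass(frozen=True)
class ProgressionReport:
    """Aggregated progression results.

    ``slopes``: one row per (rater, sequence) with the x100 slope.
    ``per_rater``: mean slope and mean plausibility per rater.
    ``plausibility_hist``: per-sequence counts over levels 1-5.
    ``overall_mean_slope`` / ``overall_mean_plausibility``: unweighted
    means of the per-rater means.
    ``extreme_counts``: totals of level-1 ("very unlikely") and level-5
    ("very likely") plausibility ratings across all responses.
    """

    slopes: pd.DataFrame
    per_rater: pd.DataFrame
    plausibility_hist: pd.DataFrame
    overall_mean_slope: float
    overall_mean_plausibility: float
    extreme_counts: dict[str, int] = field(default_factory=dict)


def progression_report(
    responses: Sequence[ProgressionResponse],
) -> ProgressionReport:
    """Full per-sequence / per-rater / overall progression summary."""
    if not responses:
        raise ValidationError("responses must be non-empty")
    lengths = {len(r.severities) for r in responses}
    if len(lengths) > 1:
        raise ValidationError(
            f"all sequences must have the same length, got lengths {sorted(lengths)}"
        )

    slope_rows = [
        {
            "rater_id": r.rater_id,
            "sequence_id": r.sequence_id,
            "slope": severity_slope(r.severities),
        }
        for r in responses
    ]
    slopes = pd.DataFrame(slope_rows)

    plaus = pd.DataFrame(
        [
            {"rater_id": r.rater_id, "sequence_id": r.sequence_id,
             "plausibility": r.plausibility}
            for r in responses
        ]
    )
    per_rater = (
        slopes.groupby("rater_id")["slope"].mean().to_frame("mean_slope")
        .join(plaus.groupby("rater_id")["plausibility"].mean()
              .to_frame("mean_plausibility"))
        .reset_index()
    )
    hist = (
        plaus.groupby("sequence_id")["plausibility"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(PLAUSIBILITY_LEVELS), fill_value=0)
    )
    hist.columns = [f"level_{c}" for c in hist.columns]

    return ProgressionReport(
        slopes=slopes,
        per_rater=per_rater,
        plausibility_hist=hist.reset_index(),
        overall_mean_slope=float(per_rater["mean_slope"].mean()),
        overall_mean_plausibility=float(per_rater["mean_plausibility"].mean()),
        extreme_counts={
            "very_unlikely": int((plaus["plausibility"] == 1).sum()),
            "very_likely": int((plaus["plausibility"] == 5).sum()),
        },
    )


def positionwise_rolling_mean(
    responses: Sequence[ProgressionResponse], window: int = 5
) -> dict[str, pd.DataFrame]:
    """Trailing rolling mean of severity per image position, per rater.

    For rater ``r`` and image position ``p``, the series of r's
    severities at p across sequences (in sequence-id order) is smoothed
    by a trailing mean over ``window`` sequences; leading entries use
    the partial window.  Returns one DataFrame per rater, indexed by
    sequence_id with one ``position_p`` column per image position.
    A window longer than the number of sequences degrades to the
    running full-series mean, with a warning.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if not responses:
        raise ValidationError("responses must be non-empty")

    out: dict[str, pd.DataFrame] = {}
    for rid in sorted({r.rater_id for r in responses}):
        rows = sorted(
            (r for r in responses if r.rater_id == rid),
            key=lambda r: r.sequence_id,
        )
        if window > len(rows):
            warnings.warn(
                f"window {window} exceeds the {len(rows)} sequences of rater "
                f"{rid!r}; returning the running full-series mean",
                stacklevel=2,
            )
        frame = pd.DataFrame(
            [list(r.severities) for r in rows],
            index=[r.sequence_id for r in rows],
            columns=[f"position_{p + 1}" for p in range(len(rows[0].severities))],
            dtype=float,
        )
        out[rid] = frame.rolling(window=window, min_periods=1).mean()
    return out
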