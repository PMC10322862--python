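"""Realism-ranking analysis.

Raters order 4-image sets (two real, two generated) by decreasing
realness.  Two per-rater percentages quantify whether synthetic images
can be preferred over real ones when viewed side by side:

* ``pct_first_generate`` — how often the rank-1 (most realistic) item is
  generated; 50% under label-blind ranking.
* ``pct_both_generates`` — how often both generates occupy the top two
  ranks; 1/6 under label-blind ranking (of the C(4,2) = 6 equally likely
  placements of the two generated labels among four ranks, exactly one
  puts both on top).

Cross-rater averages are unweighted means of the per-rater percentages,
which matches simple averaging when every rater ranked the same number
of sets.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .rater_sim import GENERATED, RankingResponse


def ranking_summary(responses: Sequence[RankingResponse]) -> pd.DataFrame:
    """Per-rater preference percentages over validated 4-image sets.

    Columns: rater_id, n_sets, n_first_generate, n_both_generates,
    pct_first_generate, pct_both_generates (percent scale, full
    precision).  Set invariants (4 distinct items, exactly two generated)
    are enforced by :class:`RankingResponse`; a malformed set raises a
    validation error naming the set.
    """
    if not responses:
        raise ValidationError("responses must be non-empty")

    per: dict[str, dict[str, int]] = {}
    for r in responses:
        top_labels = [r.labels[i] for i in r.ordering[:2]]
        acc = per.setdefault(
            r.rater_id, {"n_sets": 0, "n_first": 0, "n_both": 0}
        )
        acc["n_sets"] += 1
        acc["n_first"] += top_labels[0] == GENERATED
        acc["n_both"] += top_labels[0] == GENERATED and top_labels[1] == GENERATED

    rows = [
        {
            "rater_id": rid,
            "n_sets": a["n_sets"],
            "n_first_generate": a["n_first"],
            "n_both_generates": a["n_both"],
            "pct_first_generate": 100.0 * a["n_first"] / a["n_sets"],
            "pct_both_generates": 100.0 * a["n_both"] / a["n_sets"],
        }
        for rid, a in per.items()
    ]
    return pd.DataFrame(rows)


def ranking_averages(summary: pd.DataFrame) -> dict[str, float]:
    """Unweighted cross-rater means of the two preference percentages."""
    if summary.empty:
        raise ValidationError("summary must contain at least one rater")
    return {
        "mean_pct_first": float(summary["pct_first_generate"].mean()),
        "mean_pct_both": float(summary["pct_both_generates"].mean()),
    }
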