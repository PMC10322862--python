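"""Krippendorff's alpha for inter-rater reliability.

Alpha is the chance-corrected agreement coefficient

    alpha = 1 - D_o / D_e,

computed here in the coincidence-matrix formulation: for every item
(unit) with m_u >= 2 non-missing ratings, each ordered pair of ratings
within the item contributes weight 1 / (m_u - 1) to the coincidence
count o_ck.  Observed disagreement D_o averages the difference function
over the coincidence matrix; expected disagreement D_e averages it over
the marginals as if ratings were shuffled across items:

    D_o = (1/n)          sum_{c,k} o_ck  * delta(c, k)
    D_e = (1/(n(n-1)))   sum_{c,k} n_c n_k * delta(c, k)

with difference functions delta per measurement level:

* nominal  — 0 if c == k else 1
* interval — (c - k)^2
* ordinal  — (sum of coincidence marginals n_g for g between c and k,
              minus (n_c + n_k)/2)^2

This item-weighted formulation tolerates missing data, which matters
here: raters judged unequal numbers of images, and pairwise agreement is
taken over the 50-image block common to all raters.  alpha = 1 is
perfect agreement, 0 is chance, negative values indicate systematic
disagreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedAlphaError, ValidationError
from .rater_sim import TuringResponse

NOMINAL = "nominal"
ORDINAL = "ordinal"
INTERVAL = "interval"
_LEVELS = (NOMINAL, ORDINAL, INTERVAL)


@dataclass(frozen=True)
class ReliabilityMatrix:
    """Items x raters grid of ratings with NaN/None as missing marks.

    ``values`` is a pandas DataFrame indexed by item id with one column
    per rater; ``level`` selects the difference function.
    """

    values: pd.DataFrame
    level: str = NOMINAL

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValidationError(f"level must be one of {_LEVELS}, got {self.level!r}")
        if self.values.shape[1] < 2:
            raise ValidationError("a reliability matrix needs at least 2 raters")


@dataclass(frozen=True)
class AlphaMatrix:
    """Pairwise alphas (symmetric, diagonal 1), overall alpha, and the
    number of items each pair was computed on."""

    raters: tuple[str, ...]
    pairwise: pd.DataFrame
    overall: float
    n_items: pd.DataFrame


def _coincidence(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    """Coincidence matrix, its marginals, and the sorted category list.

    ``values`` is an items x raters object array with None/NaN missing.
    """
    def present(v) -> bool:
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    cats: list = sorted({v for row in values for v in row if present(v)})
    index = {c: i for i, c in enumerate(cats)}
    q = len(cats)
    o = np.zeros((q, q))
    used_any = False
    for row in values:
        got = [index[v] for v in row if present(v)]
        m = len(got)
        if m < 2:
            continue  # items with fewer than two ratings are unpairable
        used_any = True
        w = 1.0 / (m - 1)
        # ordered pairs of distinct rater slots (equal categories included)
        counts = np.bincount(got, minlength=q).astype(float)
        o += w * (np.outer(counts, counts) - np.diag(counts))
    if not used_any:
        raise UndefinedAlphaError(
            "alpha undefined: no item has two or more non-missing ratings"
        )
    return o, o.sum(axis=1), cats


def _delta(cats: Sequence, marginals: np.ndarray, level: str) -> np.ndarray:
    q = len(cats)
    if level == NOMINAL:
        return 1.0 - np.eye(q)
    vals = np.asarray(cats, dtype=float)
    if level == INTERVAL:
        d = vals[:, None] - vals[None, :]
        return d * d
    # ordinal: squared sum of marginals between the two categories
    # (inclusive) minus half the endpoints
    delta = np.zeros((q, q))
    for c in range(q):
        for k in range(q):
            lo, hi = min(c, k), max(c, k)
            s = marginals[lo : hi + 1].sum() - (marginals[c] + marginals[k]) / 2.0
            delta[c, k] = s * s
    return delta


def krippendorff_alpha(data: ReliabilityMatrix) -> float:
    """Krippendorff's alpha for one reliability matrix.

    Raises :class:`UndefinedAlphaError` when no item is pairable.  When
    expected disagreement is zero (all observed values identical) alpha
    is 1.0 by convention, with a warning.
    """
    values = data.values.to_numpy(dtype=object)
    o, marginals, cats = _coincidence(values)
    delta = _delta(cats, marginals, data.level)
    n = marginals.sum()
    d_o = float((o * delta).sum() / n)
    d_e = float((np.outer(marginals, marginals) * delta).sum() / (n * (n - 1)))
    if d_e == 0.0:
        warnings.warn(
            "expected disagreement is zero (all ratings identical); "
            "alpha set to 1.0 by convention",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - d_o / d_e


def responses_to_matrix(
    responses: Sequence[TuringResponse], level: str = NOMINAL,
    field: str = "judged_label",
) -> ReliabilityMatrix:
    """Pivot Turing responses into an items x raters reliability matrix.

    ``field`` selects the rating: ``judged_label`` (nominal agreement on
    real-vs-generated) or ``difficulty`` (ordinal agreement)."""
    rows = [
        {"image_id": r.image_id, "rater_id": r.rater_id,
         "value": getattr(r, field)}
        for r in responses
    ]
    if not rows:
        raise ValidationError("responses must be non-empty")
    grid = pd.DataFrame(rows).pivot(
        index="image_id", columns="rater_id", values="value"
    )
    return ReliabilityMatrix(values=grid, level=level)


def pairwise_alpha_matrix(
    responses: Sequence[TuringResponse], common_only: bool = True
) -> AlphaMatrix:
    """Pairwise and overall alpha over Turing judgments (nominal level).

    ``common_only`` restricts every computation to the items judged by
    *all* raters — the study's common block — so pairwise entries are
    comparable.  A pair sharing fewer than 2 items gets a missing entry
    and a warning.  The overall alpha uses all raters jointly on the
    common subset.
    """
    matrix = responses_to_matrix(responses, level=NOMINAL)
    grid = matrix.values
    if grid.shape[1] < 2:
        raise ValidationError("need at least 2 raters for pairwise agreement")

    common = grid.dropna(axis=0, how="any")
    base = common if common_only else grid
    raters = tuple(grid.columns)
    q = len(raters)
    pw = pd.DataFrame(np.eye(q), index=raters, columns=raters)
    n_items = pd.DataFrame(0, index=raters, columns=raters, dtype=int)

    for i, a in enumerate(raters):
        for j, b in enumerate(raters):
            if j <= i:
                continue
            pair = base[[a, b]].dropna(axis=0, how="any")
            n_items.loc[a, b] = n_items.loc[b, a] = len(pair)
            if len(pair) < 2:
                warnings.warn(
                    f"raters {a!r} and {b!r} share fewer than 2 items; "
                    "pairwise alpha left missing",
                    stacklevel=2,
                )
                pw.loc[a, b] = pw.loc[b, a] = np.nan
                continue
            alpha = krippendorff_alpha(
                ReliabilityMatrix(values=pair, level=NOMINAL)
            )
            pw.loc[a, b] = pw.loc[b, a] = alpha

    overall = krippendorff_alpha(ReliabilityMatrix(values=common, level=NOMINAL))
    return AlphaMatrix(raters=raters, pairwise=pw, overall=overall, n_items=n_items)
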