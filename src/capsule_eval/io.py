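"""Reading and writing the delimited response tables.

Four UTF-8 CSV schemas with mandatory header rows:

* ``turing.csv`` — rater_id, image_id, true_label, judged_label,
  difficulty, category (empty for real images)
* ``ranking.csv`` — rater_id, set_id, rank, image_id, true_label
  (4 rows per set, rank 1 = most realistic)
* ``progression_ratings.csv`` — rater_id, sequence_id, position, severity
* ``progression_plausibility.csv`` — rater_id, sequence_id, plausibility

Labels are the literal strings "real"/"generated"; categories come from
{vascular, anatomical, debris, abnormal}.  Loading validates every row
and reports all offending rows together, so a malformed export fails
loudly and auditable-y rather than one row at a time.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .rater_sim import (
    CATEGORIES,
    GENERATED,
    REAL,
    ProgressionResponse,
    RankingResponse,
    TuringResponse,
)

_LABELS = (REAL, GENERATED)

TURING_COLUMNS = ["rater_id", "image_id", "true_label", "judged_label",
                  "difficulty", "category"]
RANKING_COLUMNS = ["rater_id", "set_id", "rank", "image_id", "true_label"]
RATINGS_COLUMNS = ["rater_id", "sequence_id", "position", "severity"]
PLAUSIBILITY_COLUMNS = ["rater_id", "sequence_id", "plausibility"]


def write_turing(responses: Sequence[TuringResponse], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "rater_id": r.rater_id,
                "image_id": r.image_id,
                "true_label": r.true_label,
                "judged_label": r.judged_label,
                "difficulty": r.difficulty,
                "category": r.category or "",
            }
            for r in responses
        ],
        columns=TURING_COLUMNS,
    ).to_csv(path, index=False)


def write_ranking(responses: Sequence[RankingResponse], path: str | Path) -> None:
    rows = []
    for r in responses:
        for rank, image_id in enumerate(r.ordering, start=1):
            rows.append(
                {
                    "rater_id": r.rater_id,
                    "set_id": r.set_id,
                    "rank": rank,
                    "image_id": image_id,
                    "true_label": r.labels[image_id],
                }
            )
    pd.DataFrame(rows, columns=RANKING_COLUMNS).to_csv(path, index=False)


def write_progression(
    responses: Sequence[ProgressionResponse],
    ratings_path: str | Path,
    plausibility_path: str | Path,
) -> None:
    ratings, plaus = [], []
    for r in responses:
        for pos, sev in enumerate(r.severities, start=1):
            ratings.append(
                {"rater_id": r.rater_id, "sequence_id": r.sequence_id,
                 "position": pos, "severity": sev}
            )
        plaus.append(
            {"rater_id": r.rater_id, "sequence_id": r.sequence_id,
             "plausibility": r.plausibility}
        )
    pd.DataFrame(ratings, columns=RATINGS_COLUMNS).to_csv(ratings_path, index=False)
    pd.DataFrame(plaus, columns=PLAUSIBILITY_COLUMNS).to_csv(
        plausibility_path, index=False
    )


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in columns]
    missing = [c for c in columns if c not in df.columns]
    if unknown or missing:
        raise ValidationError(
            f"{path.name}: header mismatch (missing {missing}, unknown {unknown})"
        )
    if df.empty:
        warnings.warn(f"{path.name}: file contains a header but no rows",
                      stacklevel=3)
    return df


def _raise_collected(path: str | Path, problems: list[str]) -> None:
    if problems:
        shown = "; ".join(problems[:20])
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        raise ValidationError(f"{Path(path).name}: {shown}{more}")


def read_turing(path: str | Path) -> list[TuringResponse]:
    df = _read_csv(path, TURING_COLUMNS)
    problems, out, seen = [], [], set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.true_label not in _LABELS or row.judged_label not in _LABELS:
            problems.append(f"row {i}: labels must be real/generated")
            continue
        try:
            difficulty = int(row.difficulty)
        except ValueError:
            difficulty = -1
        if difficulty not in (1, 2, 3, 4, 5):
            problems.append(f"row {i}: difficulty must be an integer in 1..5")
            continue
        category = row.category or None
        if row.true_label == GENERATED and category not in CATEGORIES:
            problems.append(f"row {i}: generated image needs a category "
                            f"from {CATEGORIES}")
            continue
        if row.true_label == REAL and category is not None:
            problems.append(f"row {i}: real image must not carry a category")
            continue
        key = (row.rater_id, row.image_id)
        if key in seen:
            problems.append(f"row {i}: duplicate (rater_id, image_id) {key}")
            continue
        seen.add(key)
        out.append(
            TuringResponse(
                rater_id=row.rater_id, image_id=row.image_id,
                true_label=row.true_label, judged_label=row.judged_label,
                difficulty=difficulty, category=category,
            )
        )
    _raise_collected(path, problems)
    return out


def read_ranking(path: str | Path) -> list[RankingResponse]:
    df = _read_csv(path, RANKING_COLUMNS)
    problems, out = [], []
    for (rater_id, set_id), grp in df.groupby(["rater_id", "set_id"], sort=True):
        try:
            ranks = [int(v) for v in grp["rank"]]
        except ValueError:
            problems.append(f"set {set_id}: non-integer rank")
            continue
        if sorted(ranks) != [1, 2, 3, 4]:
            problems.append(f"set {set_id}: ranks must be exactly 1..4 (ties "
                            "are malformed)")
            continue
        ordered = grp.assign(rank=ranks).sort_values("rank")
        labels = dict(zip(ordered["image_id"], ordered["true_label"]))
        try:
            out.append(
                RankingResponse(
                    rater_id=rater_id, set_id=set_id,
                    ordering=tuple(ordered["image_id"]), labels=labels,
                )
            )
        except ValidationError as exc:
            problems.append(str(exc))
    _raise_collected(path, problems)
    return out


def read_progression(
    ratings_path: str | Path, plausibility_path: str | Path
) -> list[ProgressionResponse]:
    ratings = _read_csv(ratings_path, RATINGS_COLUMNS)
    plaus = _read_csv(plausibility_path, PLAUSIBILITY_COLUMNS)
    plaus_map = {
        (r.rater_id, r.sequence_id): r.plausibility
        for r in plaus.itertuples(index=False)
    }
    problems, out = [], []
    for (rater_id, seq_id), grp in ratings.groupby(
        ["rater_id", "sequence_id"], sort=True
    ):
        try:
            ordered = grp.assign(position=grp["position"].astype(int)).sort_values(
                "position"
            )
            severities = tuple(int(v) for v in ordered["severity"])
        except ValueError:
            problems.append(f"sequence {seq_id}: non-integer position/severity")
            continue
        if list(ordered["position"]) != list(range(1, len(ordered) + 1)):
            problems.append(f"sequence {seq_id}: positions must be 1..k")
            continue
        key = (rater_id, seq_id)
        if key not in plaus_map:
            problems.append(f"sequence {seq_id}: no plausibility row for "
                            f"rater {rater_id}")
            continue
        try:
            out.append(
                ProgressionResponse(
                    rater_id=rater_id, sequence_id=seq_id,
                    severities=severities,
                    plausibility=int(plaus_map[key]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(str(exc))
    _raise_collected(ratings_path, problems)
    return out
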