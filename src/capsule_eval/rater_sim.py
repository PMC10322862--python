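"""Synthetic rater-response generator for the three subjective tasks.

Real reader studies of synthetic wireless capsule endoscopy (WCE) images
collect expert judgments that cannot be regenerated at will.  This module
replaces the human panel with a parametric response model whose ground
truth is known, so every downstream analysis (detection tests, agreement
coefficients, ranking preferences, severity slopes) has a
parameter-recovery test:

* **Visual Turing test** — each simulated expert judges images as real or
  generated.  The probability of a correct judgment is the rater's
  ``detection_skill``; a nonzero ``tell_loading`` couples raters to a
  shared per-image "tell" signal through a logistic link, which induces
  inter-rater correlation without changing the marginal difficulty much.
* **Realism ranking** — raters order 4-image sets (two real, two
  generated) by perceived realism, modelled as an additive score
  ``realism_bias_real * is_real + noise``.  With zero bias the labels are
  exchangeable, giving the analytic nulls 1/2 (a generate ranks first)
  and 1/6 (both generates occupy the top two ranks).
* **Disease progression** — latent severity grows linearly with image
  position at slope ``severity_trend`` plus a per-rater bias and Gaussian
  noise, then is binned by fixed thresholds into the ordinal scale
  normal < mild < moderate < severe.  Plausibility ratings are drawn from
  each rater's 5-level tendency distribution.

Randomness: one global seed feeds per-task, per-rater substreams via
``numpy.random.SeedSequence`` spawn keys, so adding raters to a design
never perturbs the streams of existing raters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

CATEGORIES = ("vascular", "anatomical", "debris", "abnormal")
REAL = "real"
GENERATED = "generated"

#: Bin edges mapping latent severity onto ordinal levels 1..4.  With a
#: unit per-position trend these midpoints reproduce the ideal noiseless
#: pattern [1, 2, 3, 4, 4] over five images: a four-level scale over five
#: positions necessarily repeats one level.
DEFAULT_SEVERITY_THRESHOLDS = (1.5, 2.5, 3.5)

# Task indices used in substream spawn keys.
_TASK_TURING, _TASK_RANKING, _TASK_PROGRESSION = 0, 1, 2
# Spawn-key rater slot reserved for streams shared by all raters.
_SHARED_STREAM = 1 << 16


@dataclass(frozen=True)
class RaterProfile:
    """Ground-truth response parameters for one simulated expert.

    Parameters
    ----------
    rater_id:
        Identifier carried into every response row.
    detection_skill:
        Probability in [0, 1] of judging an image's true label correctly
        in the Turing task (0.5 = chance).
    tell_loading:
        Nonnegative coupling to the shared per-image tell signal;
        0 makes raters mutually independent given the images.
    severity_bias:
        Additive offset on the latent severity scale (a rater who "rates
        higher than other experts on the same image" has positive bias).
    severity_noise_sd:
        Standard deviation of the Gaussian noise on latent severity.
    realism_bias_real:
        Added to the perceived realism of real images in the ranking
        task; 0 makes real and generated exchangeable.
    plausibility_tendency:
        Probability vector over the 5 plausibility levels
        (very unlikely ... very likely).
    """

    rater_id: str
    detection_skill: float = 0.5
    tell_loading: float = 0.0
    severity_bias: float = 0.0
    severity_noise_sd: float = 0.35
    realism_bias_real: float = 0.0
    # Default mimics the study-level plausibility profile: no
    # "very unlikely" ratings, mass centred between neutral and likely
    # (mean ~3.7), occasional "very likely".
    plausibility_tendency: tuple[float, ...] = (0.0, 0.08, 0.30, 0.45, 0.17)

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_skill <= 1.0:
            raise ValidationError(
                f"detection_skill must lie in [0, 1], got {self.detection_skill}"
            )
        if self.tell_loading < 0:
            raise ValidationError(
                f"tell_loading must be nonnegative, got {self.tell_loading}"
            )
        if self.severity_noise_sd < 0:
            raise ValidationError(
                f"severity_noise_sd must be nonnegative, got {self.severity_noise_sd}"
            )
        pt = np.asarray(self.plausibility_tendency, dtype=float)
        if pt.shape != (5,):
            raise ValidationError(
                "plausibility_tendency must have exactly 5 entries, "
                f"got shape {pt.shape}"
            )
        if np.any(pt < 0) or abs(pt.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "plausibility_tendency must be a probability vector summing "
                f"to 1 (got sum {pt.sum()!r})"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Sizes and structure of the three-task study.

    Defaults reproduce the published study layout: 100 Turing images per
    rater of which the first 50 are common to all raters, 37 ranking
    sets, and 22 progression sequences of 5 images each.
    """

    n_images: int = 100
    n_common: int = 50
    n_sets: int = 37
    n_sequences: int = 22
    images_per_sequence: int = 5
    category_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    severity_trend: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_images", "n_common", "n_sets", "n_sequences",
                     "images_per_sequence"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be a count >= 1, got {value}")
        if self.n_common > self.n_images:
            raise ValidationError(
                f"n_common ({self.n_common}) cannot exceed n_images "
                f"({self.n_images})"
            )
        cw = np.asarray(self.category_weights, dtype=float)
        if cw.shape != (len(CATEGORIES),):
            raise ValidationError(
                f"category_weights must have {len(CATEGORIES)} entries"
            )
        if np.any(cw < 0) or abs(cw.sum() - 1.0) > 1e-9:
            raise ValidationError("category_weights must sum to 1")


@dataclass(frozen=True)
class TuringResponse:
    """One expert judgment in the visual Turing test."""

    rater_id: str
    image_id: str
    true_label: str
    judged_label: str
    difficulty: int  # ordinal 1 ("very difficult") .. 5 ("very easy")
    category: str | None  # present iff the image is generated


@dataclass(frozen=True)
class RankingResponse:
    """One expert's forced ordering of a 4-image set (2 real, 2 generated).

    ``ordering`` lists image ids from most realistic (rank 1) to least;
    ``labels`` maps each image id to its true label.
    """

    rater_id: str
    set_id: str
    ordering: tuple[str, str, str, str]
    labels: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != 4:
            raise ValidationError(
                f"set {self.set_id}: ordering must be a permutation of 4 "
                "distinct items"
            )
        lab = sorted(self.labels[i] for i in self.ordering)
        if lab != [GENERATED, GENERATED, REAL, REAL]:
            raise ValidationError(
                f"set {self.set_id}: label multiset must be two real and two "
                f"generated, got {lab}"
            )


@dataclass(frozen=True)
class ProgressionResponse:
    """One expert's severity scores plus plausibility for one sequence."""

    rater_id: str
    sequence_id: str
    severities: tuple[int, ...]  # one per image position, each in 1..4
    plausibility: int  # 1 (very unlikely) .. 5 (very likely)

    def __post_init__(self) -> None:
        if any(s not in (1, 2, 3, 4) for s in self.severities):
            raise ValidationError(
                f"sequence {self.sequence_id}: severities must be in 1..4"
            )
        if self.plausibility not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"sequence {self.sequence_id}: plausibility must be in 1..5"
            )


def _rng(design: StudyDesign, task: int, slot: int) -> np.random.Generator:
    """Independent substream keyed by (task, rater-or-shared slot)."""
    return np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(task, slot))
    )


def _check_raters(raters: Sequence[RaterProfile]) -> None:
    if not raters:
        raise ValidationError("raters must contain at least one RaterProfile")
    ids = [r.rater_id for r in raters]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate rater_id among {ids}")


def _balanced_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    """n labels, half real half generated (odd n: generated gets the extra),
    in shuffled order."""
    n_gen = (n + 1) // 2
    labels = np.array([GENERATED] * n_gen + [REAL] * (n - n_gen), dtype=object)
    rng.shuffle(labels)
    return labels


def simulate_turing(
    design: StudyDesign, raters: Sequence[RaterProfile]
) -> list[TuringResponse]:
    """Simulate the visual Turing test.

    Every rater judges ``design.n_images`` images; the first
    ``design.n_common`` image ids form a block shared by all raters (with
    consistent true labels, categories and tell signals), emulating the
    common subset over which agreement is computed.  True labels are
    balanced 50/50 per rater.

    The judgment is correct with probability ``detection_skill`` when
    ``tell_loading`` is zero; otherwise with probability
    ``sigmoid(logit(skill) + loading * tell)`` where the tell is a
    standard-normal per-image signal shared across raters.

    The difficulty rating is a rounded, clipped draw from a unit-variance
    Gaussian centred at ``6 - 5 * |2 * skill - 1|``: the rating mean
    decreases with the rater's distance from chance.
    """
    _check_raters(raters)

    shared = _rng(design, _TASK_TURING, _SHARED_STREAM)
    common_ids = [f"img_{i:04d}" for i in range(design.n_common)]
    common_labels = _balanced_labels(design.n_common, shared)
    common_tells = shared.standard_normal(design.n_common)
    common_cats = {
        cid: CATEGORIES[shared.choice(len(CATEGORIES), p=design.category_weights)]
        for cid, lab in zip(common_ids, common_labels)
        if lab == GENERATED
    }

    responses: list[TuringResponse] = []
    n_extra = design.n_images - design.n_common
    for idx, rater in enumerate(raters):
        rng = _rng(design, _TASK_TURING, idx)

        ids = list(common_ids)
        labels = list(common_labels)
        tells = list(common_tells)
        cats = dict(common_cats)
        if n_extra:
            # Extra labels chosen so the rater's total stays balanced.
            n_gen_total = (design.n_images + 1) // 2
            n_gen_extra = n_gen_total - int(np.sum(common_labels == GENERATED))
            extra_labels = np.array(
                [GENERATED] * n_gen_extra + [REAL] * (n_extra - n_gen_extra),
                dtype=object,
            )
            rng.shuffle(extra_labels)
            for j, lab in enumerate(extra_labels):
                iid = f"{rater.rater_id}_extra_{j:04d}"
                ids.append(iid)
                labels.append(lab)
                tells.append(rng.standard_normal())
                if lab == GENERATED:
                    cats[iid] = CATEGORIES[
                        rng.choice(len(CATEGORIES), p=design.category_weights)
                    ]

        skill = rater.detection_skill
        if rater.tell_loading > 0:
            s = min(max(skill, 1e-9), 1 - 1e-9)
            logits = math.log(s / (1 - s)) + rater.tell_loading * np.asarray(tells)
            p_correct = 1.0 / (1.0 + np.exp(-logits))
        else:
            p_correct = np.full(len(ids), skill)

        correct = rng.random(len(ids)) < p_correct
        diff_mean = 6.0 - 5.0 * abs(2.0 * skill - 1.0)
        difficulty = np.clip(
            np.rint(rng.normal(diff_mean, 1.0, size=len(ids))), 1, 5
        ).astype(int)

        for iid, lab, ok, dif in zip(ids, labels, correct, difficulty):
            judged = lab if ok else (REAL if lab == GENERATED else GENERATED)
            responses.append(
                TuringResponse(
                    rater_id=rater.rater_id,
                    image_id=iid,
                    true_label=lab,
                    judged_label=judged,
                    difficulty=int(dif),
                    category=cats.get(iid),
                )
            )
    return responses


def simulate_ranking(
    design: StudyDesign, raters: Sequence[RaterProfile]
) -> list[RankingResponse]:
    """Simulate the realism-ranking task.

    Each of ``design.n_sets`` sets holds two real and two generated
    images in randomized positions.  A rater scores each item with
    ``realism_bias_real * is_real + N(0, 1)`` and ranks by decreasing
    score; zero bias makes the two labels exchangeable.
    """
    _check_raters(raters)

    responses: list[RankingResponse] = []
    for idx, rater in enumerate(raters):
        rng = _rng(design, _TASK_RANKING, idx)
        for s in range(design.n_sets):
            set_id = f"set_{s:04d}"
            items = [f"{set_id}_item_{j}" for j in range(4)]
            labels = np.array([REAL, REAL, GENERATED, GENERATED], dtype=object)
            rng.shuffle(labels)
            scores = (
                rater.realism_bias_real * (labels == REAL).astype(float)
                + rng.standard_normal(4)
            )
            order = np.argsort(-scores, kind="stable")
            responses.append(
                RankingResponse(
                    rater_id=rater.rater_id,
                    set_id=set_id,
                    ordering=tuple(items[j] for j in order),
                    labels={i: str(l) for i, l in zip(items, labels)},
                )
            )
    return responses


def simulate_progression(
    design: StudyDesign,
    raters: Sequence[RaterProfile],
    thresholds: Sequence[float] = DEFAULT_SEVERITY_THRESHOLDS,
) -> list[ProgressionResponse]:
    """Simulate the disease-progression scoring task.

    Latent severity at 1-based position ``p`` is
    ``severity_trend * p + severity_bias + N(0, severity_noise_sd)``,
    binned by ``thresholds`` into the ordinal levels 1..4.  Plausibility
    is drawn per sequence from the rater's ``plausibility_tendency``.
    """
    _check_raters(raters)
    if design.images_per_sequence < 2:
        raise ValidationError("images_per_sequence must be >= 2")
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or len(thr) != 3 or np.any(np.diff(thr) <= 0):
        raise ValidationError(
            "thresholds must be a strictly increasing vector of 3 bin edges, "
            f"got {list(thresholds)}"
        )

    positions = np.arange(1, design.images_per_sequence + 1, dtype=float)
    responses: list[ProgressionResponse] = []
    for idx, rater in enumerate(raters):
        rng = _rng(design, _TASK_PROGRESSION, idx)
        for s in range(design.n_sequences):
            latent = (
                design.severity_trend * positions
                + rater.severity_bias
                + rng.normal(0.0, rater.severity_noise_sd, size=len(positions))
                if rater.severity_noise_sd > 0
                else design.severity_trend * positions + rater.severity_bias
            )
            levels = np.searchsorted(thr, latent, side="right") + 1
            plaus = int(rng.choice(5, p=rater.plausibility_tendency)) + 1
            responses.append(
                ProgressionResponse(
                    rater_id=rater.rater_id,
                    sequence_id=f"seq_{s:04d}",
                    severities=tuple(int(v) for v in levels),
                    plausibility=plaus,
                )
            )
    return responses


def default_panel(n_raters: int = 8) -> list[RaterProfile]:
    """A study-like expert panel: detection skills scattered around
    chance (one clearly above, as observed for the most experienced
    reader), moderate shared-tell coupling, and heterogeneous severity
    biases producing rater-specific rating curves."""
    skills = [0.51, 0.58, 0.43, 0.49, 0.54, 0.57, 0.55, 0.42]
    biases = [0.5, 0.1, -0.1, -0.5, 0.2, -0.2, 0.0, 0.3]
    return [
        RaterProfile(
            rater_id=f"user_{i + 1}",
            detection_skill=skills[i % len(skills)],
            tell_loading=0.5,
            severity_bias=biases[i % len(biases)],
        )
        for i in range(n_raters)
    ]
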