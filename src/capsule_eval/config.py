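"""Run configuration: one structured YAML/JSON file drives a pipeline run.

Documented keys (all optional unless noted)::

    seed: 7                      # global seed; feeds every stochastic stage
    out_dir: results/run1        # required; created if absent
    design:                      # StudyDesign fields
      n_images: 100
      n_common: 50
      n_sets: 37
      n_sequences: 22
      images_per_sequence: 5
      severity_trend: 1.0
    raters:                      # list of RaterProfile fields; omitted ->
      - rater_id: user_1         #   the default 8-expert panel
        detection_skill: 0.55
        tell_loading: 0.5
    analysis:
      method: exact_binomial     # or z_no_continuity
      window: 5                  # rolling-mean window
      common_only: true          # agreement on the common block only
      min_wrong_fraction: 0.875  # consensus-error threshold (7/8)
    inputs:                      # analyze pre-existing tables instead of
      turing: path/to/turing.csv #   simulating; all referenced files must
      ranking: path/to/ranking.csv       # exist at validation time
      ratings: path/to/progression_ratings.csv
      plausibility: path/to/progression_plausibility.csv

Command-line flags override config values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .rater_sim import RaterProfile, StudyDesign, default_panel


@dataclass(frozen=True)
class AnalysisOptions:
    method: str = "exact_binomial"
    window: int = 5
    common_only: bool = True
    min_wrong_fraction: float = 0.875


@dataclass(frozen=True)
class RunConfig:
    out_dir: Path
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    raters: tuple[RaterProfile, ...] = ()
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    inputs: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, path in self.inputs.items():
            if not Path(path).exists():
                raise ValidationError(f"configured input {tag!r} does not exist: {path}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a YAML (or JSON, a YAML subset) config file.

    Keyword overrides (e.g. ``seed=3`` from a CLI flag) take precedence
    over file values.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file does not exist: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config root must be a mapping, got {type(raw).__name__}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return build_config(raw)


def build_config(raw: dict) -> RunConfig:
    if "out_dir" not in raw:
        raise ValidationError("config must set out_dir")
    seed = int(raw.get("seed", 0))
    design_kwargs = dict(raw.get("design", {}))
    design_kwargs.setdefault("seed", seed)
    design = StudyDesign(**design_kwargs)
    raters_raw = raw.get("raters")
    raters = (
        tuple(RaterProfile(**r) for r in raters_raw)
        if raters_raw
        else tuple(default_panel())
    )
    analysis = AnalysisOptions(**raw.get("analysis", {}))
    inputs = {k: Path(v) for k, v in raw.get("inputs", {}).items()}
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        seed=seed,
        design=design,
        raters=raters,
        analysis=analysis,
        inputs=inputs,
    )


def dump_config(config: RunConfig) -> str:
    """Round-trippable JSON rendering of a config (for the report)."""
    return json.dumps(
        {
            "seed": config.seed,
            "out_dir": str(config.out_dir),
            "design": {k: v for k, v in config.design.__dict__.items()},
            "raters": [r.__dict__ for r in config.raters],
            "analysis": config.analysis.__dict__,
            "inputs": {k: str(v) for k, v in config.inputs.items()},
        },
        default=list,
        indent=2,
        sort_keys=True,
    )
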