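"""Run configuration: every model and protocol constant in one overridable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List

import yaml

from .maturation import MaturationSchedule, TurnoverPolicy
from .rbm import VARIANTS

__all__ = ["ExperimentConfig", "REGIMES"]

REGIMES = ("same", "multi")


@dataclass
class ExperimentConfig:
    """Configuration of one interference experiment.

    ``variants`` selects which models to run on the same per-repetition
    datasets; ``regime`` selects same-session (no maturation between groups)
    or multi-session (age advance, connectivity growth and turnover between
    groups). Dataset, model and maturation constants default to the standard
    protocol: a 200-visible x 1000-hidden machine, 10%-dense patterns in 5
    classes x 11 subclasses, mini-batches of 5 (one pattern per class), one
    pass through the data, 20 repetitions.
    """

    variants: List[str] = field(default_factory=lambda: list(VARIANTS))
    regime: str = "same"
    n_repetitions: int = 20
    seed: int = 0

    # model
    n_visible: int = 200
    n_hidden: int = 1000
    p_target: float = 0.05
    learning_rate: float = 0.1
    sparse_cost: float = 0.9
    weight_decay: float = 2e-4
    sigma_init: float = 0.01
    batch_size: int = 5
    cd_stats: str = "prob"
    cd_k: int = 1
    eval_mode: str = "stochastic"

    # dataset
    pattern_length: int = 200
    density: float = 0.1
    n_classes: int = 5
    n_subclasses: int = 11
    proto_reset: float = 0.2
    instance_reset: float = 0.05
    train_per_prototype: int = 18
    test_candidates_per_prototype: int = 4
    n_test: int = 200

    # maturation / turnover
    schedule: MaturationSchedule = field(default_factory=MaturationSchedule)
    policy: TurnoverPolicy = field(default_factory=TurnoverPolicy)

    # bootstrap comparison
    n_boot: int = 10_000

    def __post_init__(self) -> None:
        unknown = [v for v in self.variants if v not in VARIANTS]
        if unknown:
            raise ValueError(f"unknown variant(s) {unknown}; expected from {VARIANTS}")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.cd_stats not in ("prob", "sample"):
            raise ValueError("cd_stats must be 'prob' or 'sample'")
        if self.eval_mode not in ("stochastic", "mean_field"):
            raise ValueError("eval_mode must be 'stochastic' or 'mean_field'")
        if self.cd_k < 1:
            raise ValueError("cd_k must be at least 1")
        group_size = self.n_classes * self.train_per_prototype
        if group_size % self.batch_size:
            raise ValueError("batch size must divide the group size")
        if self.pattern_length != self.n_visible:
            raise ValueError("pattern length must equal the number of visible units")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        if "schedule" in d and isinstance(d["schedule"], dict):
            d["schedule"] = MaturationSchedule(**d["schedule"])
        if "policy" in d and isinstance(d["policy"], dict):
            d["policy"] = TurnoverPolicy(**d["policy"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
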