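"""Run configuration: serializable parameters for every pipeline stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .texture import FeatureConfig

__all__ = ["RunConfig", "CvConfig", "CopulaConfig", "SimulateConfig", "config_hash"]


@dataclass
class SimulateConfig:
    """Phantom cohort shape: sizes mirror the study cohort by default."""

    n_subjects: int = 70
    n_rep: int = 13
    volume_size: int = 48
    alpha: float = 18.0
    beta: tuple = (0.7,)
    gamma: tuple = (0.3,)
    baseline_death: tuple = (1.3, 600.0)
    baseline_censor: tuple = (1.2, 1100.0)
    noise_sd: float = 2.0
    texture_sd: float = 8.0


@dataclass
class CvConfig:
    """Balanced-resampling cross-validation parameters."""

    iterations: int = 1000
    folds: int = 5
    k_final: int = 3
    screen_iterations: int = 100
    sampling: dict | None = None       # per-class counts, e.g. {1: 25, 0: 13}
    learner_params: dict = field(default_factory=dict)


@dataclass
class CopulaConfig:
    """Dependence grid and survival feature-selection parameters."""

    alpha_grid: tuple = tuple(range(0, 32, 2))
    folds: int = 5
    f1_threshold: float = 0.7
    f1_iterations: int = 10
    p_threshold: float = 0.05
    top_k: int = 3
    n_perm: int = 1000


@dataclass
class RunConfig:
    """Everything a pipeline run needs; archived beside its outputs."""

    out_dir: str = "runs/default"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    copula: CopulaConfig = field(default_factory=CopulaConfig)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("simulate", SimulateConfig), ("features", FeatureConfig),
                         ("cv", CvConfig), ("copula", CopulaConfig)):
            if key in d and isinstance(d[key], dict):
                payload = {k: (tuple(v) if isinstance(v, list) else v)
                           for k, v in d[key].items()}
                d[key] = sub(**payload)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
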