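"""Run configuration: a YAML-serializable bundle of pipeline settings."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """Settings of a pipeline run; mirrors :class:`~wcie.estimator.LandmarkWCIE`."""

    window: float = 24.0
    grid_step: float = 1.0
    exposure_n_inner_knots: int = 4
    exposure_knot_mode: str = "quantile"
    exposure_random_structure: str = "spline"
    confounders: tuple[str, ...] = ("age0", "education")
    include_v0: bool = False
    weight_knot_candidates: tuple[int, ...] = (1, 2, 3, 4, 5)
    history_mode: str = "discrete-sum"
    n_bootstrap: int = 500
    bootstrap_param_set: str = "all"
    ci_level: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        self.confounders = tuple(self.confounders)
        self.weight_knot_candidates = tuple(int(k) for k in self.weight_knot_candidates)
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        if self.bootstrap_param_set not in ("all", "fixed"):
            raise ValueError('bootstrap_param_set must be "all" or "fixed"')

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confounders"] = list(self.confounders)
        d["weight_knot_candidates"] = list(self.weight_knot_candidates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def estimator_kwargs(self) -> dict:
        d = self.to_dict()
        seed = d.pop("seed")
        d["random_state"] = seed
        return d


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical YAML form, for output provenance."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
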