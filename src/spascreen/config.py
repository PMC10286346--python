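"""Run configuration: a flat key-value document validated in one pass.

Every choice the analysis leaves open (test-selection rule is fixed, but the
correlation method, retention rule, loading threshold, reliability floor,
convergence floor, cutoff rounding and CI method are all knobs) is a config
key, so a run manifest fully records how its numbers were produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]

STAGES = ("screen", "factor", "reliability", "performance")


class ConfigError(ValueError):
    """Invalid run configuration; carries the full list of problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    # input source: exactly one of (seed-driven generator, cohort file)
    seed: int | None = 7
    cohort_path: str | None = None
    factor_corr: float = 0.3
    # stage toggles
    stages: tuple[str, ...] = STAGES
    # thresholds
    alpha: float = 0.05
    loading_threshold: float = 0.36
    reliability_floor: float = 0.70
    convergence_floor: float = 0.40
    rounding_rule: str = "floor"
    correlation_method: str = "pearson_phi"
    retention: str = "kaiser"
    fixed_k: int | None = None
    ci_method: str = "hanley"
    pca_groups: tuple[str, ...] | None = None  # None = pooled
    # output
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        if self.pca_groups is not None:
            d["pca_groups"] = list(self.pca_groups)
        return d


def validate_config(raw: dict) -> RunConfig:
    """Build a RunConfig from a flat mapping, collecting every error."""
    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})

    if isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    if isinstance(cfg.pca_groups, list):
        cfg.pca_groups = tuple(cfg.pca_groups)

    if (cfg.seed is None) == (cfg.cohort_path is None):
        errors.append(
            "exactly one input source required: set seed (generator) or "
            "cohort_path (file), not both or neither"
        )
    for stage in cfg.stages:
        if stage not in STAGES:
            errors.append(f"unknown stage {stage!r} (choose from {STAGES})")
    for name, lo, hi in (
        ("alpha", 0.0, 1.0),
        ("loading_threshold", 0.0, 1.0),
        ("reliability_floor", 0.0, 1.0),
        ("convergence_floor", 0.0, 1.0),
    ):
        v = getattr(cfg, name)
        if not isinstance(v, (int, float)) or not (lo <= v <= hi):
            errors.append(f"{name} must be a number in [{lo}, {hi}], got {v!r}")
    if not (-1.0 < cfg.factor_corr < 1.0):
        errors.append(f"factor_corr must lie in (-1, 1), got {cfg.factor_corr!r}")
    if cfg.rounding_rule not in ("floor", "ceil"):
        errors.append(f"rounding_rule must be floor or ceil, got {cfg.rounding_rule!r}")
    if cfg.correlation_method not in ("pearson_phi", "tetrachoric"):
        errors.append(
            f"correlation_method must be pearson_phi or tetrachoric, got "
            f"{cfg.correlation_method!r}"
        )
    if cfg.retention not in ("kaiser", "fixed_k"):
        errors.append(f"retention must be kaiser or fixed_k, got {cfg.retention!r}")
    if cfg.retention == "fixed_k" and (
        cfg.fixed_k is None or not isinstance(cfg.fixed_k, int) or cfg.fixed_k < 1
    ):
        errors.append("fixed_k retention requires a positive integer fixed_k")
    if cfg.ci_method not in ("hanley", "delong"):
        errors.append(f"ci_method must be hanley or delong, got {cfg.ci_method!r}")

    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML config file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"unparseable config: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a flat mapping"])
    return validate_config(raw)
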