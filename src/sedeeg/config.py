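"""Run configuration: YAML schema, validation, defaults.

The YAML mirrors the pipeline stages::

    seed: 0
    log_level: INFO
    paths: {out_dir: results, input_store: null}
    synth: {n_subjects: 4, ...}          # omit to read from input_store
    preprocess: {band_hz: [0.5, 25], ...}
    features: {sampen_m: 2, ...}
    models:
      - {family: ET-B, grid: {n_estimators: [30, 60]}}
    evaluate: {cv_unit: recording, n_boot: 1000}

Unknown keys are an error in strict mode (default) and a warning in
lenient mode. A frozen, fully-defaulted copy of the configuration is
written next to the outputs by the pipeline runner.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .features import FeatureConfig
from .models import ModelSpec
from .preprocess import PreprocessConfig
from .synth import BurstSuppressionParams, GeneratorConfig, SpectralTemplate

_TOP_KEYS = {"seed", "log_level", "paths", "synth", "preprocess", "features",
             "models", "evaluate"}
_PATH_KEYS = {"out_dir", "input_store"}
_EVAL_KEYS = {"cv_unit", "n_boot"}


@dataclass
class RunConfig:
    out_dir: Path
    input_store: Path | None = None
    synth: GeneratorConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    models: list = field(default_factory=list)
    cv_unit: str = "recording"
    n_boot: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def normalized(self) -> dict:
        """Fully-defaulted plain-dict view (what gets frozen to disk)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, list):
                return [enc(v) for v in obj]
            return obj

        return {
            "seed": self.seed,
            "log_level": self.log_level,
            "paths": {
                "out_dir": str(self.out_dir),
                "input_store": str(self.input_store) if self.input_store else None,
            },
            "synth": enc(self.synth) if self.synth else None,
            "preprocess": enc(self.preprocess),
            "features": enc(self.features),
            "models": [
                {"family": s.family, "grid": enc(s.grid),
                 "inner_folds": s.inner_folds, "seed": s.seed}
                for s in self.models
            ],
            "evaluate": {"cv_unit": self.cv_unit, "n_boot": self.n_boot},
        }


def _check_keys(section: dict, allowed, where: str, strict: bool) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        msg = f"unknown key(s) {sorted(unknown)} under {where!r}"
        if strict:
            raise ConfigError(msg)
        warnings.warn(msg, stacklevel=3)


def _build(cls, section: dict, where: str, strict: bool, **extra):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, fields, where, strict)
    kwargs = {k: v for k, v in section.items() if k in fields}
    # YAML lists -> tuples where the dataclass expects tuples
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            val = kwargs[f.name]
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in val
            )
    kwargs.update(extra)
    return cls(**kwargs)


def _build_synth(section: dict, strict: bool) -> GeneratorConfig:
    section = dict(section)
    for tmpl_key in ("awake_template", "sedated_template"):
        if tmpl_key in section and isinstance(section[tmpl_key], dict):
            section[tmpl_key] = _build(
                SpectralTemplate, section[tmpl_key], f"synth.{tmpl_key}", strict
            )
    if "bs_params" in section and isinstance(section["bs_params"], dict):
        section["bs_params"] = _build(
            BurstSuppressionParams, section["bs_params"], "synth.bs_params", strict
        )
    return _build(GeneratorConfig, section, "synth", strict)


def validate_config(path, strict: bool = True) -> RunConfig:
    """Load, validate and normalize a run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<top>", strict)

    paths = raw.get("paths") or {}
    _check_keys(paths, _PATH_KEYS, "paths", strict)
    if "out_dir" not in paths:
        raise ConfigError("config missing required key 'paths.out_dir'")

    if "models" not in raw or not raw["models"]:
        raise ConfigError("config missing required key 'models'")
    models = []
    for i, entry in enumerate(raw["models"]):
        fields = {f.name for f in dataclasses.fields(ModelSpec)}
        _check_keys(entry, fields, f"models[{i}]", strict)
        models.append(ModelSpec(**entry))

    ev = raw.get("evaluate") or {}
    _check_keys(ev, _EVAL_KEYS, "evaluate", strict)

    cfg = RunConfig(
        out_dir=Path(paths["out_dir"]),
        input_store=Path(paths["input_store"]) if paths.get("input_store") else None,
        synth=_build_synth(raw["synth"], strict) if raw.get("synth") else None,
        preprocess=_build(PreprocessConfig, raw.get("preprocess") or {}, "preprocess", strict),
        features=_build(FeatureConfig, raw.get("features") or {}, "features", strict),
        models=models,
        cv_unit=ev.get("cv_unit", "recording"),
        n_boot=int(ev.get("n_boot", 1000)),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if cfg.synth is None and cfg.input_store is None:
        raise ConfigError("config needs either a 'synth' section or 'paths.input_store'")
    return cfg
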