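"""Run configuration: structured file + override merging, hashing, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .coords import (
    LoopAnnotation,
    ProbePanel,
    default_loop_annotation,
    default_probe_panel,
    load_probe_panel,
)
from .fish_sim import DistanceModel, NucleusConfig, parse_pair, _DEFAULT_MU

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, reproducibly.

    All fields have working defaults; a YAML config file and CLI flags
    override them (flags win).
    """

    probe_panel: str = "default"
    loop_annotation: str = "default"
    distance_model: dict[str, Any] = field(default_factory=dict)
    nucleus: dict[str, Any] = field(default_factory=dict)
    n_nuclei: int = 200
    k: int = 40
    seed: int = 0
    out_dir: str = "loopdist_out"
    verbosity: int = 0
    contact: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_nuclei < self.k:
            raise ConfigError(
                f"n_nuclei ({self.n_nuclei}) must be >= k ({self.k}): "
                "the top-k statistic needs at least k measurements"
            )
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed}")
        for name in ("probe_panel", "loop_annotation"):
            val = getattr(self, name)
            if val != "default" and not Path(val).exists():
                raise ConfigError(f"{name}: path does not exist: {val}")

    def config_hash(self) -> str:
        # hash only fields that affect results, not where they are written
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("out_dir", "verbosity")
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    # --- materialized objects ---

    def panel(self) -> ProbePanel:
        if self.probe_panel == "default":
            return default_probe_panel()
        return load_probe_panel(self.probe_panel)

    def loops(self) -> LoopAnnotation:
        if self.loop_annotation == "default":
            return default_loop_annotation()
        with open(self.loop_annotation) as fh:
            raw = yaml.safe_load(fh)
        try:
            return LoopAnnotation(
                chrom=raw["chrom"],
                boundaries=tuple(raw["boundaries"]),
                labels=tuple(raw["labels"]),
                genes=tuple(tuple(g) for g in raw.get("genes", ())),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"loop_annotation: {exc}") from exc

    def model(self) -> DistanceModel:
        mu = dict(_DEFAULT_MU)
        overrides = self.distance_model.get("mu", {})
        for tag, by_geno in overrides.items():
            pair = parse_pair(str(tag))
            for geno, val in by_geno.items():
                mu[(pair, geno)] = float(val)
        try:
            return DistanceModel(
                mu=mu,
                tau=float(self.distance_model.get("tau", 0.0)),
                sigma_loc=float(self.distance_model.get("sigma_loc", 0.0)),
            )
        except ValueError as exc:
            raise ConfigError(f"distance_model: {exc}") from exc

    def nucleus_config(self) -> NucleusConfig:
        try:
            return NucleusConfig(**self.nucleus)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"nucleus: {exc}") from exc

    def header_comments(self) -> list[str]:
        return [f"config_hash={self.config_hash()} seed={self.seed}"]


def load_config(path: str | Path | None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides (flags win)."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
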