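"""Run configuration: one serialisable object covering every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gdp_filter import GdpThresholds
from .synthetic import GeneratorConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run depends on, fully serialisable."""

    generator: GeneratorConfig = GeneratorConfig()
    thresholds: GdpThresholds = GdpThresholds()
    max_gap_s: float = 120.0
    iso_levels: tuple[float, ...] = (280.0, 330.0, 380.0)
    iso_tolerance: float = 10.0
    recommend_hb_grid: tuple[float, float, float] = (6.0, 14.0, 0.5)  # start, stop, step
    output_dir: str = "gdp_run"
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "RunConfig":
        gen = dataclasses.replace(self.generator, seed=seed)
        return dataclasses.replace(self, generator=gen, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _tupled(cls, d: dict):
    """Build a dataclass from a dict, coercing list fields back to tuples."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; omitted keys keep defaults."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    gen = _tupled(GeneratorConfig, data.get("generator", {}))
    thr = _tupled(GdpThresholds, data.get("thresholds", {}))
    top = {k: (tuple(v) if isinstance(v, list) else v)
           for k, v in data.items() if k not in ("generator", "thresholds")}
    top.update(overrides)
    cfg = RunConfig(generator=gen, thresholds=thr, **top)
    if "seed" in data or "seed" in overrides:
        cfg = cfg.with_seed(cfg.seed)
    return cfg


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def config_hash(config: RunConfig) -> str:
    """Stable content hash of a configuration, for the run manifest."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
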