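"""Pipeline configuration: one YAML file, strict keys, stable seed fan-out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .classifier import TrainConfig
from .envelope import MOMENT_MAP_WINDOW_MM, NORMALIZATION_WINDOW_MM
from .roi import ROISpec
from .synthetic import CohortSpec


def _from_mapping(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where}")
    cleaned = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**cleaned)


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, loadable from a single YAML file."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    roi: ROISpec = field(default_factory=ROISpec)
    train: TrainConfig = field(default_factory=TrainConfig.small)
    norm_window_mm: tuple[float, float] = NORMALIZATION_WINDOW_MM
    map_window_mm: tuple[float, float] = MOMENT_MAP_WINDOW_MM
    input_size_px: tuple[int, int] = (32, 32)
    outdir: str = "esgrade_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys {sorted(unknown)}")
        kwargs = {}
        for key, sub in (("cohort", CohortSpec), ("roi", ROISpec),
                         ("train", TrainConfig)):
            if key in data:
                kwargs[key] = _from_mapping(sub, data[key] or {}, key)
        for key in ("norm_window_mm", "map_window_mm", "input_size_px"):
            if key in data:
                kwargs[key] = tuple(data[key])
        for key in ("outdir", "seed"):
            if key in data:
                kwargs[key] = data[key]
        cfg = cls(**kwargs)
        return cfg.with_seed(cfg.seed)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Fan the global seed out to per-stage seeds by stable hashing, so
        each stage is independently reproducible from the global seed."""
        self.seed = int(seed)
        self.cohort.seed = derive_seed(seed, "cohort")
        self.roi.seed = derive_seed(seed, "roi")
        self.train.seed = derive_seed(seed, "train")
        return self

    def hash(self) -> str:
        payload = {
            "cohort": asdict(self.cohort),
            "roi": asdict(self.roi),
            "train": asdict(self.train),
            "norm_window_mm": self.norm_window_mm,
            "map_window_mm": self.map_window_mm,
            "input_size_px": self.input_size_px,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
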