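"""Pipeline configuration: defaults, YAML loading and provenance echo."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import json
from pathlib import Path

import yaml

from .augment import AugmentationSpec
from .lstm import LstmConfig

__all__ = ["PipelineConfig", "load_config", "echo_config"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults matching the
    reference experiment (3-s windows, 50 % overlap, 512-point FFT
    blocks at 50 Hz, S = L = 25)."""

    fs: float = 50.0
    window_seconds: float = 3.0
    overlap_fraction: float = 0.5
    fft_length: int = 512
    segment_length: int | None = None  # None → min(window, 128)
    hop: int | None = None             # None → segment_length // 2
    S: int = 25
    L: int = 25
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    lstm: LstmConfig = field(default_factory=LstmConfig)
    sweep_rates: tuple[float, ...] = (0.0002, 0.003, 0.006, 0.01, 0.015)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["lstm"].get("sequence_reshape") is not None:
            d["lstm"]["sequence_reshape"] = list(d["lstm"]["sequence_reshape"])
        d["sweep_rates"] = list(self.sweep_rates)
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """PipelineConfig from a YAML file; missing keys keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    aug_kwargs = raw.pop("augmentation", {})
    lstm_kwargs = raw.pop("lstm", {})
    if "sequence_reshape" in lstm_kwargs and lstm_kwargs["sequence_reshape"] is not None:
        lstm_kwargs["sequence_reshape"] = tuple(lstm_kwargs["sequence_reshape"])
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "sweep_rates" in raw:
        raw["sweep_rates"] = tuple(raw["sweep_rates"])
    return PipelineConfig(
        augmentation=AugmentationSpec(**aug_kwargs),
        lstm=LstmConfig(**lstm_kwargs),
        **raw,
    )


def echo_config(cfg: PipelineConfig, out_dir: str | Path,
                seeds: list[int] | None = None) -> Path:
    """Write the effective configuration (and seeds used) into an output
    directory so every artefact carries full provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": cfg.to_dict()}
    if seeds is not None:
        payload["seeds"] = list(seeds)
    path = out_dir / "effective_config.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
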