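"""Run configuration: every tunable of the pipeline in one YAML-serialisable object."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .features import BandScheme
from .model import EncoderConfig, TrainConfig
from .postprocess import PostprocessParams
from .synthdata import NoiseSpec, SeizureSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables; round-trips losslessly through YAML."""

    bands: BandScheme = field(default_factory=BandScheme)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seizures: SeizureSpec = field(default_factory=SeizureSpec)
    split_ratio: float = 0.75
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        # tuples -> lists for clean YAML; restored on load
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(doc), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            bands=BandScheme(
                bands=tuple(tuple(b) for b in doc["bands"]["bands"]),
                n_time_blocks=doc["bands"]["n_time_blocks"],
            ),
            encoder=EncoderConfig(**doc["encoder"]),
            training=TrainConfig(**doc["training"]),
            postprocess=PostprocessParams(**doc["postprocess"]),
            noise=NoiseSpec(**doc["noise"]),
            seizures=SeizureSpec(
                **{
                    **doc["seizures"],
                    "duration_range_s": tuple(doc["seizures"]["duration_range_s"]),
                    "freq_range_hz": tuple(doc["seizures"]["freq_range_hz"]),
                    "times": (
                        tuple(tuple(t) for t in doc["seizures"]["times"])
                        if doc["seizures"]["times"] is not None
                        else None
                    ),
                }
            ),
            split_ratio=doc["split_ratio"],
            seed=doc["seed"],
        )


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj
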