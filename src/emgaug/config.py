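"""Run configuration and seed management.

A single global seed is fanned out to named substreams (data sampling,
weight initialization, latent draws, ...), so individual randomness
sources can be ablated without disturbing the others, and identical
configurations reproduce identical artifacts.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = ["substream", "RunConfig"]


def substream(seed: int, name: str) -> np.random.Generator:
    """A named random substream derived from the global seed."""
    return np.random.default_rng([int(seed) % (2 ** 31),
                                  zlib.crc32(name.encode())])


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see :func:`emgaug.pipeline.run_pipeline`).

    The defaults describe a reduced-scale but complete run: synthesize
    tremor and movement records, train a GAN variant on the tremor
    record, generate samples, score them, and optionally run style
    transfer using the trained discriminator as feature extractor.
    """

    seed: int = 0
    out_dir: str = "emgaug-run"
    rate: float = 2000.0
    # synthetic data
    tremor_freq: float = 5.0
    tremor_duration_s: float = 16.0
    movement_repetitions: int = 2
    # GAN stage
    variant: str = "4CNN-MBD-MA"
    epochs: int = 100
    batch_size: int = 16
    gen_filters: int = 8
    disc_filters: int = 8
    disc_final_filters: int = 8
    learning_rate: float = 0.002
    metric_every: int = 0
    n_generate: int = 10
    # style stage
    run_style: bool = False
    style_window_len: int = 4000
    style_epochs: int = 5
    style_iters_per_epoch: int = 50
    w_sty: float = 2.0
    w_cont: float = 2.0
    eps_cs: float = 0.1
    alpha_cs: float = 10.0
    style_init: str = "content"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys {sorted(unknown)} in {path}")
        return cls(**raw)
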