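"""Declarative YAML configuration for the pipeline CLI."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from .classifier import TrainConfig
from .pipeline import PipelineConfig
from .synth import CohortConfig, EffectProfile, NoiseProfile


def load_config(path: str | Path | None = None, *, seed: int | None = None,
                preset: str | None = None,
                modalities: tuple[str, ...] | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus CLI overrides.

    The YAML mirrors the dataclass structure; unknown keys raise. A missing
    file yields the defaults.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}

    cohort_raw = raw.pop("cohort", {})
    noise_raw = cohort_raw.pop("noise", {})
    effects_raw = cohort_raw.pop("effects", {})

    effects = EffectProfile()
    if effects_raw.pop("null", False):
        effects = EffectProfile.null()
    if effects_raw:
        effects = replace(effects, **{k: np.asarray(v, dtype=float)
                                      for k, v in effects_raw.items()})
    noise = NoiseProfile(**noise_raw)
    cohort = CohortConfig(effects=effects, noise=noise, **cohort_raw)

    train_raw = raw.pop("train", {})
    train = TrainConfig(epochs=10, batch_size=32)
    if train_raw:
        train = replace(train, **train_raw)

    if "modalities" in raw:
        raw["modalities"] = tuple(raw["modalities"])
    config = PipelineConfig(cohort=cohort, train=train, **raw)

    if seed is not None:
        config = replace(config, cohort=replace(cohort, seed=seed), seed=seed)
    if preset is not None:
        config = replace(config, preset=preset)
    if modalities is not None:
        config = replace(config, modalities=modalities)
    return config
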