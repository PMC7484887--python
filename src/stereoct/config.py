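"""Flat YAML configuration shared by the CLI subcommands.

One namespace covers every tunable: ``phantom.*``, ``factors.*``,
``transform.*``, ``merge.*``, ``artifact.*`` and ``study.*``.  Values merge
in order defaults → YAML file → command-line overrides, and the resolved
mapping is written alongside every run's outputs for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .experiment import DEFAULT_ANGLES, STUDY_GRID_SHAPE, STUDY_SPACING, StudyConfig
from .merge import MergeConfig
from .phantom import ArtifactModel, PhantomSpec
from .tilt import FACTOR_TABLE, TransformSpec

DEFAULTS: dict = {
    "phantom.spacing": list(PhantomSpec.spacing),
    "phantom.grid_shape": list(PhantomSpec.grid_shape),
    "phantom.amalgam": True,
    "factors.source": "geometric",
    "factors.table": {str(k): list(v) for k, v in FACTOR_TABLE.items()},
    "transform.fill_hu": -1000.0,
    "transform.single_resample": True,
    "merge.metal_threshold_hu": 2000.0,
    "merge.reference_mismatch_tol": 2,
    "artifact.streak_amplitude_hu": ArtifactModel.streak_amplitude_hu,
    "artifact.n_streaks": ArtifactModel.n_streaks,
    "artifact.decay_mm": ArtifactModel.decay_mm,
    "artifact.dark_band_hu": ArtifactModel.dark_band_hu,
    "artifact.dark_band_width_mm": ArtifactModel.dark_band_width_mm,
    "artifact.noise_sd_hu": ArtifactModel.noise_sd_hu,
    "study.angles": list(DEFAULT_ANGLES),
    "study.grid_shape": list(STUDY_GRID_SHAPE),
    "study.spacing": list(STUDY_SPACING),
    "seed": 0,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional YAML file and explicit overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            cfg[key] = value
    return cfg


def transform_spec(cfg: dict) -> TransformSpec:
    table = tuple(
        (int(angle), (float(pair[0]), float(pair[1])))
        for angle, pair in sorted(cfg["factors.table"].items(), key=lambda kv: int(kv[0]))
    )
    return TransformSpec(
        fill_hu=float(cfg["transform.fill_hu"]),
        source=str(cfg["factors.source"]),
        single_resample=bool(cfg["transform.single_resample"]),
        factor_table=table,
    )


def merge_config(cfg: dict) -> MergeConfig:
    return MergeConfig(
        metal_threshold_hu=float(cfg["merge.metal_threshold_hu"]),
        reference_mismatch_tol=int(cfg["merge.reference_mismatch_tol"]),
    )


def artifact_model(cfg: dict) -> ArtifactModel:
    return ArtifactModel(
        streak_amplitude_hu=float(cfg["artifact.streak_amplitude_hu"]),
        n_streaks=int(cfg["artifact.n_streaks"]),
        decay_mm=float(cfg["artifact.decay_mm"]),
        dark_band_hu=float(cfg["artifact.dark_band_hu"]),
        dark_band_width_mm=float(cfg["artifact.dark_band_width_mm"]),
        noise_sd_hu=float(cfg["artifact.noise_sd_hu"]),
        metal_threshold_hu=float(cfg["merge.metal_threshold_hu"]),
        seed=int(cfg["seed"]),
    )


def phantom_spec(cfg: dict, amalgam: bool | None = None) -> PhantomSpec:
    return PhantomSpec(
        amalgam=bool(cfg["phantom.amalgam"] if amalgam is None else amalgam),
        spacing=tuple(cfg["phantom.spacing"]),
        grid_shape=tuple(cfg["phantom.grid_shape"]),
    )


def study_config(cfg: dict) -> StudyConfig:
    return StudyConfig(
        grid_shape=tuple(cfg["study.grid_shape"]),
        spacing=tuple(cfg["study.spacing"]),
        angles=tuple(float(a) for a in cfg["study.angles"]),
        seed=int(cfg["seed"]),
        artifact=artifact_model(cfg),
        merge=merge_config(cfg),
        transform=transform_spec(cfg),
    )


def dump_resolved(cfg: dict, path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=1, sort_keys=True))
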