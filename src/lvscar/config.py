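"""Single YAML experiment configuration with per-module sections.

Every tolerance and protocol default is named here so a run is fully
described by one file plus a seed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .classifier import SwarmConfig, TrainConfig
from .nn import FocalLossParams, NetworkSpec
from .synthetic import CohortSpec, ScarSpec

__all__ = [
    "default_config",
    "load_config",
    "train_config_from",
    "cohort_spec_from",
    "network_spec_from",
    "swarm_config_from",
]

DEFAULTS = {
    "geometry": {
        "n_slices": 25,
        "apex_offset": 0.20,
        "mask_size": 256,
        "resolution_mm": 1.0,
        "min_pixels": 50,
        "valve_clearance_mm": 2.0,
        "slice_jitter": False,
    },
    "polar": {
        "radial_resolution_mm": 1.0,
        "angular_steps": 256,
    },
    "synthetic": {
        "n_patients": 60,
        "scar_prevalence": 0.5,
        "size_range": [80.0, 100.0],
        "wall_thickness_range": [8.0, 12.0],
        "modality_perturbation": 0.19,
        "scar": {
            "angular_extent": 75.0,
            "axial_extent": 0.35,
            "thinning_factor": 0.5,
            "shape_noise": 0.02,
        },
    },
    "registration": {
        "max_iterations": 200,
        "tolerance_mm": 1.0e-4,
        "translation_only": False,
    },
    "train": {
        "architecture": "vgg_small",
        "learning_rate": 0.009,
        "momentum": 0.73,
        "batch_size": 10,
        "epochs": 100,
        "final_epochs": 500,
        "gamma": 1.560,
        "alpha": 0.6,
        "prediction_threshold": 0.5,
        "cv_folds": 10,
        "augment_shift": False,
        "oversample": False,
    },
    "tune": {
        "n_particles": 20,
        "iterations": 30,
        "inertia": 0.729,
        "cognitive": 1.49445,
        "social": 1.49445,
        "tuning_epochs": 10,
        "bounds": {
            "learning_rate": [1.0e-4, 0.05],
            "momentum": [0.5, 0.95],
            "batch_size": [4, 32],
            "gamma": [0.0, 3.0],
            "alpha": [0.1, 0.9],
        },
    },
    "evaluation": {
        "n_boot": 2000,
        "band": "percentile",
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Defaults overlaid with the YAML file at ``path`` (when given)."""
    cfg = default_config()
    if path is not None:
        with open(Path(path)) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return cfg


def train_config_from(cfg: dict, seed: int = 0, epochs=None) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(
        learning_rate=t["learning_rate"],
        momentum=t["momentum"],
        batch_size=t["batch_size"],
        epochs=epochs if epochs is not None else t["epochs"],
        loss=FocalLossParams(gamma=t["gamma"], alpha=t["alpha"]),
        seed=seed,
        prediction_threshold=t["prediction_threshold"],
        augment_shift=t["augment_shift"],
        oversample=t["oversample"],
    )


def network_spec_from(cfg: dict) -> NetworkSpec:
    return NetworkSpec(
        architecture=cfg["train"]["architecture"],
        input_size=cfg["geometry"]["mask_size"],
    )


def cohort_spec_from(cfg: dict, seed: int = 0) -> CohortSpec:
    s = cfg["synthetic"]
    return CohortSpec(
        n_patients=s["n_patients"],
        scar_prevalence=s["scar_prevalence"],
        size_range=tuple(s["size_range"]),
        wall_thickness_range=tuple(s["wall_thickness_range"]),
        scar_spec=ScarSpec(
            angular_extent=s["scar"]["angular_extent"],
            axial_extent=s["scar"]["axial_extent"],
            thinning_factor=s["scar"]["thinning_factor"],
            shape_noise=s["scar"]["shape_noise"],
        ),
        modality_perturbation=s["modality_perturbation"],
        seed=seed,
    )


def swarm_config_from(cfg: dict, seed: int = 0) -> SwarmConfig:
    t = cfg["tune"]
    return SwarmConfig(
        n_particles=t["n_particles"],
        iterations=t["iterations"],
        inertia=t["inertia"],
        cognitive=t["cognitive"],
        social=t["social"],
        bounds={k: tuple(v) for k, v in t["bounds"].items()},
        seed=seed,
    )
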