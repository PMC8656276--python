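"""YAML run-configuration loading and the run manifest.

The config schema mirrors the shipped ``data/default_config.yaml``:
``population.size``, ``exposure.*`` tier sizes, ``media.*`` preference and
hours parameters, ``risk.*`` dose-response parameters, ``calibration.
targets.*`` and ``experiment.*`` (replicates, scenarios, seed).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exposure import ExposureConfig
from .media import HoursDistribution, MediaPreferenceParams
from .risk import CalibrationTargets, RiskParams
from .runner import ExperimentConfig, replicate_seed
from .scenarios import ScenarioSpec
from .synthpop import default_marginals

__all__ = ["load_config", "default_config_dict", "experiment_from_config",
           "calibration_targets_from_config", "write_manifest"]

_ALLOWED_TOP = {"population", "exposure", "media", "risk", "calibration", "experiment"}


def default_config_dict() -> dict:
    """The shipped default configuration as a plain dict."""
    ref = resources.files("ptsdsim.data") / "default_config.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON config, layered over the shipped defaults."""
    cfg = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - _ALLOWED_TOP
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def experiment_from_config(
    cfg: dict,
    scenario: str | None = None,
    engagement: str | None = None,
    replicates: int | None = None,
    seed: int | None = None,
) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a config dict, with optional
    CLI-style overrides."""
    media = cfg.get("media", {})
    risk = cfg.get("risk", {})
    exp = cfg.get("experiment", {})
    eng = engagement if engagement is not None else media.get("engagement", "none")
    if scenario is not None:
        specs = [ScenarioSpec(id=scenario, engagement=eng)]
    else:
        specs = [
            ScenarioSpec(id=s, engagement=eng)
            for s in exp.get("scenarios", ["baseline"])
        ]
    return ExperimentConfig(
        size=int(cfg.get("population", {}).get("size", 118_000)),
        marginals=default_marginals(),
        exposure=ExposureConfig(**cfg.get("exposure", {})),
        media=MediaPreferenceParams(
            tv_preference_fraction=float(media.get("tv_preference_fraction", 0.3969)),
            by_age=media.get("tv_preference_by_age") or None,
        ),
        hours=HoursDistribution(tuple(media.get("hours_weights", (0.112, 0.131, 0.108, 0.649)))),
        risk=RiskParams(
            p=tuple(risk.get("p", RiskParams().p)),
            m_casual=float(risk.get("m_casual", RiskParams().m_casual)),
            m_video=float(risk.get("m_video", RiskParams().m_video)),
            cap=float(risk.get("cap", 1.0)),
        ),
        scenarios=tuple(specs),
        replicates=int(replicates if replicates is not None else exp.get("replicates", 50)),
        master_seed=int(seed if seed is not None else exp.get("seed", 1)),
    )


def calibration_targets_from_config(cfg: dict) -> CalibrationTargets:
    targets = cfg.get("calibration", {}).get("targets", {})
    return CalibrationTargets(**targets) if targets else CalibrationTargets()


def write_manifest(config: ExperimentConfig, outdir: str | Path) -> str:
    """JSON run manifest: config hash, per-replicate seeds, library versions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_repr = {
        "size": config.size,
        "exposure": asdict(config.exposure),
        "media": {
            "tv_preference_fraction": config.media.tv_preference_fraction,
            "by_age": config.media.by_age,
        },
        "hours_weights": list(config.hours.weights),
        "risk": asdict(config.risk),
        "scenarios": [
            {"id": s.id, "engagement": s.engagement} for s in config.scenarios
        ],
        "replicates": config.replicates,
        "master_seed": config.master_seed,
    }
    blob = json.dumps(cfg_repr, sort_keys=True).encode()
    manifest = {
        "config": cfg_repr,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": {
            s.label: [
                replicate_seed(config.master_seed, s, r)
                for r in range(config.replicates)
            ]
            for s in config.scenarios
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return str(path)
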