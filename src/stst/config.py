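"""Run configuration: YAML/JSON parsing, validation and model construction.

The default values reproduce the reference hyperparameters: octaves
(-2, -1, 0) with scale 1.5, iterations (250, 750, 1000), learning rates
(0.001, 0.003, 0.005), TV weights (0.05, 0.1, 0.5), texture weights
beta = lam = 1, blending ratio phi = 0.95 and xi = 5 padding frames.
Seeds are mandatory in config files: no silent nondeterminism.
"""

from __future__ import annotations

import hashlib
import json
import os

import yaml

from .losses import ConfigError, LossSpec
from .synthesis import OctaveSchedule, SynthesisConfig
from .twostream import StreamModel, get_model

_TOP_KEYS = {"seed", "targets", "models", "loss", "schedule", "phi", "xi",
             "color_transfer", "color_reference", "color_iterations", "output"}
_LOSS_KEYS = {"alpha", "beta", "theta", "lam", "omega", "spatial_layers",
              "temporal_layers", "routing"}
_SCHED_KEYS = {"octaves", "sigma", "iterations", "learning_rates", "tv_weights"}
_MODEL_KEYS = {"name", "seed", "weights", "arity", "n_scales", "gain"}


def load_config(path: str) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) if not path.endswith(".json") else json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return raw


def _check_keys(section: dict, allowed: set, where: str) -> None:
    bad = sorted(set(section) - allowed)
    if bad:
        raise ConfigError(f"unknown key(s) in {where}: {bad}")


def parse_config(raw: dict) -> tuple[SynthesisConfig, dict, dict]:
    """Validate a raw config mapping.

    Returns (SynthesisConfig, target paths {id: path}, model specs).
    """
    _check_keys(raw, _TOP_KEYS, "config")
    if "seed" not in raw:
        raise ConfigError("config must state a seed explicitly")
    loss_raw = dict(raw.get("loss", {}))
    _check_keys(loss_raw, _LOSS_KEYS, "loss")
    spec = LossSpec(**loss_raw)
    sched_raw = dict(raw.get("schedule", {}))
    _check_keys(sched_raw, _SCHED_KEYS, "schedule")
    schedule = OctaveSchedule(**sched_raw)
    cfg = SynthesisConfig(
        loss_spec=spec,
        schedule=schedule,
        phi=float(raw.get("phi", 0.95)),
        xi=int(raw.get("xi", 5)),
        seed=int(raw["seed"]),
        color_transfer=bool(raw.get("color_transfer", True)),
        color_reference=raw.get("color_reference"),
        color_iterations=int(raw.get("color_iterations", 20)),
    )
    targets = dict(raw.get("targets", {}))
    if not targets:
        raise ConfigError("config must name at least one target video")
    missing = {spec.routed_target(t) for t in spec.active_terms} - set(targets)
    if missing:
        raise ConfigError(f"routing points at undeclared target(s): {sorted(missing)}")
    models_raw = raw.get("models", {"spatial": {"name": "vgg19"}, "temporal": {"name": "msoe"}})
    for stream, m in models_raw.items():
        if stream not in ("spatial", "temporal"):
            raise ConfigError(f"unknown model stream '{stream}'")
        _check_keys(m, _MODEL_KEYS, f"models.{stream}")
    return cfg, targets, models_raw


def build_models(models_raw: dict, seed: int) -> dict[str, StreamModel]:
    out = {}
    for stream, m in models_raw.items():
        kwargs = {k: v for k, v in m.items() if k not in ("name", "seed", "weights")}
        if stream == "temporal" and m.get("name") == "fixture":
            kwargs.setdefault("arity", 2)
        out[stream] = get_model(
            m["name"], seed=int(m.get("seed", seed)),
            weights_path=m.get("weights") if m.get("name") == "vgg19" else None,
            **kwargs,
        )
    return out


def config_hash(raw: dict) -> str:
    return hashlib.sha256(json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(out_dir: str, raw: dict, extra: dict | None = None) -> str:
    manifest = {"config_hash": config_hash(raw), "seed": raw.get("seed"), "config": raw}
    manifest.update(extra or {})
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
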