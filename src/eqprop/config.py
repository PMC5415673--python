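"""YAML run configuration: flat keys mirroring the training and relaxation
settings, plus shipped presets for the benchmark architectures."""

from __future__ import annotations

import yaml

from .relaxation import RelaxationConfig
from .learning import TrainConfig

__all__ = ["DEFAULT_CONFIG", "PRESETS", "load_config", "save_config",
           "build_train_config"]

DEFAULT_CONFIG: dict = {
    "architecture": [10, 20, 3],
    "n_iter_free": 20,
    "n_iter_nudged": 4,
    "epsilon": 0.5,
    "beta": 1.0,
    "learning_rates": [0.1, 0.05],
    "minibatch_size": 20,
    "n_epochs": 25,
    "seed": 0,
    "random_beta_sign": True,
    "persistent_particles": True,
    "activation": "hard_sigmoid",
    "l2_penalty": 0.0,
    "data": {
        "kind": "clusters",
        "n_classes": 3,
        "n_per_class": [267, 267, 266],
        "n_features": 10,
        "spread": 0.05,
        "valid_fraction": 0.25,
    },
}

# Benchmark hyperparameter presets: per-architecture phase durations, step
# size, clamping factor and per-layer rates.
PRESETS: dict[str, dict] = {
    "784-500-10": {
        "architecture": [784, 500, 10],
        "n_iter_free": 20, "n_iter_nudged": 4, "epsilon": 0.5, "beta": 1.0,
        "learning_rates": [0.1, 0.05],
    },
    "784-500-500-10": {
        "architecture": [784, 500, 500, 10],
        "n_iter_free": 100, "n_iter_nudged": 6, "epsilon": 0.5, "beta": 1.0,
        "learning_rates": [0.4, 0.1, 0.01],
    },
    "784-500-500-500-10": {
        "architecture": [784, 500, 500, 500, 10],
        "n_iter_free": 500, "n_iter_nudged": 8, "epsilon": 0.5, "beta": 1.0,
        "learning_rates": [0.128, 0.032, 0.008, 0.002],
    },
}


def load_config(path) -> dict:
    """Read a YAML config, filling unset keys from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    cfg = {**DEFAULT_CONFIG, **user}
    if "data" in user and isinstance(user["data"], dict):
        kind = user["data"].get("kind", "clusters")
        if kind == "clusters":
            cfg["data"] = {**DEFAULT_CONFIG["data"], **user["data"]}
        else:
            cfg["data"] = dict(user["data"])
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def build_train_config(cfg: dict, seed: int | None = None) -> TrainConfig:
    """Translate a flat config mapping into a :class:`TrainConfig`."""
    free = RelaxationConfig(epsilon=float(cfg["epsilon"]),
                            n_iter=int(cfg["n_iter_free"]))
    nudged = RelaxationConfig(epsilon=float(cfg["epsilon"]),
                              n_iter=int(cfg["n_iter_nudged"]))
    return TrainConfig(
        beta_magnitude=float(cfg["beta"]),
        random_beta_sign=bool(cfg["random_beta_sign"]),
        layer_rates=tuple(float(r) for r in cfg["learning_rates"]),
        minibatch_size=int(cfg["minibatch_size"]),
        n_epochs=int(cfg["n_epochs"]),
        seed=int(cfg["seed"] if seed is None else seed),
        persistent_particles=bool(cfg["persistent_particles"]),
        free_config=free,
        nudged_config=nudged,
        l2_penalty=float(cfg["l2_penalty"]),
        activation=str(cfg["activation"]),
    )
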