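"""High-level modelling interface: an :class:`EquilibriumPropagation` model
built from data whose ``fit()`` returns an :class:`EqPropResults` carrying
the trained parameters, the per-epoch metrics history and a summary table.
"""

from __future__ import annotations

import io
import json

import numpy as np
import pandas as pd

from .data import Dataset
from .energy import NetworkParams, load_params, save_params
from .learning import ParticleStore, TrainConfig, evaluate, fit
from .relaxation import RelaxationConfig, predict as _predict

__all__ = ["EquilibriumPropagation", "EqPropResults"]


class EquilibriumPropagation:
    """A layered symmetric-weight energy network trained by the two-phase
    contrastive rule.

    Parameters
    ----------
    dataset : Dataset
        Supervised examples with train/valid split tags; features must lie
        in [0, 1], targets are one-hot.
    hidden_sizes : sequence of int
        Hidden layer widths, inputs and outputs are taken from the data.
    """

    def __init__(self, dataset: Dataset, hidden_sizes=(20,)):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.dataset = dataset
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.layer_sizes = (dataset.n_features, *self.hidden_sizes,
                            dataset.n_classes)

    @classmethod
    def from_arrays(cls, features, labels, n_classes=None, hidden_sizes=(20,),
                    valid_fraction=0.0):
        """Build the model from raw feature/label arrays."""
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if n_classes is None:
            n_classes = int(labels.max()) + 1
        one_hot = np.zeros((labels.size, n_classes))
        one_hot[np.arange(labels.size), labels] = 1.0
        split = np.array(["train"] * labels.size, dtype=object)
        n_valid = int(round(valid_fraction * labels.size))
        if n_valid:
            split[labels.size - n_valid:] = "valid"
        return cls(Dataset(features, labels, one_hot, split),
                   hidden_sizes=hidden_sizes)

    def fit(self, config: TrainConfig | None = None,
            init_params: NetworkParams | None = None,
            store: ParticleStore | None = None, start_epoch: int = 0,
            **overrides) -> "EqPropResults":
        """Train and return the results object. Keyword overrides are
        applied on top of the given (or default) :class:`TrainConfig`."""
        if config is None:
            config = TrainConfig()
        if overrides:
            from dataclasses import replace
            config = replace(config, **overrides)
        params, history, store = fit(
            self.dataset, self.layer_sizes, config,
            init_params=init_params, store=store, start_epoch=start_epoch)
        return EqPropResults(self, params, history, config, store)


class EqPropResults:
    """Trained parameters plus diagnostics of the run that produced them."""

    def __init__(self, model: EquilibriumPropagation | None,
                 params: NetworkParams, history: pd.DataFrame,
                 config: TrainConfig, store: ParticleStore | None = None):
        self.model = model
        self.params = params
        self.history = history
        self.config = config
        self.store = store

    def predict(self, features) -> np.ndarray:
        """Free-phase class predictions for a batch of inputs."""
        return np.atleast_1d(_predict(self.params, np.asarray(features, float),
                                      self.config.activation,
                                      self.config.free_config))

    def error_rate(self, features, labels) -> float:
        """Stateless misclassification rate on the given examples."""
        preds = self.predict(features)
        return float(np.mean(preds != np.asarray(labels, dtype=int)))

    def evaluate(self, dataset: Dataset) -> float:
        err, _ = evaluate(self.params, dataset, self.config.activation,
                          self.config.free_config)
        return err

    def summary(self) -> str:
        """Plain-text run summary in the spirit of a fitted-model report."""
        buf = io.StringIO()
        arch = "-".join(str(s) for s in self.params.layer_sizes)
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Equilibrium Propagation results",
            "=" * 46,
            f"{'Architecture:':<28}{arch}",
            f"{'Activation:':<28}{self.config.activation}",
            f"{'Clamping factor |beta|:':<28}{self.config.beta_magnitude}",
            f"{'Random beta sign:':<28}{self.config.random_beta_sign}",
            f"{'Step size epsilon:':<28}{self.config.free_config.epsilon}",
            f"{'Free-phase iterations:':<28}{self.config.free_config.n_iter}",
            f"{'Learning rates:':<28}"
            f"{tuple(self.config.layer_rates)}",
            f"{'Minibatch size:':<28}{self.config.minibatch_size}",
            f"{'Epochs run:':<28}{len(self.history)}",
        ]
        if last is not None:
            lines += [
                "-" * 46,
                f"{'Final train error:':<28}{last['train_error']:.4f}",
                f"{'Final valid error:':<28}{last['valid_error']:.4f}",
                f"{'Final mean cost:':<28}{last['mean_cost']:.6f}",
                f"{'Final mean energy:':<28}{last['mean_energy']:.4f}",
            ]
        buf.write("\n".join(lines))
        return buf.getvalue()

    def save(self, path) -> None:
        """Checkpoint: parameters, config, history and particles in one
        archive, sufficient to resume training bit-identically."""
        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg["free_config"] = asdict(self.config.free_config)
        cfg["nudged_config"] = (asdict(self.config.nudged_config)
                                if self.config.nudged_config else None)
        extra = {
            "config": cfg,
            "n_epochs_done": int(self.history["epoch"].max() + 1)
            if len(self.history) else 0,
            "history": self.history.to_csv(index=False),
        }
        arrays = {}
        if self.store is not None:
            sd = self.store.state_dict()
            arrays = {f"particle_{k}": v for k, v in sd.items()}
        save_params(path, self.params, activation=self.config.activation,
                    extra=extra, **arrays)

    @classmethod
    def load(cls, path) -> "EqPropResults":
        params, data = load_params(path)
        header = data["header"]
        cfg_dict = header["config"]
        free = RelaxationConfig(**cfg_dict.pop("free_config"))
        nudged_dict = cfg_dict.pop("nudged_config")
        nudged = RelaxationConfig(**nudged_dict) if nudged_dict else None
        cfg_dict["layer_rates"] = tuple(cfg_dict["layer_rates"])
        config = TrainConfig(free_config=free, nudged_config=nudged,
                             **cfg_dict)
        history = pd.read_csv(io.StringIO(header["history"]),
                              float_precision="round_trip") \
            if header["history"].strip() else pd.DataFrame()
        sd = {k[len("particle_"):]: v for k, v in data.items()
              if k.startswith("particle_")}
        store = ParticleStore.from_state_dict(sd) if sd else ParticleStore()
        return cls(None, params, history, config, store)
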