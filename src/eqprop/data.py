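"""Synthetic datasets, seeded network fixtures, and the IDX (MNIST) reader.

Everything the test suites need is generated here at desk scale; the IDX
reader exists so the full MNIST replication can be run from local files,
but no download logic is provided.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .energy import NetworkParams, WorldInput
from .relaxation import init_state

__all__ = [
    "Dataset",
    "make_clusters",
    "make_fixture_network",
    "layered_mask",
    "glorot_weights",
    "read_idx",
    "IdxFormatError",
    "IdxCountMismatchError",
]


@dataclass
class Dataset:
    """Supervised examples: features in [0, 1], integer labels, one-hot
    targets, and a train/valid split tag per row."""

    features: np.ndarray
    labels: np.ndarray
    one_hot: np.ndarray
    split: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.one_hot = np.asarray(self.one_hot, dtype=float)
        self.split = np.asarray(self.split)

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return self.one_hot.shape[1]

    def subset(self, tag: str) -> "Dataset":
        m = self.split == tag
        return Dataset(self.features[m], self.labels[m], self.one_hot[m],
                       self.split[m])

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.features,
                          columns=[f"x{i}" for i in range(self.n_features)])
        df["label"] = self.labels
        df["split"] = self.split
        df.to_csv(path, index=False)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    oh = np.zeros((labels.size, n_classes))
    oh[np.arange(labels.size), labels] = 1.0
    return oh


def make_clusters(n_classes: int = 3, n_per_class=200,
                  n_features: int = 10, spread: float = 0.05,
                  seed: int = 0, valid_fraction: float = 0.25) -> Dataset:
    """Gaussian-ish class clusters in the unit hypercube.

    Class centers are drawn uniformly in [0.2, 0.8]^n so the noise rarely
    clips; features are clipped to [0, 1] regardless. Deterministic per
    seed. ``n_per_class`` may be a single count or one count per class.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.2, 0.8, size=(n_classes, n_features))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    feats = centers[labels] + rng.normal(scale=spread,
                                         size=(labels.size, n_features))
    feats = np.clip(feats, 0.0, 1.0)
    order = rng.permutation(labels.size)
    feats, labels = feats[order], labels[order]
    n_valid = int(round(valid_fraction * labels.size))
    split = np.array(["train"] * labels.size, dtype=object)
    split[labels.size - n_valid:] = "valid"
    return Dataset(feats, labels, _one_hot(labels, n_classes), split)


def layered_mask(layer_sizes) -> np.ndarray:
    """Connectivity of a layered net: consecutive layers fully connected,
    no skip-layer connections, no lateral connections within a layer."""
    n = int(sum(layer_sizes))
    mask = np.zeros((n, n), dtype=bool)
    edges = np.cumsum([0, *layer_sizes])
    for a, b, c in zip(edges[:-2], edges[1:-1], edges[2:]):
        mask[a:b, b:c] = True
        mask[b:c, a:b] = True
    return mask


def glorot_weights(layer_sizes, rng: np.random.Generator) -> np.ndarray:
    """Fan-based uniform initialization per inter-layer weight block,
    mirrored so the full matrix is exactly symmetric."""
    n = int(sum(layer_sizes))
    W = np.zeros((n, n))
    edges = np.cumsum([0, *layer_sizes])
    for a, b, c in zip(edges[:-2], edges[1:-1], edges[2:]):
        fan_in, fan_out = b - a, c - b
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        block = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        W[a:b, b:c] = block
        W[b:c, a:b] = block.T
    return W


def make_fixture_network(layer_sizes, seed: int = 0,
                         scale: float | None = None
                         ) -> tuple[NetworkParams, WorldInput]:
    """Seeded random layered network plus one world input (random clamped
    input in [0, 1], random one-hot target) for gradient checking."""
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if len(layer_sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    rng = np.random.default_rng(seed)
    W = glorot_weights(layer_sizes, rng)
    if scale is not None:
        W = W * scale
    mask = layered_mask(layer_sizes)
    p = NetworkParams(W, np.zeros(int(sum(layer_sizes))), mask, layer_sizes)
    x = rng.uniform(0.0, 1.0, size=layer_sizes[0])
    d = np.zeros(layer_sizes[-1])
    d[rng.integers(layer_sizes[-1])] = 1.0
    return p, WorldInput(x=x, d=d)


def fixture_state(p: NetworkParams, w: WorldInput, fill: float = 0.0):
    """Zero-initialized state matching a fixture network's architecture."""
    n_out = p.layer_sizes[-1]
    n_hidden = p.n_units - p.layer_sizes[0] - n_out
    return init_state(w.x, n_hidden, n_out, fill=fill)


class IdxFormatError(ValueError):
    """Malformed IDX file (bad magic number or truncated payload)."""


class IdxCountMismatchError(ValueError):
    """Image and label files disagree on the number of examples."""


def _read_idx_images(path) -> np.ndarray:
    with open(path, "rb") as fh:
        head = fh.read(16)
        if len(head) < 16:
            raise IdxFormatError(f"{path}: truncated IDX image header")
        magic, n, rows, cols = struct.unpack(">IIII", head)
        if magic != 2051:
            raise IdxFormatError(f"{path}: bad image magic {magic}, expected 2051")
        payload = fh.read(n * rows * cols)
    if len(payload) != n * rows * cols:
        raise IdxFormatError(f"{path}: truncated IDX image payload")
    return np.frombuffer(payload, dtype=np.uint8).reshape(n, rows * cols)


def _read_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        head = fh.read(8)
        if len(head) < 8:
            raise IdxFormatError(f"{path}: truncated IDX label header")
        magic, n = struct.unpack(">II", head)
        if magic != 2049:
            raise IdxFormatError(f"{path}: bad label magic {magic}, expected 2049")
        payload = fh.read(n)
    if len(payload) != n:
        raise IdxFormatError(f"{path}: truncated IDX label payload")
    return np.frombuffer(payload, dtype=np.uint8).astype(int)


def write_idx(images_path, labels_path, images: np.ndarray,
              labels: np.ndarray, rows: int, cols: int) -> None:
    """Write IDX files (big-endian, magic 2051/2049); used by round-trip
    tests and for preparing small local fixtures."""
    images = np.asarray(images, dtype=np.uint8).reshape(-1, rows * cols)
    labels = np.asarray(labels, dtype=np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", 2051, images.shape[0], rows, cols))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", 2049, labels.size))
        fh.write(labels.tobytes())


def read_idx(images_path, labels_path, n_valid: int = 10_000) -> Dataset:
    """Read an IDX image/label pair; pixels are scaled to [0, 1], images
    flattened, targets one-hot over 10 classes. The last ``n_valid``
    examples are tagged as the validation split (capped at half the file
    for small fixtures)."""
    images = _read_idx_images(images_path)
    labels = _read_idx_labels(labels_path)
    if images.shape[0] != labels.shape[0]:
        raise IdxCountMismatchError(
            f"{images.shape[0]} images but {labels.shape[0]} labels"
        )
    feats = images.astype(float) / 255.0
    n = labels.size
    n_valid = min(n_valid, n // 2)
    split = np.array(["train"] * n, dtype=object)
    if n_valid:
        split[n - n_valid:] = "valid"
    n_classes = max(10, int(labels.max(initial=0)) + 1)
    return Dataset(feats, labels, _one_hot(labels, n_classes), split)
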