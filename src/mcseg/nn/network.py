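"""The shared detector/segmentator architecture.

Both networks use the same patch classifier: six 3x3 stride-1 convolutions
(the first two each followed by 2x2 max-pooling), then two fully connected
layers of 64 and 2 units.  Convolutions can run unpadded ("valid", the
feature map shrinks by 2 per conv) or zero-padded ("same", the spatial
size is preserved); with a 49x49 input the valid path contracts to a 2x2
map entering the first dense layer.  Every layer except the final dense
one is followed by batch normalization (placed after the ReLU); dropout
(50%) regularizes the 64-unit layer; weights use He initialization.

The class posterior is the softmax of the two output scores,
``p(y=l | X) = exp(s_l) / sum_k exp(s_k)`` with ``s = f(X, W)``, trained
by minimizing the categorical cross-entropy ``H(y, p) = -sum_j y_j log p_j``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .layers import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool2,
    ReLU,
)

#: indices (1-based) of conv layers followed by a 2x2 max-pool
_POOL_AFTER = (1, 2)
_N_CONV = 6
_KERNEL = 3


class InvalidConfigError(ValueError):
    """The architecture under-runs a 1x1 feature map for this patch size."""


def feature_map_side(n: int, padding_mode: str) -> int:
    """Spatial side of the final conv feature map for an N x N input.

    Valid convolution subtracts ``kernel - 1 = 2`` per layer, same
    convolution preserves the side, and each of the two max-pools halves
    it with floor division.  Raises :class:`InvalidConfigError` naming the
    failing layer if the side under-runs (a valid conv needs side >= 3;
    a pool needs side >= 2).
    """
    if padding_mode not in ("same", "valid"):
        raise ValueError("padding_mode must be 'same' or 'valid'")
    if n % 2 == 0 or n < 9:
        raise ValueError("patch side must be odd and >= 9")
    side = n
    for conv in range(1, _N_CONV + 1):
        if padding_mode == "valid":
            if side < _KERNEL:
                raise InvalidConfigError(
                    f"feature map side {side} before conv {conv} is below the "
                    f"{_KERNEL}x{_KERNEL} valid-convolution minimum"
                )
            side -= _KERNEL - 1
        if conv in _POOL_AFTER:
            if side < 2:
                raise InvalidConfigError(
                    f"feature map side {side} before pool after conv {conv} is below 2"
                )
            side //= 2
    if side < 1:
        raise InvalidConfigError("architecture contracts to an empty feature map")
    return side


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the patch-classifier architecture."""

    patch_side: int = 49
    padding_mode: str = "same"
    conv_filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    fc_units: int = 64
    n_classes: int = 2
    dropout_rate: float = 0.5
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if len(self.conv_filters) != _N_CONV:
            raise ValueError(f"conv_filters must list {_N_CONV} layer widths")
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("conv filter counts must be positive")
        feature_map_side(self.patch_side, self.padding_mode)  # validates

    @property
    def final_side(self) -> int:
        return feature_map_side(self.patch_side, self.padding_mode)

    @property
    def flatten_size(self) -> int:
        return self.final_side**2 * self.conv_filters[-1]


def softmax_posterior(s: np.ndarray) -> np.ndarray:
    """Softmax class posterior of unnormalized scores (last axis).

    Computed with max-subtraction so large scores cannot overflow; the
    output is strictly positive and sums to 1, and is invariant to adding
    any constant to all scores.
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


#: clamp for log() inside the cross-entropy
CROSSENTROPY_EPS = 1e-12


def crossentropy(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Categorical cross-entropy of a one-hot target and a posterior vector."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y.shape != y_pred.shape:
        raise ValueError("target and prediction lengths differ")
    return float(-(y * np.log(np.clip(y_pred, CROSSENTROPY_EPS, None))).sum(axis=-1))


class Network:
    """A stack of layers with a combined softmax/cross-entropy head."""

    def __init__(self, config: NetworkConfig, layers: list[Layer]):
        self.config = config
        self.layers = layers

    # -- plumbing ---------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i:02d}/param{j}"] = p.copy()
            if isinstance(layer, BatchNorm):
                out[f"layer{i:02d}/running_mean"] = layer.running_mean.copy()
                out[f"layer{i:02d}/running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i:02d}/param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i:02d}/running_mean"]
                layer.running_var[...] = state[f"layer{i:02d}/running_var"]

    # -- forward / backward ----------------------------------------------
    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Unnormalized class scores ``s = f(X, W)`` for a (B,1,N,N) batch."""
        out = x
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        dout = dscores
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def loss_and_grad(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[float, float]:
        """One training forward/backward pass; returns (loss, accuracy)."""
        scores = self.forward(x, train=True, rng=rng)
        probs = softmax_posterior(scores)
        batch = x.shape[0]
        loss = float(
            -(y * np.log(np.clip(probs, CROSSENTROPY_EPS, None))).sum() / batch
        )
        acc = float((probs.argmax(axis=1) == y.argmax(axis=1)).mean())
        dscores = ((probs - y) / batch).astype(scores.dtype)
        self.backward(dscores)
        return loss, acc

    # -- inference --------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class posteriors for an arbitrary number of patches."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(softmax_posterior(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(outs) if outs else np.empty((0, self.config.n_classes))

    def predict(self, x: np.ndarray, threshold: float = 0.5, batch_size: int = 512) -> np.ndarray:
        """Binary decisions; an exact posterior tie goes to the negative class."""
        proba = self.predict_proba(x, batch_size)
        return (proba[:, 1] > threshold).astype(np.int8)


def build_network(config: NetworkConfig, seed: int = 0, dtype=np.float32) -> Network:
    """Instantiate the architecture with He-initialized weights.

    Layer order per block is conv -> ReLU -> BN (-> pool for the first two
    blocks); the head is flatten -> dense(64) -> ReLU -> BN -> dropout ->
    dense(2).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    in_ch = 1
    for conv_idx, filters in enumerate(config.conv_filters, start=1):
        layers.append(Conv2D(in_ch, filters, config.padding_mode, rng, dtype=dtype))
        layers.append(ReLU())
        if config.batchnorm:
            layers.append(BatchNorm(filters, spatial=True, dtype=dtype))
        if conv_idx in _POOL_AFTER:
            layers.append(MaxPool2())
        in_ch = filters
    layers.append(Flatten())
    layers.append(Dense(config.flatten_size, config.fc_units, rng, dtype=dtype))
    layers.append(ReLU())
    if config.batchnorm:
        layers.append(BatchNorm(config.fc_units, spatial=False, dtype=dtype))
    layers.append(Dropout(config.dropout_rate))
    layers.append(Dense(config.fc_units, config.n_classes, rng, dtype=dtype))
    return Network(config, layers)


@dataclass
class TrainedModel:
    """A network plus its training history and stopping point."""

    config: NetworkConfig
    network: Network
    history: dict = field(default_factory=dict)
    stopping_step: int = 0
    role: str = ""

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return self.network.predict(x, threshold)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(x)

    def copy_weights(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.network.state_dict())

    # -- persistence (HDF5 container with embedded config) ----------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            cfg = f.create_group("config")
            cfg.attrs["patch_side"] = self.config.patch_side
            cfg.attrs["padding_mode"] = self.config.padding_mode
            cfg.attrs["conv_filters"] = list(self.config.conv_filters)
            cfg.attrs["fc_units"] = self.config.fc_units
            cfg.attrs["n_classes"] = self.config.n_classes
            cfg.attrs["dropout_rate"] = self.config.dropout_rate
            cfg.attrs["batchnorm"] = self.config.batchnorm
            cfg.attrs["role"] = self.role
            cfg.attrs["stopping_step"] = self.stopping_step
            w = f.create_group("weights")
            for key, val in self.network.state_dict().items():
                w.create_dataset(key, data=val)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with h5py.File(path, "r") as f:
            a = f["config"].attrs
            config = NetworkConfig(
                patch_side=int(a["patch_side"]),
                padding_mode=str(a["padding_mode"]),
                conv_filters=tuple(int(v) for v in a["conv_filters"]),
                fc_units=int(a["fc_units"]),
                n_classes=int(a["n_classes"]),
                dropout_rate=float(a["dropout_rate"]),
                batchnorm=bool(a["batchnorm"]),
            )
            net = build_network(config, seed=0)
            state: dict[str, np.ndarray] = {}

            def _visit(name: str, obj) -> None:
                if isinstance(obj, h5py.Dataset):
                    state[name] = np.asarray(obj)

            f["weights"].visititems(_visit)
            net.load_state_dict(state)
            return cls(
                config=config,
                network=net,
                role=str(a["role"]),
                stopping_step=int(a["stopping_step"]),
            )


def make_adam(network: Network, lr: float) -> Adam:
    return Adam(network.parameters(), lr=lr)
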