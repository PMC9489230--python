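"""1D CNN regressors for spectra and their training regime.

Six architectures are available: four self-designed nets (``cnn1``–``cnn4``,
one to four convolution blocks of 32 kernels of size 3 with max pooling,
then 512- and 32-node fully connected layers) and 1D adaptations of AlexNet
and a 9-layer VGGNet, both ending in two 4096-node fully connected layers.
All end in a single output node.  An input batch-normalization layer
standardizes the spectra; the self-designed nets also carry a BN layer after
each convolution block.

Training uses the L2 loss, Adam, batches of 64, and a stepped learning-rate
schedule: initial rate 0.005, divided by 10 every 200 epochs, stopping when
the loss stabilizes (or at ``max_epochs``).  The checkpoint with the best
validation loss is kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .dataset import SpectraSet

__all__ = ["ArchitectureSpec", "TrainConfig", "CNNRegressor",
           "ARCHITECTURES", "get_architecture", "build", "train",
           "learning_rate"]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a 1D CNN.

    ``conv_layers`` is an ordered list of ``(filters, kernel_size,
    has_max_pool)``; ``fc_layers`` the hidden fully connected widths.
    ``block_bn`` adds a BatchNorm after each conv block (the self-designed
    nets); ``bn_before_pool`` swaps the block order to conv→ReLU→BN→pool.
    """

    name: str
    conv_layers: tuple[tuple[int, int, bool], ...]
    fc_layers: tuple[int, ...]
    input_width: int = 2071
    block_bn: bool = True
    bn_before_pool: bool = False


def _self_designed(name: str, n_blocks: int) -> ArchitectureSpec:
    return ArchitectureSpec(
        name=name,
        conv_layers=tuple((32, 3, True) for _ in range(n_blocks)),
        fc_layers=(512, 32),
    )


ARCHITECTURES: dict[str, ArchitectureSpec] = {
    "cnn1": _self_designed("cnn1", 1),
    "cnn2": _self_designed("cnn2", 2),
    "cnn3": _self_designed("cnn3", 3),
    "cnn4": _self_designed("cnn4", 4),
    "alexnet": ArchitectureSpec(
        name="alexnet",
        conv_layers=((96, 11, True), (256, 5, True), (384, 3, True),
                     (384, 3, False), (256, 3, False)),
        fc_layers=(4096, 4096),
        block_bn=False,
    ),
    "vggnet9": ArchitectureSpec(
        name="vggnet9",
        conv_layers=((64, 5, False), (64, 3, True), (128, 3, False),
                     (128, 3, True), (256, 3, False), (256, 3, False),
                     (256, 3, True)),
        fc_layers=(4096, 4096),
        block_bn=False,
    ),
}


def get_architecture(name: str, input_width: int | None = None) -> ArchitectureSpec:
    key = name.strip().lower().replace("-", "").replace("_", "")
    if key not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture '{name}'; choose from {sorted(ARCHITECTURES)}"
        )
    spec = ARCHITECTURES[key]
    if input_width is not None:
        spec = replace(spec, input_width=input_width)
    return spec


@dataclass
class TrainConfig:
    """Training schedule; defaults follow the standard regime.

    The learning rate at epoch ``e`` is
    ``initial_lr / lr_decay_factor ** (e // lr_decay_every)``.
    ``plateau_tolerance`` is the relative training-loss improvement below
    which ``plateau_window`` consecutive epochs trigger early termination.
    """

    initial_lr: float = 0.005
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 200
    max_epochs: int = 600
    batch_size: int = 64
    plateau_tolerance: float = 1e-4
    plateau_window: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be > 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Stepped schedule value at a (0-based) epoch."""
    return cfg.initial_lr / cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


@dataclass
class CNNRegressor:
    """A built (possibly trained) CNN bound to its architecture."""

    arch: ArchitectureSpec
    network: nn.Network
    kind: str = "cnn"
    trained: bool = False
    history: dict = field(default_factory=dict, repr=False)

    def _as_input(self, data: SpectraSet | np.ndarray) -> np.ndarray:
        x = data.reflectance if isinstance(data, SpectraSet) else np.asarray(data)
        if x.shape[1] != self.arch.input_width:
            raise ValueError(
                f"input width {x.shape[1]} != architecture width "
                f"{self.arch.input_width}"
            )
        return x[:, None, :]

    def predict(self, data: SpectraSet | np.ndarray) -> np.ndarray:
        return self.network.predict(self._as_input(data))

    def input_gradients(self, data: SpectraSet | np.ndarray) -> np.ndarray:
        """Per-sample d(output)/d(wavelength), shape (n, width)."""
        return self.network.input_gradient(self._as_input(data))[:, 0, :]

    def clone(self) -> "CNNRegressor":
        return CNNRegressor(arch=self.arch, network=self.network.clone(),
                            trained=self.trained, history=dict(self.history))


def build(arch: ArchitectureSpec | str, seed: int = 0,
          input_width: int | None = None) -> CNNRegressor:
    """Construct an untrained network with seeded He initialization."""
    if isinstance(arch, str):
        arch = get_architecture(arch, input_width)
    elif input_width is not None:
        arch = replace(arch, input_width=input_width)
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.BatchNorm1d(1)]
    length, channels = arch.input_width, 1
    for filters, kernel, has_pool in arch.conv_layers:
        conv = nn.Conv1d(channels, filters, kernel, rng)
        length = conv.out_length(length)
        layers += [conv, nn.ReLU()]
        if arch.block_bn and arch.bn_before_pool:
            layers.append(nn.BatchNorm1d(filters))
        if has_pool:
            length //= 2
            layers.append(nn.MaxPool1d(2))
        if arch.block_bn and not arch.bn_before_pool:
            layers.append(nn.BatchNorm1d(filters))
        channels = filters
        if length < 1:
            raise ValueError(
                f"architecture '{arch.name}' reduces width {arch.input_width} "
                "below 1; increase input_width"
            )
    layers.append(nn.Flatten())
    features = channels * length
    for width in arch.fc_layers:
        layers += [nn.Dense(features, width, rng), nn.ReLU()]
        features = width
    layers.append(nn.Dense(features, 1, rng))
    return CNNRegressor(arch=arch, network=nn.Network(layers))


def _fit_network(net: nn.Network, x_train: np.ndarray, y_train: np.ndarray,
                 x_val: np.ndarray, y_val: np.ndarray,
                 cfg: TrainConfig) -> dict[str, list[float]]:
    """Core training loop on raw arrays; returns the loss history.

    Applies the stepped LR schedule, stops at the loss plateau (no relative
    training-loss improvement over the running best for ``plateau_window``
    consecutive epochs) or at ``max_epochs``, and restores the parameters
    of the best-validation epoch when a validation set is given.
    """
    cfg.validate()
    n = x_train.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(net.parameters())
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = net.state()
    best_train = np.inf
    stale = 0
    x_train = np.asarray(x_train, dtype=np.float32)
    for epoch in range(cfg.max_epochs):
        lr = learning_rate(cfg, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = net.forward(x_train[idx], train=True)
            loss, grad = nn.mse_loss(pred, y_train[idx])
            net.backward(grad)
            optimizer.step(net.gradients(), lr)
            epoch_loss += loss * idx.size
        epoch_loss /= n
        if y_val.size:
            val_pred = net.predict(x_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
        else:
            val_loss = float("nan")
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if y_val.size and val_loss < best_val:
            best_val = val_loss
            best_state = net.state()
        if epoch_loss < best_train * (1.0 - cfg.plateau_tolerance):
            best_train = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.plateau_window:
                break
    if y_val.size:
        net.load_state(best_state)
    return history


def train(model: CNNRegressor, train_set: SpectraSet, val_set: SpectraSet,
          cfg: TrainConfig, init_output_bias: bool = True) -> CNNRegressor:
    """Train in place; returns the model at its best-validation checkpoint.

    ``init_output_bias`` starts the output node's bias at the training-set
    mean response, which conditions the L2 optimisation without changing
    the model class (skipped when resuming from pretrained weights).
    """
    if train_set.n_samples == 0:
        raise ValueError("empty training set")
    x_train = model._as_input(train_set)
    y_train = train_set.reference_value.astype(np.float32)
    x_val = model._as_input(val_set)
    y_val = val_set.reference_value.astype(np.float32)
    if init_output_bias:
        model.network.layers[-1].bias[...] = y_train.mean()
    model.history = _fit_network(model.network, x_train, y_train,
                                 x_val, y_val, cfg)
    model.trained = True
    return model
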