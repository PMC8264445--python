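"""The bidirectional-LSTM window classifier.

Architecture: embedding (dim 21) -> stacked bidirectional LSTM layers
(128 units per direction, sequences returned at every timestep) ->
time-distributed dense (128) -> flatten -> dropout (0.4) -> dense (64)
-> dense (2, softmax).  Compiled against binary cross-entropy (exactly
the two-class softmax cross-entropy) with the Adam optimizer at
learning rate 0.01, batch size 512, up to 30 epochs.

Training keeps the parameters of the epoch with the best validation
accuracy (checkpointing) and halves the learning rate when validation
loss plateaus.  All randomness — initialization, shuffling, dropout,
the validation split — derives from one seed, so runs are
bit-reproducible single-threaded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .encoding import build_encoding

ARCHITECTURE_FIELDS = (
    "window_size",
    "embedding_dim",
    "bilstm_layers",
    "bilstm_units",
    "time_distributed_units",
    "dense_units",
    "output_units",
    "vocabulary_size",
)


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the classifier; defaults are the published tuning."""

    window_size: int = 31
    embedding_dim: int = 21
    bilstm_layers: int = 2
    bilstm_units: int = 128
    time_distributed_units: int = 128
    dropout_rate: float = 0.4
    dense_units: int = 64
    output_units: int = 2
    learning_rate: float = 0.01
    batch_size: int = 512
    epochs: int = 30
    seed: int = 0
    vocabulary_size: int = 22
    # reduce-LR-on-plateau controls (monitoring validation loss)
    lr_factor: float = 0.5
    lr_patience: int = 3
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0 or self.window_size < 1:
            raise ValueError(f"window_size must be odd and positive: {self.window_size}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1): {self.dropout_rate}")
        if self.output_units != 2:
            raise ValueError("output_units is fixed at 2 (softmax over two classes)")
        for name in ("embedding_dim", "bilstm_layers", "bilstm_units",
                     "time_distributed_units", "dense_units", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def architecture(self) -> dict:
        return {k: getattr(self, k) for k in ARCHITECTURE_FIELDS}

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, seed=seed)


def architecturally_equal(a: ModelSpec, b: ModelSpec) -> bool:
    return a.architecture() == b.architecture()


@dataclass
class TrainedModel:
    """A (possibly still untrained) classifier instance.

    ``history`` holds per-epoch loss/accuracy on the training and
    validation partitions; ``best_epoch`` is the 0-based index of the
    checkpointed (maximal validation accuracy) epoch.  ``lineage``
    records the provenance chain for transfer-learned models.
    """

    spec: ModelSpec
    network: nn.Network
    history: dict = field(default_factory=lambda: {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [], "lr": []})
    best_epoch: int = -1
    lineage: list = field(default_factory=list)

    def get_weights(self) -> dict[str, np.ndarray]:
        return self.network.get_weights()

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.network.set_weights(weights)

    def layer_names(self) -> list[str]:
        return self.network.layer_names()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability for each encoded window."""
        if X.ndim != 2 or X.shape[1] != self.spec.window_size:
            raise ValueError(
                f"expected windows of length {self.spec.window_size}, "
                f"got shape {X.shape}"
            )
        logits = self.network.forward(X, training=False)
        return nn.softmax(logits)[:, 1]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binary calls at the given probability threshold."""
        return (self.predict_proba(X) >= threshold).astype(int)


def build_model(spec: ModelSpec) -> TrainedModel:
    """Instantiate the layer stack with seeded initial parameters."""
    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Layer] = [
        nn.Embedding("embedding", spec.vocabulary_size, spec.embedding_dim, rng)
    ]
    in_dim = spec.embedding_dim
    for i in range(spec.bilstm_layers):
        layers.append(nn.BiLSTM(f"bilstm_{i + 1}", in_dim, spec.bilstm_units, rng))
        in_dim = 2 * spec.bilstm_units
    layers.append(
        nn.TimeDistributedDense("time_distributed", in_dim,
                                spec.time_distributed_units, rng)
    )
    layers.append(nn.Flatten("flatten"))
    layers.append(nn.Dropout("dropout", spec.dropout_rate))
    layers.append(
        nn.Dense("dense_1", spec.window_size * spec.time_distributed_units,
                 spec.dense_units, rng, activation="relu")
    )
    layers.append(
        nn.Dense("output", spec.dense_units, spec.output_units, rng,
                 activation="linear")
    )
    return TrainedModel(spec=spec, network=nn.Network(layers))


def _stratified_validation_split(
    Y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index split keeping each class's share of the validation partition."""
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in range(Y.shape[1]):
        members = np.flatnonzero(Y[:, cls] == 1)
        members = members[rng.permutation(len(members))]
        n_val = max(1, int(round(fraction * len(members)))) if len(members) > 1 else 0
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return (np.sort(np.array(train_idx, dtype=int)),
            np.sort(np.array(val_idx, dtype=int)))


def _evaluate(network: nn.Network, X: np.ndarray, Y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses = []
    correct = 0
    for start in range(0, len(X), batch_size):
        xb, yb = X[start : start + batch_size], Y[start : start + batch_size]
        logits = network.forward(xb, training=False)
        loss, p, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((p.argmax(axis=1) == yb.argmax(axis=1)).sum())
    return sum(losses) / len(X), correct / len(X)


def train(
    model: TrainedModel,
    X: np.ndarray,
    Y: np.ndarray,
    validation_fraction: float = 0.1,
    seed: int | None = None,
    frozen_layers: set[str] | None = None,
    validation_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Fit the model in place and return it with the best checkpoint restored.

    A stratified ``validation_fraction`` of the training data is held
    out for checkpoint selection and the learning-rate schedule (unless
    explicit ``validation_data`` is given).  The returned model carries
    the parameters of the epoch with maximal validation accuracy.
    """
    if len(X) == 0:
        raise ValueError("empty training data")
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    spec = model.spec
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    if validation_data is None:
        tr_idx, val_idx = _stratified_validation_split(Y, validation_fraction, rng)
        if len(val_idx) == 0:
            # corpus too small to hold anything out: checkpoint on the
            # training data itself (degenerate but well-defined)
            X_tr, Y_tr = X, Y
            X_val, Y_val = X, Y
        else:
            X_tr, Y_tr = X[tr_idx], Y[tr_idx]
            X_val, Y_val = X[val_idx], Y[val_idx]
    else:
        X_tr, Y_tr = X, Y
        X_val, Y_val = validation_data
    if len(X_val) == 0:
        raise ValueError("validation partition is empty; need more data")

    optimizer = nn.Adam(model.network, lr=spec.learning_rate,
                        frozen=frozen_layers)
    history = {k: [] for k in ("loss", "accuracy", "val_loss", "val_accuracy", "lr")}
    best_weights = model.get_weights()
    best_val_acc = -np.inf
    best_epoch = -1
    plateau_wait = 0
    best_val_loss = np.inf

    for epoch in range(spec.epochs):
        order = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, len(X_tr), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = X_tr[idx], Y_tr[idx]
            for layer in model.network.layers:
                layer.zero_grads()
            logits = model.network.forward(xb, training=True, rng=rng)
            loss, p, dlogits = nn.softmax_cross_entropy(logits, yb)
            model.network.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(xb)
            epoch_correct += int((p.argmax(axis=1) == yb.argmax(axis=1)).sum())

        val_loss, val_acc = _evaluate(model.network, X_val, Y_val, spec.batch_size)
        history["loss"].append(epoch_loss / len(X_tr))
        history["accuracy"].append(epoch_correct / len(X_tr))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(optimizer.lr)

        if val_acc > best_val_acc:  # checkpoint on validation accuracy
            best_val_acc = val_acc
            best_epoch = epoch
            best_weights = model.get_weights()

        # reduce LR on validation-loss plateau
        if val_loss < best_val_loss - 1e-12:
            best_val_loss = val_loss
            plateau_wait = 0
        else:
            plateau_wait += 1
            if plateau_wait > spec.lr_patience:
                optimizer.lr = max(optimizer.lr * spec.lr_factor, spec.min_lr)
                plateau_wait = 0

    model.set_weights(best_weights)
    model.history = history
    model.best_epoch = best_epoch
    return model


# ---------------------------------------------------------------------------
# Persistence: a directory with weights.npz + spec.json (+ history.json)


def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(path / "weights.npz",
             **{k.replace("/", "__"): v for k, v in weights.items()})
    (path / "spec.json").write_text(json.dumps(asdict(model.spec), indent=2) + "\n")
    (path / "history.json").write_text(
        json.dumps({"history": model.history, "best_epoch": model.best_epoch,
                    "lineage": model.lineage}, indent=2) + "\n")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    try:
        spec_dict = json.loads((path / "spec.json").read_text())
        spec = ModelSpec(**spec_dict)
        with np.load(path / "weights.npz") as npz:
            weights = {k.replace("__", "/"): npz[k] for k in npz.files}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    model = build_model(spec)
    model.set_weights(weights)
    hist_path = path / "history.json"
    if hist_path.exists():
        extras = json.loads(hist_path.read_text())
        model.history = extras.get("history", model.history)
        model.best_epoch = extras.get("best_epoch", -1)
        model.lineage = extras.get("lineage", [])
    return model


def encode_and_train(model: TrainedModel, dataset, **kwargs) -> TrainedModel:
    """Convenience: encode a SiteDataset with the canonical scheme and train."""
    from .encoding import encode_windows

    X, Y = encode_windows(dataset, build_encoding())
    return train(model, X, Y, **kwargs)
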