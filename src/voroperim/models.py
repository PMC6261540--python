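"""Classifier models: the compact voronoi-image CNN and the flat-NN baseline.

The CNN consumes a single-channel 61x61 voronoi image and emits the
probability that the examination belongs to the early-glaucoma class.  Its
architecture is intentionally small so it trains on cohorts of a few
thousand fields:

    [conv 4@3x3 - BN - ReLU] x2 -> maxpool/2
    [conv 4@3x3 - BN - ReLU] x2 -> maxpool/2
    conv 4@3x3 - BN - ReLU -> global average pool
    FC 32 - ReLU - BN -> FC 32 - ReLU - dropout 0.5 -> FC 1 - sigmoid

The NN baseline shares the dense head (two 32-unit ReLU layers, dropout
after the second) but takes the raw deviation vector concatenated with MD
and sLV — i.e. the same information without spatial structure.

Both are trained with Adam on binary cross-entropy, batch size 32, and the
checkpoint minimizing validation loss is the model that is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nets
from .indices import index_features
from .io import TestPattern, VisualFieldRecord, flip_to_right_eye
from .voronoi import GRID_SIZE, region_assignment, to_voronoi_image


@dataclass
class ModelSpec:
    """Hyperparameters of a classifier; ``kind`` selects the input contract
    (61x61 image for CNN, length L+2 vector for NN)."""

    kind: str = "CNN"
    conv_filters: int = 4
    kernel: int = 3
    fc_units: int = 32
    dropout: float = 0.5
    batch_size: int = 32
    lr: float = 1e-3
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("CNN", "NN"):
            raise ValueError("kind must be CNN or NN")
        for name in ("conv_filters", "kernel", "fc_units", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout < 1) or self.lr <= 0:
            raise ValueError("invalid dropout or learning rate")


@dataclass
class TrainedModel:
    """A fitted network plus its training record.

    ``selected_epoch`` (1-based) is the argmin of validation loss in
    ``history``; the stored weights are that checkpoint's.
    """

    spec: ModelSpec
    net: nets.Sequential
    history: list[dict] = field(default_factory=list)
    selected_epoch: int = 0
    input_len: Optional[int] = None  # NN only

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d(probability)/d(input), inference mode, per sample."""
        X = self._check_input(np.asarray(X, dtype=float))
        logits = self.net.forward(X, train=False)
        p = nets.sigmoid(logits)
        self.net.zero_grad()
        return self.net.backward(p * (1.0 - p))

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        if self.spec.kind == "CNN":
            if X.ndim == 2:
                X = X[None, :, :, None]
            elif X.ndim == 3 and X.shape == (GRID_SIZE, GRID_SIZE, 1):
                X = X[None]
            elif X.ndim == 3:
                X = X[:, :, :, None]
            if X.shape[1:] != (GRID_SIZE, GRID_SIZE, 1):
                raise ValueError(f"CNN expects (n, {GRID_SIZE}, {GRID_SIZE}, 1) images")
        else:
            if X.ndim == 1:
                X = X[None]
            if self.input_len is not None and X.shape[1] != self.input_len:
                raise ValueError(f"NN expects {self.input_len} input features, got {X.shape[1]}")
        return X


def build_cnn(spec: ModelSpec) -> nets.Sequential:
    """The 61x61 voronoi-image classifier (seeded, deterministic init)."""
    if spec.kind != "CNN":
        raise ValueError("build_cnn needs spec.kind == 'CNN'")
    rng = np.random.default_rng(spec.seed)
    f, k, u = spec.conv_filters, spec.kernel, spec.fc_units

    def conv_block(in_ch):
        return [nets.Conv2d(in_ch, f, rng, kernel=k), nets.BatchNorm(f), nets.ReLU()]

    layers = (
        conv_block(1)
        + conv_block(f)
        + [nets.MaxPool2()]
        + conv_block(f)
        + conv_block(f)
        + [nets.MaxPool2()]
        + conv_block(f)
        + [nets.GlobalAvgPool()]
        + [nets.Dense(f, u, rng), nets.ReLU(), nets.BatchNorm(u)]
        + [nets.Dense(u, u, rng), nets.ReLU(), nets.Dropout(spec.dropout)]
        + [nets.Dense(u, 1, rng)]
    )
    return nets.Sequential(layers)


def build_nn(spec: ModelSpec, input_len: int) -> nets.Sequential:
    """Flat baseline on [deviations, MD, sLV]: FC32-ReLU, FC32-ReLU-dropout, FC1."""
    if spec.kind != "NN":
        raise ValueError("build_nn needs spec.kind == 'NN'")
    rng = np.random.default_rng(spec.seed)
    u = spec.fc_units
    return nets.Sequential(
        [
            nets.Dense(input_len, u, rng),
            nets.ReLU(),
            nets.Dense(u, u, rng),
            nets.ReLU(),
            nets.Dropout(spec.dropout),
            nets.Dense(u, 1, rng),
        ]
    )


# ---------------------------------------------------------------------------
# feature preparation


def records_to_images(records: Sequence[VisualFieldRecord], pattern: TestPattern) -> np.ndarray:
    """Rasterize records to (n, 61, 61, 1) voronoi images, OS eyes flipped."""
    maps = {}
    out = np.empty((len(records), GRID_SIZE, GRID_SIZE, 1))
    for i, rec in enumerate(records):
        flipped, pat = flip_to_right_eye(rec, pattern)
        key = pat is pattern  # OD keeps the original, OS shares one mirror
        if key not in maps:
            maps[key] = region_assignment(pat)
        out[i, :, :, 0] = to_voronoi_image(flipped, maps[key]).values
    return out


def records_to_vectors(records: Sequence[VisualFieldRecord], pattern: TestPattern) -> np.ndarray:
    """(n, L+2) arrays: the full deviation vector plus MD and sLV."""
    devs = np.stack([rec.deviations for rec in records])
    if devs.shape[1] != pattern.L:
        raise ValueError("record length does not match the pattern")
    return np.hstack([devs, index_features(records, pattern)])


def labels_of(records: Sequence[VisualFieldRecord]) -> np.ndarray:
    labels = []
    for rec in records:
        if rec.group is None:
            raise ValueError(f"record of subject {rec.subject_id} is unlabeled")
        labels.append(1 if rec.group == "EG" else 0)
    return np.asarray(labels)


# ---------------------------------------------------------------------------
# training


def fit_arrays(
    net: nets.Sequential,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: ModelSpec,
) -> tuple[list[dict], int]:
    """Adam/BCE training loop with best-validation-loss checkpointing.

    Returns the per-epoch history and the selected (1-based) epoch; ``net``
    is left holding the selected checkpoint's weights, cast back to float64
    for batch-size-independent inference and exact saliency gradients
    (optimization itself runs in float32).
    """
    net.astype(np.float32)
    X_train = np.asarray(X_train, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    rng = np.random.default_rng(spec.seed)
    opt = nets.Adam(net.parameters(), lr=spec.lr)
    n = X_train.shape[0]
    history: list[dict] = []
    best_loss, best_state, best_epoch = np.inf, None, 0
    for epoch in range(1, spec.epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = perm[start : start + spec.batch_size]
            net.zero_grad()
            logits = net.forward(X_train[idx], train=True, rng=rng)
            loss, gl = nets.bce_with_logits(logits, y_train[idx])
            net.backward(gl)
            opt.step()
            losses.append(loss)
        val_logits = _forward_batched(net, X_val)
        val_loss, _ = nets.bce_with_logits(val_logits, y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_state = net.state_dict()
    net.load_state_dict(best_state)
    net.astype(np.float64)
    return history, best_epoch


def _forward_batched(net: nets.Sequential, X: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [net.forward(X[s : s + batch], train=False) for s in range(0, X.shape[0], batch)]
    return np.concatenate(outs, axis=0)


def train_model(
    spec: ModelSpec,
    train_records: Sequence[VisualFieldRecord],
    val_records: Sequence[VisualFieldRecord],
    pattern: TestPattern,
) -> TrainedModel:
    """Train a CNN or NN on labeled records with a held-out validation split.

    The two splits must be subject-disjoint (the cross-validation protocol
    groups by subject) and the training split must contain both classes.
    """
    if not train_records or not val_records:
        raise ValueError("training and validation splits must both be non-empty")
    overlap = {r.subject_id for r in train_records} & {r.subject_id for r in val_records}
    if overlap:
        raise ValueError(f"subject leakage between train and validation splits: {sorted(overlap)}")
    y_train, y_val = labels_of(train_records), labels_of(val_records)
    if y_train.min() == y_train.max():
        raise ValueError("training split contains a single class")
    if spec.kind == "CNN":
        net = build_cnn(spec)
        X_train = records_to_images(train_records, pattern)
        X_val = records_to_images(val_records, pattern)
        input_len = None
    else:
        X_train = records_to_vectors(train_records, pattern)
        X_val = records_to_vectors(val_records, pattern)
        input_len = X_train.shape[1]
        net = build_nn(spec, input_len)
    history, best_epoch = fit_arrays(net, X_train, y_train, X_val, y_val, spec)
    return TrainedModel(
        spec=spec, net=net, history=history, selected_epoch=best_epoch, input_len=input_len
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """EG probabilities in (0, 1); inference mode, batch-size independent."""
    X = model._check_input(np.asarray(X, dtype=float))
    return nets.sigmoid(_forward_batched(model.net, X)).ravel()


def predict_records(
    model: TrainedModel, records: Sequence[VisualFieldRecord], pattern: TestPattern
) -> np.ndarray:
    if model.spec.kind == "CNN":
        return predict(model, records_to_images(records, pattern))
    return predict(model, records_to_vectors(records, pattern))


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: TrainedModel, directory) -> None:
    """Write weights (npz) plus a JSON sidecar with spec and training record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.net.state_dict())
    sidecar = {
        "spec": asdict(model.spec),
        "selected_epoch": model.selected_epoch,
        "input_len": model.input_len,
        "history": model.history,
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(directory) -> TrainedModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    spec = ModelSpec(**sidecar["spec"])
    if spec.kind == "CNN":
        net = build_cnn(spec)
    else:
        net = build_nn(spec, sidecar["input_len"])
    with np.load(directory / "weights.npz") as data:
        net.load_state_dict(dict(data))
    return TrainedModel(
        spec=spec,
        net=net,
        history=sidecar["history"],
        selected_epoch=sidecar["selected_epoch"],
        input_len=sidecar["input_len"],
    )
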