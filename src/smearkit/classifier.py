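"""Lightweight CNN classification of single-cell ROIs into nine classes.

The classifier is a small sequential network operating on 64x64x3
background-zeroed cell crops: four 3x3 valid-padded ReLU convolutions
(32-64-128-256 filters), each followed by 2x2 max pooling, with dropout
after pools 2-4, then flatten -> dense 256 (ReLU) -> dropout -> dense 9
(softmax).  The 64x64 ingress size is forced by the architecture table's
62x62 first feature map under valid convolution; the closed-form
trainable-parameter total is 653,129.

Data are split by stratified 5-fold cross-validation: the five test folds
partition the dataset with per-class proportions preserved, and the
remainder of each fold is split train:validation 75:25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .nn.layers import Conv2D, Dense, Dropout, Flatten, MaxPool2D
from .nn.model import LayerSpec, ModelSpec, Sequential, conv_params, dense_params
from .nn.train import History, TrainingPolicy, fit

__all__ = [
    "CLASS_NAMES",
    "LWCNNConfig",
    "ClassProbabilities",
    "FoldSplit",
    "FoldResult",
    "build_lwcnn",
    "reference_lwcnn_table",
    "stratified_kfold",
    "train_classifier",
    "predict_proba",
]

#: The nine blood-cell classes, in the reference distribution's order.
CLASS_NAMES = (
    "Erythrocyte",
    "Erythroblast",
    "Neutrophil",
    "Basophil",
    "Eosinophil",
    "Lymphocyte",
    "Monocyte",
    "Immature Granulocytes",
    "Platelet",
)


@dataclass(frozen=True)
class LWCNNConfig:
    input_hw: tuple = (64, 64)
    in_channels: int = 3
    conv_filters: tuple = (32, 64, 128, 256)
    dense_units: int = 256
    n_classes: int = 9
    dropout_conv: float = 0.25  # after pools 2-4 (rates unstated upstream)
    dropout_dense: float = 0.5  # before the output layer
    extra_conv_blocks: int = 0  # 0 or 2; ablation toggle (3x3 same convs)
    activation: str = "relu"
    l2: float = 0.0

    def __post_init__(self):
        if self.extra_conv_blocks not in (0, 2):
            raise ValueError("extra_conv_blocks must be 0 or 2")


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax output for one ROI."""

    probs: np.ndarray  # shape (n_classes,), >= 0, sums to 1
    predicted_class: int
    confidence: float

    @property
    def predicted_name(self) -> str:
        return CLASS_NAMES[self.predicted_class]


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int  # 1-based
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class FoldResult:
    fold_index: int
    model: Sequential
    history: History
    test_accuracy: float
    y_true: np.ndarray
    y_pred: np.ndarray
    y_prob: np.ndarray


def _lwcnn_spec(cfg: LWCNNConfig) -> ModelSpec:
    act = "ReLU" if cfg.activation == "relu" else cfg.activation.upper()
    h, w = cfg.input_hw
    c_in = cfg.in_channels
    rows = []
    for i, f in enumerate(cfg.conv_filters):
        h, w = h - 2, w - 2  # valid 3x3
        rows.append(LayerSpec("Conv2D", "conv", (h, w, f), conv_params(3, c_in, f), (3, 3), act))
        h, w = h // 2, w // 2
        rows.append(LayerSpec("MaxPooling2D", "pool", (h, w, f), 0, (2, 2)))
        if i >= 1:
            rows.append(LayerSpec("Dropout", "dropout", (h, w, f), 0))
        c_in = f
    for _ in range(cfg.extra_conv_blocks):
        rows.append(LayerSpec("Conv2D", "conv", (h, w, c_in), conv_params(3, c_in, c_in), (3, 3), act))
    flat = h * w * c_in
    rows.append(LayerSpec("Flatten", "flatten", (flat,), 0))
    rows.append(LayerSpec("Dense", "dense", (cfg.dense_units,), dense_params(flat, cfg.dense_units), None, act))
    rows.append(LayerSpec("Dropout", "dropout", (cfg.dense_units,), 0))
    rows.append(LayerSpec("Dense", "dense", (cfg.n_classes,),
                          dense_params(cfg.dense_units, cfg.n_classes), None, "Softmax"))
    return ModelSpec(rows)


def reference_lwcnn_table() -> ModelSpec:
    """The canonical layer table for the default config (64x64x3 ingress)."""
    return _lwcnn_spec(LWCNNConfig())


def build_lwcnn(cfg: LWCNNConfig | None = None, seed: int = 0) -> Sequential:
    """Construct the seeded classifier; validates the default config's layer
    ladder against the reference table and raises naming the first divergent
    layer if the shape arithmetic ever disagrees."""
    cfg = cfg or LWCNNConfig()
    h, w = cfg.input_hw
    for i in range(len(cfg.conv_filters)):
        h, w = (h - 2) // 2, (w - 2) // 2
        if h < 1 or w < 1:
            raise ValueError(f"input {cfg.input_hw} too small for conv block {i + 1}")
    spec = _lwcnn_spec(cfg)
    if cfg == LWCNNConfig():
        for got, want in zip(spec.layers, reference_lwcnn_table().layers):
            if got != want:
                raise AssertionError(f"layer {want.name}: built {got}, reference {want}")
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = cfg.in_channels
    for i, f in enumerate(cfg.conv_filters):
        layers.append(Conv2D(c_in, f, kernel=3, padding="valid", activation=cfg.activation,
                             l2=cfg.l2, rng=rng, name=f"conv{i + 1}"))
        layers.append(MaxPool2D(name=f"pool{i + 1}"))
        if i >= 1:
            layers.append(Dropout(cfg.dropout_conv, rng=rng, name=f"drop{i + 1}"))
        c_in = f
    for j in range(cfg.extra_conv_blocks):
        layers.append(Conv2D(c_in, c_in, kernel=3, padding="same", activation=cfg.activation,
                             l2=cfg.l2, rng=rng, name=f"extra_conv{j + 1}"))
    hh, ww = cfg.input_hw
    for _ in cfg.conv_filters:
        hh, ww = (hh - 2) // 2, (ww - 2) // 2
    layers.append(Flatten())
    layers.append(Dense(hh * ww * c_in, cfg.dense_units, activation=cfg.activation,
                        l2=cfg.l2, rng=rng, name="dense1"))
    layers.append(Dropout(cfg.dropout_dense, rng=rng, name="drop_dense"))
    layers.append(Dense(cfg.dense_units, cfg.n_classes, activation="softmax",
                        rng=rng, name="head", fused_head=True))
    model = Sequential(layers, spec=spec)
    model.cfg = cfg
    return model


def stratified_kfold(labels, k: int = 5, seed: int = 0, val_fraction: float = 0.25) -> list[FoldSplit]:
    """Stratified k-fold splits with an inner train:val split of the
    non-test remainder (default 75:25)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    short = classes[counts < k]
    if short.size:
        raise ValueError(f"classes with fewer than {k} samples: {short.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_index, (rest, test) in enumerate(skf.split(np.zeros(len(labels)), labels), start=1):
        train, val = train_test_split(
            rest, test_size=val_fraction, stratify=labels[rest],
            random_state=seed + fold_index,
        )
        folds.append(FoldSplit(fold_index, np.sort(train), np.sort(val), np.sort(test)))
    return folds


def _check_fold_hygiene(folds: list[FoldSplit], n: int) -> None:
    all_test = np.concatenate([f.test_idx for f in folds])
    if len(np.unique(all_test)) != n or len(all_test) != n:
        raise ValueError("test folds do not partition the dataset")
    for f in folds:
        parts = np.concatenate([f.train_idx, f.val_idx, f.test_idx])
        if len(np.unique(parts)) != len(parts):
            raise ValueError(f"fold {f.fold_index} leaks indices between splits")


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


def _accuracy(y_onehot, p):
    return float(np.mean(p.argmax(-1) == y_onehot.argmax(-1)))


def train_classifier(
    x: np.ndarray,
    y: np.ndarray,
    folds: list[FoldSplit],
    cfg: LWCNNConfig | None = None,
    policy: TrainingPolicy | None = None,
    seed: int = 0,
    augment_fn=None,
    stop_accuracy: float | None = None,
    verbose: bool = False,
) -> list[FoldResult]:
    """Train one model per fold on that fold's train split only.

    ``x``: (N,64,64,3) unit-scaled ROIs; ``y``: integer labels.
    ``augment_fn(images, rng) -> images`` is applied to the training split
    of each fold (never to validation or test).  Per-fold seeds are
    ``seed + fold_index`` for reproducibility.
    """
    cfg = cfg or LWCNNConfig()
    policy = policy or TrainingPolicy(loss="cce", max_epochs=30)
    if policy.loss != "cce":
        raise ValueError("classification uses categorical cross-entropy")
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    _check_fold_hygiene(folds, len(x))
    results = []
    for f in folds:
        fold_seed = seed + f.fold_index
        model = build_lwcnn(cfg, seed=fold_seed)
        xt, yt = x[f.train_idx], y[f.train_idx]
        if augment_fn is not None:
            rng = np.random.default_rng(fold_seed)
            xt = augment_fn(xt, rng)
            yt = np.asarray(y[f.train_idx])
        hist = fit(
            model,
            xt, _one_hot(yt, cfg.n_classes),
            x[f.val_idx], _one_hot(y[f.val_idx], cfg.n_classes),
            policy, seed=fold_seed,
            metric_fns={"val_accuracy": _accuracy},
            stop_metric="val_accuracy" if stop_accuracy is not None else None,
            stop_value=stop_accuracy,
            verbose=verbose,
        )
        prob = np.concatenate(
            [model.forward(x[f.test_idx][i : i + 64]) for i in range(0, len(f.test_idx), 64)]
        )
        pred = prob.argmax(-1)
        acc = float(np.mean(pred == y[f.test_idx]))
        results.append(FoldResult(f.fold_index, model, hist, acc, y[f.test_idx], pred, prob))
    return results


def predict_proba(model: Sequential, roi: np.ndarray) -> ClassProbabilities:
    """Class probabilities for a single preprocessed ROI."""
    roi = np.asarray(roi, dtype=np.float32)
    if roi.ndim != 3:
        raise ValueError(f"expected one (H,W,C) ROI, got shape {roi.shape}")
    p = model.forward(roi[None], training=False)[0]
    k = int(p.argmax())
    return ClassProbabilities(probs=p, predicted_class=k, confidence=float(p[k]))
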