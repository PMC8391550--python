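"""The two per-pixel tissue classifiers: a compact 3-D CNN and an RBF-SVM.

Both models consume 5 x 5 x 100 sub-volumes and emit one score per class; the
predicted class is the argmax (ties broken toward the lowest class code). The
CNN sees the full sub-volume; the SVM path first reduces it to 100 per-wavelength
features (spatial mean) and standardizes each band with a scaler fitted on the
training fold only.

The CNN has 6 three-dimensional convolutional hidden layers that down-sample the
spectral axis (100 -> 50 -> 25 -> 13) while shrinking the spatial window
(5 -> 3 -> 1), one fully connected hidden layer, and a 7-neuron output layer.
At the default configuration it has exactly 32,628 trainable parameters. It is
trained with Adam (learning rate 0.001) on a class-weighted cross-entropy loss,
with weights inversely proportional to per-class training counts — essential
because the annotated data are severely imbalanced (skin outnumbers nerve by
more than an order of magnitude).

The SVM is scikit-learn's ``SVC`` at its defaults: RBF kernel, C = 1. Per-class
scores for ROC analysis come from the one-vs-rest decision function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.svm import SVC

from . import nn
from .core import DEFAULT_CLASSES, HSICube, TissueClassSet
from .preprocess import (
    BandScaler,
    SubVolume,
    SubVolumeDataset,
    extract_subvolume,
    snv_normalize_cube,
    svm_features,
)


class PreprocessingMismatch(ValueError):
    """Inference input preprocessing does not match training preprocessing."""


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters for the 3-D CNN.

    ``channels`` are the output channels of the six convolutional layers;
    ``hidden`` the width of the fully connected hidden layer. The defaults give
    exactly 32,628 trainable parameters at (window=5, n_bands=100, n_classes=7).
    Epochs, batch size and the fixed-epoch stopping rule are desk-scale training
    defaults; all randomness is governed by ``seed``.
    """

    window: int = 5
    n_bands: int = 100
    n_classes: int = 7
    channels: tuple = (8, 8, 21, 21, 21, 40)
    hidden: int = 44
    learning_rate: float = 0.001
    epochs: int = 12
    batch_size: int = 256
    seed: int = 0


@dataclass
class SVMConfig:
    """RBF-kernel SVM at scikit-learn defaults (C = 1, gamma = 'scale')."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: str = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("regularization parameter C must be > 0")


@dataclass
class ClassWeights:
    """Per-class loss weights, proportional to 1/n_c, normalized to sum to K."""

    weights: np.ndarray  # index = class code - 1
    class_set: TissueClassSet = field(default_factory=TissueClassSet)


def compute_class_weights(
    counts: dict, class_set: TissueClassSet = DEFAULT_CLASSES
) -> ClassWeights:
    """Weights inversely proportional to per-class training counts.

    ``counts`` maps class code -> n_c; every class must be present (a class
    missing from a training fold is a fold-construction bug, not a weighting
    question). Any positive rescaling is loss-equivalent up to the learning
    rate; the convention here normalizes the weights to sum to K.
    """
    k = class_set.n_classes
    n = np.zeros(k)
    for code in class_set.codes:
        if code not in counts or counts[code] < 1:
            raise ValueError(
                f"class '{class_set.label(code)}' has no training samples; "
                "cannot compute its loss weight"
            )
        n[code - 1] = counts[code]
    inv = 1.0 / n
    return ClassWeights(inv * (k / inv.sum()), class_set)


@dataclass
class ClassifierModel:
    """A trained (or untrained) per-pixel classifier with preprocessing provenance."""

    kind: str  # "cnn" | "svm"
    class_set: TissueClassSet
    normalization: str = "none"
    network: nn.Network | None = None
    cnn_config: CNNConfig | None = None
    estimator: SVC | None = None
    scaler: BandScaler | None = None
    trained: bool = False
    train_subjects: tuple = ()
    training_log: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        if self.kind != "cnn":
            raise ValueError("parameter count is defined for the CNN only")
        return self.network.n_params


def _cnn_layers(config: CNNConfig) -> list:
    c1, c2, c3, c4, c5, c6 = config.channels
    layers = [
        nn.Conv3d(1, c1, (3, 3, 3), stride=(1, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(c1, c2, (3, 1, 1), stride=(2, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(c2, c3, (3, 3, 3), stride=(1, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(c3, c4, (3, 1, 1), stride=(2, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(c4, c5, (3, 1, 1), stride=(1, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
        nn.Conv3d(c5, c6, (2, 1, 1), stride=(2, 1, 1), padding=(1, 0, 0)),
        nn.ReLU(),
    ]
    shape = (config.n_bands, config.window, config.window)
    for layer in layers:
        if isinstance(layer, nn.Conv3d):
            shape = layer.out_shape(shape)
    flat = layers[-2].out_channels * int(np.prod(shape))
    layers += [
        nn.Flatten(),
        nn.Dense(flat, config.hidden),
        nn.ReLU(),
        nn.Dense(config.hidden, config.n_classes),
    ]
    return layers


def build_cnn(
    config: CNNConfig | None = None, class_set: TissueClassSet = DEFAULT_CLASSES
) -> ClassifierModel:
    """Construct the (untrained) 3-D CNN.

    Six spectral-down-sampling convolutional hidden layers, one fully connected
    hidden layer, and an output layer with one neuron per class. Raises if the
    layer arithmetic collapses a dimension for the given window/band counts.
    """
    config = config or CNNConfig(n_classes=class_set.n_classes)
    network = nn.Network(_cnn_layers(config), seed=config.seed)
    return ClassifierModel(
        kind="cnn", class_set=class_set, network=network, cnn_config=config
    )


def _to_batch(values: np.ndarray) -> np.ndarray:
    """(n, w, w, B) sub-volumes -> (n, 1, B, w, w) network input."""
    return np.ascontiguousarray(values.transpose(0, 3, 1, 2)[:, None, :, :, :]).astype(
        np.float32
    )


def train_cnn(
    model: ClassifierModel, dataset: SubVolumeDataset, config: CNNConfig | None = None
) -> ClassifierModel:
    """Train the CNN with Adam on class-weighted cross-entropy.

    Every class must be present in the dataset (weights are undefined
    otherwise). Sample order is reshuffled each epoch from the seeded stream, so
    training is deterministic given (seed, data). The per-epoch mean loss is
    appended to ``model.training_log``.
    """
    config = config or model.cnn_config
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    weights = compute_class_weights(dataset.class_counts(), dataset.class_set).weights
    x = _to_batch(dataset.values)
    y = dataset.labels - 1  # 0-based for the loss
    rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.Adam(model.network, lr=config.learning_rate)
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.network.forward(x[idx], train=True)
            loss, dlogits = nn.weighted_cross_entropy(logits, y[idx], weights)
            model.network.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        model.training_log.append((epoch, float(np.mean(losses))))
    model.trained = True
    model.normalization = dataset.normalization
    model.train_subjects = tuple(sorted(set(dataset.subject_ids)))
    return model


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    config: SVMConfig | None = None,
    scaler: BandScaler | None = None,
    class_set: TissueClassSet = DEFAULT_CLASSES,
    normalization: str = "none",
    train_subjects: tuple = (),
) -> ClassifierModel:
    """Fit the RBF-SVM on band-auto-scaled per-wavelength features.

    ``scaler`` must have been fitted on these training features only; it is
    stored inside the model so inference cannot bypass it. Requires at least two
    classes in ``labels``.
    """
    config = config or SVMConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("SVM training requires at least two classes")
    if scaler is None:
        scaler = BandScaler.fit(features)
    estimator = SVC(
        C=config.C,
        kernel=config.kernel,
        gamma=config.gamma,
        decision_function_shape="ovr",
        random_state=config.seed,
    )
    estimator.fit(scaler.transform(features), labels)
    return ClassifierModel(
        kind="svm",
        class_set=class_set,
        normalization=normalization,
        estimator=estimator,
        scaler=scaler,
        trained=True,
        train_subjects=tuple(sorted(train_subjects)),
    )


def _check_provenance(model: ClassifierModel, normalization: str) -> None:
    if normalization != model.normalization:
        raise PreprocessingMismatch(
            f"model was trained with normalization='{model.normalization}' but input "
            f"declares '{normalization}'"
        )


def predict_scores_batch(
    model: ClassifierModel, values: np.ndarray, normalization: str = "none"
) -> np.ndarray:
    """Per-class scores for an (n, w, w, B) batch of sub-volumes.

    ``normalization`` declares the preprocessing already applied to the inputs;
    it must match the model's training preprocessing (provenance is enforced,
    not trusted). Higher score = more likely; scores are comparable across
    pixels, as ROC analysis requires.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    _check_provenance(model, normalization)
    values = np.asarray(values, dtype=np.float32)
    if values.ndim == 3:
        values = values[None]
    if model.kind == "cnn":
        cfg = model.cnn_config
        if values.shape[1:] != (cfg.window, cfg.window, cfg.n_bands):
            raise ValueError(
                f"expected sub-volumes of shape {(cfg.window, cfg.window, cfg.n_bands)}, "
                f"got {values.shape[1:]}"
            )
        out = []
        for start in range(0, len(values), 1024):
            out.append(model.network.forward(_to_batch(values[start : start + 1024])))
        scores = np.concatenate(out, axis=0)
    else:
        feats = svm_features(values)
        scores = model.estimator.decision_function(model.scaler.transform(feats))
        if scores.ndim == 1:  # binary SVC returns one column
            scores = np.column_stack([-scores, scores])
        # SVC orders columns by sorted class label; map back to code order 1..K
        full = np.full((len(feats), model.class_set.n_classes), -np.inf)
        for j, code in enumerate(model.estimator.classes_):
            full[:, int(code) - 1] = scores[:, j]
        scores = full
    if np.isnan(scores).any():
        raise ValueError("classifier produced NaN scores")
    return scores


def predict_scores(
    model: ClassifierModel, sub: SubVolume, normalization: str = "none"
) -> np.ndarray:
    """Scores for a single sub-volume; see :func:`predict_scores_batch`."""
    return predict_scores_batch(model, sub.values[None], normalization)[0]


def classify(scores: np.ndarray) -> int:
    """Argmax class code (1-based); exact ties break toward the lowest code."""
    scores = np.asarray(scores)
    if np.isnan(scores).any():
        raise ValueError("cannot classify NaN scores")
    return int(np.argmax(scores)) + 1


def classify_batch(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores)
    if np.isnan(scores).any():
        raise ValueError("cannot classify NaN scores")
    return np.argmax(scores, axis=1) + 1


def predict_dataset(model: ClassifierModel, dataset: SubVolumeDataset) -> tuple:
    """(predicted codes, score matrix) for every sample of a labeled dataset."""
    scores = predict_scores_batch(model, dataset.values, dataset.normalization)
    return classify_batch(scores), scores


def predict_image(
    model: ClassifierModel,
    cube: HSICube,
    pixels: list | None = None,
    window: int = 5,
) -> tuple:
    """Per-pixel prediction over a hypercube.

    ``pixels`` is a list of (row, col); ``None`` means dense full-image
    prediction. The model's training-time normalization is applied to the cube
    here, so provenance is consistent by construction. Returns ``(label_map,
    score_maps)`` where unrequested pixels hold 0 / NaN.
    """
    if model.normalization == "snv":
        cube = snv_normalize_cube(cube)
    h, w, _ = cube.shape
    if pixels is None:
        pixels = [(r, c) for r in range(h) for c in range(w)]
    for r, c in pixels:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"pixel ({r}, {c}) outside cube of shape {h} x {w}")
    values = np.stack(
        [extract_subvolume(cube, (r, c), window).values for r, c in pixels]
    )
    scores = predict_scores_batch(model, values, model.normalization)
    labels = classify_batch(scores)
    label_map = np.zeros((h, w), dtype=np.uint8)
    score_maps = np.full((h, w, model.class_set.n_classes), np.nan)
    for (r, c), lab, s in zip(pixels, labels, scores):
        label_map[r, c] = lab
        score_maps[r, c] = s
    return label_map, score_maps


def save_model(model: ClassifierModel, path) -> None:
    """Persist a trained model (parameters + config + preprocessing provenance)."""
    payload = {
        "kind": model.kind,
        "labels": model.class_set.labels,
        "normalization": model.normalization,
        "train_subjects": model.train_subjects,
        "cnn_config": model.cnn_config,
        "state": model.network.state() if model.kind == "cnn" else None,
        "estimator": model.estimator,
        "scaler": model.scaler,
        "training_log": model.training_log,
    }
    joblib.dump(payload, path)


def load_model(path) -> ClassifierModel:
    payload = joblib.load(path)
    class_set = TissueClassSet(tuple(payload["labels"]))
    if payload["kind"] == "cnn":
        model = build_cnn(payload["cnn_config"], class_set)
        model.network.load_state(payload["state"])
    else:
        model = ClassifierModel(
            kind="svm",
            class_set=class_set,
            estimator=payload["estimator"],
            scaler=payload["scaler"],
        )
    model.normalization = payload["normalization"]
    model.train_subjects = tuple(payload["train_subjects"])
    model.training_log = list(payload["training_log"])
    model.trained = True
    return model
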