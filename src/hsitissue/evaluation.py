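"""Leave-one-subject-out cross-validation and the full metric suite.

Generalization to *new subjects* is the clinically relevant question, and
between-subject spectral shifts are the dominant source of intra-class
variation, so evaluation is leave-one-patient-out (LOPOCV): each subject is held
out once while models train on all others. All fold-level preprocessing (band
scaler, class weights) is fitted strictly on the training subjects.

Metrics follow the standard segmentation-evaluation suite: row-normalized
confusion matrices (the diagonal is per-class sensitivity), one-vs-all
sensitivity / specificity / Dice (DSC = 2TP/(2TP+FP+FN), the F1 score), macro
averages, per-class ROC curves with trapezoidal AUC, and two-tailed paired
t-tests across folds for model comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from .classifiers import (
    CNNConfig,
    SVMConfig,
    build_cnn,
    predict_dataset,
    train_cnn,
    train_svm,
)
from .core import DEFAULT_CLASSES, TissueClassSet
from .preprocess import BandScaler, build_dataset, svm_features


def lopocv_split(subject_ids: list) -> list:
    """Leave-one-out folds over subjects: ``[(train_ids, test_id), ...]``.

    Every subject is the test subject exactly once; its samples never appear in
    the corresponding training set. Duplicate ids are an error.
    """
    if len(subject_ids) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    return [
        ([s for s in subject_ids if s != test], test)
        for test in subject_ids
    ]


@dataclass
class ConfusionMatrix:
    """K x K counts; row i, column j = pixels of true class i predicted as j."""

    counts: np.ndarray
    class_set: TissueClassSet = field(default_factory=TissueClassSet)

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized form: each row with support sums to 1; zero-support
        rows are returned as NaN rather than divided."""
        support = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / support
        out[support[:, 0] == 0] = np.nan
        return out

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.class_set)


def confusion(
    true: np.ndarray, predicted: np.ndarray, class_set: TissueClassSet = DEFAULT_CLASSES
) -> ConfusionMatrix:
    """Confusion matrix over class codes 1..K; codes outside the set are errors."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape or true.size == 0:
        raise ValueError("true and predicted labels must be equal-length and nonempty")
    k = class_set.n_classes
    for name, vec in (("true", true), ("predicted", predicted)):
        bad = np.setdiff1d(np.unique(vec), class_set.codes)
        if bad.size:
            raise ValueError(f"{name} labels outside the class set: {bad.tolist()}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (true - 1, predicted - 1), 1)
    return ConfusionMatrix(counts, class_set)


def one_vs_all_metrics(true: np.ndarray, predicted: np.ndarray, code: int) -> dict:
    """Binary sensitivity, specificity and Dice for one class against the rest.

    With zero support for the class, sensitivity and Dice are undefined and
    returned as NaN (flagged missing), never as 0.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    tp = int(np.sum((true == code) & (predicted == code)))
    fn = int(np.sum((true == code) & (predicted != code)))
    fp = int(np.sum((true != code) & (predicted == code)))
    tn = int(np.sum((true != code) & (predicted != code)))
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    dsc = 2 * tp / (2 * tp + fp + fn) if (tp + fn) else float("nan")
    return {"sensitivity": sensitivity, "specificity": specificity, "dsc": dsc}


def macro_average(values) -> float:
    """Unweighted mean over classes with defined (non-NaN) values."""
    values = np.asarray(list(values), dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise ValueError("macro average undefined: no class has a defined value")
    return float(defined.mean())


@dataclass
class ROCData:
    """One-vs-all ROC curve for a single class."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(true_binary: np.ndarray, scores: np.ndarray) -> ROCData:
    """ROC by sweeping the detection threshold over all distinct scores.

    AUC is the trapezoidal area, which equals the probability that a randomly
    chosen positive outscores a randomly chosen negative (ties counted 1/2).
    Requires both positives and negatives.
    """
    true_binary = np.asarray(true_binary).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if true_binary.all() or not true_binary.any():
        raise ValueError("ROC needs both positive and negative samples")
    fpr, tpr, thr = skmetrics.roc_curve(true_binary, scores)
    return ROCData(fpr, tpr, thr, float(skmetrics.auc(fpr, tpr)))


def paired_t_test(a, b) -> dict:
    """Two-tailed paired t-test between per-fold metrics of two models.

    Returns t, degrees of freedom, p and significance stars ('*' for p < 0.05,
    '**' for p < 0.01). Zero difference variance is flagged degenerate, with no
    p reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs equal-length samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return {"t": float("nan"), "df": a.size - 1, "p": float("nan"), "degenerate": True,
                "stars": ""}
    t, p = stats.ttest_rel(a, b)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {"t": float(t), "df": a.size - 1, "p": float(p), "degenerate": False,
            "stars": stars}


@dataclass
class FoldResult:
    """Predictions and per-class metrics for one held-out subject."""

    test_subject: str
    train_subjects: tuple
    true: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray  # n x K
    confusion: ConfusionMatrix
    per_class: dict  # code -> {"sensitivity", "specificity", "dsc"}

    def __post_init__(self) -> None:
        if self.test_subject in self.train_subjects:
            raise ValueError("held-out subject leaked into the training set")
        if len(self.true) != len(self.predicted):
            raise ValueError("label vectors must be equal length")


@dataclass
class CVReport:
    """Assembled LOPOCV results for one model configuration."""

    model_name: str
    class_set: TissueClassSet
    folds: list

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        total = self.folds[0].confusion
        for fold in self.folds[1:]:
            total = total + fold.confusion
        return total

    def per_class_metric(self, metric: str) -> dict:
        """code -> array of per-fold values (NaN where the class was absent)."""
        return {
            code: np.array([f.per_class[code][metric] for f in self.folds])
            for code in self.class_set.codes
        }

    def summary(self, metric: str) -> dict:
        """Per-class mean, SD and standard error across folds (NaN folds excluded).

        Folds where a class has no annotated pixels do not contribute; the
        number of contributing folds is reported alongside.
        """
        out = {}
        for code, values in self.per_class_metric(metric).items():
            defined = values[~np.isnan(values)]
            n = defined.size
            if n == 0:
                out[code] = {"mean": float("nan"), "sd": float("nan"),
                             "se": float("nan"), "n_folds": 0}
                continue
            sd = float(defined.std(ddof=1)) if n > 1 else 0.0
            out[code] = {
                "mean": float(defined.mean()),
                "sd": sd,
                "se": sd / np.sqrt(n),
                "n_folds": n,
            }
        return out

    def macro(self, metric: str) -> float:
        return macro_average(s["mean"] for s in self.summary(metric).values())

    def pooled_sensitivity(self) -> dict:
        """Per-class sensitivity from the pooled confusion diagonal."""
        norm = self.pooled_confusion.normalized
        return {code: float(norm[code - 1, code - 1]) for code in self.class_set.codes}

    def pooled_roc(self) -> dict:
        """One-vs-all ROC per class, pooling test-pixel scores over all folds."""
        true = np.concatenate([f.true for f in self.folds])
        scores = np.vstack([f.scores for f in self.folds])
        out = {}
        for code in self.class_set.codes:
            positives = true == code
            if positives.any() and not positives.all():
                out[code] = roc_curve(positives, scores[:, code - 1])
        return out


MODEL_CONFIGURATIONS = ("CNN", "CNN+SNV", "SVM", "SVM+SNV")


def _parse_configuration(name: str) -> tuple:
    base = name.upper()
    normalization = "none"
    if base.endswith("+SNV"):
        normalization = "snv"
        base = base[:-4]
    if base not in ("CNN", "SVM"):
        raise ValueError(f"unknown model configuration '{name}'")
    return base.lower(), normalization


def run_cv(
    cohort: list,
    model_name: str,
    cnn_config: CNNConfig | None = None,
    svm_config: SVMConfig | None = None,
    window: int = 5,
    seed: int = 0,
) -> CVReport:
    """Run one model configuration (e.g. "CNN" or "SVM+SNV") through LOPOCV.

    Per fold: the dataset is split by subject, the band scaler (SVM) and class
    weights (CNN) are fitted on training subjects only, the model is trained and
    the held-out subject predicted. Every class must appear in every training
    fold. Fully seeded and deterministic.
    """
    kind, normalization = _parse_configuration(model_name)
    dataset = build_dataset(cohort, window=window, normalization=normalization)
    class_set = dataset.class_set
    subject_ids = [s.subject_id if hasattr(s, "subject_id") else s[0].subject_id for s in cohort]
    folds = []
    for i, (train_ids, test_id) in enumerate(lopocv_split(subject_ids)):
        train, test = dataset.split_by_subject(test_id)
        assert set(train.subject_ids) == set(train_ids)
        missing = [
            class_set.label(c) for c in class_set.codes if c not in train.class_counts()
        ]
        if missing:
            raise ValueError(
                f"fold {i} (test subject {test_id}): classes missing from training: {missing}"
            )
        if kind == "cnn":
            config = cnn_config or CNNConfig(
                window=window, n_bands=dataset.n_bands, n_classes=class_set.n_classes
            )
            fold_config = CNNConfig(**{**config.__dict__, "seed": config.seed + seed + i})
            model = build_cnn(fold_config, class_set)
            train_cnn(model, train, fold_config)
        else:
            config = svm_config or SVMConfig()
            feats = svm_features(train.values)
            scaler = BandScaler.fit(feats)
            model = train_svm(
                feats,
                train.labels,
                config,
                scaler,
                class_set,
                normalization=normalization,
                train_subjects=tuple(set(train.subject_ids)),
            )
        model.train_subjects = tuple(sorted(set(train.subject_ids)))
        predicted, scores = predict_dataset(model, test)
        per_class = {
            code: one_vs_all_metrics(test.labels, predicted, code)
            for code in class_set.codes
        }
        folds.append(
            FoldResult(
                test_subject=test_id,
                train_subjects=tuple(sorted(train_ids)),
                true=test.labels,
                predicted=predicted,
                scores=scores,
                confusion=confusion(test.labels, predicted, class_set),
                per_class=per_class,
            )
        )
    return CVReport(model_name.upper(), class_set, folds)


def compare_models(reports: dict, metric: str = "dsc") -> dict:
    """Pairwise paired t-tests across folds between model configurations.

    For each model pair and class, per-fold metric values are paired by held-out
    subject. Returns ``{(name_a, name_b): {code: t-test dict}}``.
    """
    names = list(reports)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            per_pair = {}
            for code in reports[a].class_set.codes:
                va = reports[a].per_class_metric(metric)[code]
                vb = reports[b].per_class_metric(metric)[code]
                ok = ~(np.isnan(va) | np.isnan(vb))
                if ok.sum() >= 2:
                    per_pair[code] = paired_t_test(va[ok], vb[ok])
            out[(a, b)] = per_pair
    return out
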