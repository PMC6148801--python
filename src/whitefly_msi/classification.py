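"""Pixel-level species classifiers and the median-probability image rule.

Two classifiers are provided. For benchtop leaf scenes a linear PLS-DA
(partial least squares regression onto one-hot class indicators, argmax
decision) is trained on a fixed number of randomly drawn samples per
species. For the high-resolution trials a two-class support-vector
classifier with probabilistic output is fitted on body-pixel features,
always on a *grouped* split: pixels of one image never straddle the
train/test boundary.

An image is classified from its body pixels by the median rule: predict
class 1 iff the median over pixels of P(class = 1) exceeds 0.5 (strict).
Images with fewer body pixels than a minimum count abstain and are excluded
from scoring rather than counted as errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "AutoscaleStats",
    "LabelledPixels",
    "ClassifierModel",
    "ImageClassification",
    "autoscale",
    "apply_autoscale",
    "fit_plsda",
    "fit_svc_grouped",
    "predict_pixel_probs",
    "predict_labels",
    "classify_image_median",
    "classify_images",
]


@dataclass
class AutoscaleStats:
    """Column means and standard deviations for autoscaling reuse."""

    mean: np.ndarray
    std: np.ndarray


def autoscale(features: np.ndarray) -> tuple[np.ndarray, AutoscaleStats]:
    """Mean-centre and scale each column to unit (population) standard deviation.

    Zero-variance columns get scale 1 (they centre to zero); logged, not fatal.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    degenerate = std == 0
    if np.any(degenerate):
        logger.warning("autoscale: %d zero-variance column(s); scale set to 1",
                       int(degenerate.sum()))
        std = np.where(degenerate, 1.0, std)
    stats = AutoscaleStats(mean=mean, std=std)
    return apply_autoscale(x, stats), stats


def apply_autoscale(features: np.ndarray, stats: AutoscaleStats) -> np.ndarray:
    return (np.asarray(features, dtype=float) - stats.mean) / stats.std


@dataclass
class LabelledPixels:
    """Feature rows with class labels and source-image identifiers."""

    features: np.ndarray
    labels: np.ndarray
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.image_ids = np.asarray(self.image_ids)
        n = self.features.shape[0]
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("features must be a non-empty N x F matrix")
        if len(self.labels) != n or len(self.image_ids) != n:
            raise ValueError("labels/image_ids must match the feature row count")


@dataclass
class ClassifierModel:
    """A fitted pixel classifier (``kind`` in {svc, plsda}).

    ``classes`` fixes the order: ``classes[1]`` is "class 1", the class whose
    per-pixel probability feeds the image-level median rule. For the
    two-class task that is the viral-vector class (SSA1).
    """

    kind: str
    estimator: object
    scaler: AutoscaleStats
    classes: tuple
    split_train_ids: tuple = ()

    def positive_class(self):
        return self.classes[1]


def fit_plsda(
    pixels: LabelledPixels,
    n_latent: int = 5,
    n_train_per_class: int = 20,
    seed: int = 0,
) -> ClassifierModel:
    """PLS-DA: autoscaled features regressed onto one-hot class indicators.

    ``n_train_per_class`` samples per class are drawn without replacement
    with the given seed (the benchtop protocol used 20 per species); the
    remainder is available for holdout scoring. Multiclass capable; the
    decision is the argmax of the predicted indicators.
    """
    x, y, ids = pixels.features, pixels.labels, pixels.image_ids
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    if n_latent >= x.shape[1] + 1 or n_latent >= x.shape[0]:
        raise ValueError("n_latent must be below both the feature and sample counts")
    rng = np.random.default_rng(seed)
    train_idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        if len(members) < n_train_per_class:
            raise ValueError(
                f"class {c!r} has {len(members)} samples; need {n_train_per_class}"
            )
        train_idx.append(rng.choice(members, size=n_train_per_class, replace=False))
    train_idx = np.sort(np.concatenate(train_idx))

    xs, stats = autoscale(x[train_idx])
    onehot = np.stack([(y[train_idx] == c).astype(float) for c in classes], axis=1)
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(xs, onehot)
    return ClassifierModel(
        kind="plsda",
        estimator=pls,
        scaler=stats,
        classes=tuple(classes),
        split_train_ids=tuple(sorted(set(np.asarray(ids)[train_idx].tolist()))),
    )


def fit_svc_grouped(
    pixels: LabelledPixels,
    split,
    C: float = 1.0,
    kernel: str = "rbf",
    gamma="scale",
    seed: int = 0,
    max_train_pixels: int | None = None,
    positive_label=None,
) -> ClassifierModel:
    """Two-class SVC with probability outputs, trained on the split's train images.

    ``split`` is an :class:`~whitefly_msi.evaluation.GroupedSplit`; only
    pixels whose ``image_id`` is in ``split.train_image_ids`` are used for
    fitting, and any overlap between train and test identifier sets is a
    hard error (leakage guard). ``max_train_pixels`` optionally subsamples
    the training pixels (seeded) to bound fit time.
    """
    train_ids = set(split.train_image_ids)
    test_ids = set(split.test_image_ids)
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"leakage: image ids in both train and test: {sorted(overlap)}")
    in_train = np.isin(pixels.image_ids, sorted(train_ids))
    x, y = pixels.features[in_train], pixels.labels[in_train]
    leaked = set(np.unique(pixels.image_ids[in_train]).tolist()) & test_ids
    if leaked:
        raise ValueError(f"leakage: test image ids present in training pixels: {sorted(leaked)}")
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"two-class SVC requires exactly 2 classes in training data, got {list(uniq)}")
    if positive_label is None:
        positive_label = "SSA1" if "SSA1" in uniq else sorted(uniq.tolist())[-1]
    negative_label = [u for u in uniq.tolist() if u != positive_label][0]

    if max_train_pixels is not None and len(y) > max_train_pixels:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(y), size=max_train_pixels, replace=False)
        x, y = x[keep], y[keep]
        if len(np.unique(y)) != 2:  # pragma: no cover - pathological subsample
            raise ValueError("training subsample lost a class; raise max_train_pixels")

    xs, stats = autoscale(x)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecation notice for probability=True; the Platt
        # calibration it performs is exactly what the median rule needs.
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(C=C, kernel=kernel, gamma=gamma, probability=True, random_state=int(seed))
        svc.fit(xs, y)
    return ClassifierModel(
        kind="svc",
        estimator=svc,
        scaler=stats,
        classes=(negative_label, positive_label),
        split_train_ids=tuple(sorted(train_ids)),
    )


def predict_pixel_probs(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Per-row P(class = 1) in [0, 1]; P(class 0) is its complement.

    For PLS-DA the predicted one-hot indicators are clipped to [0, 1] and
    normalised (uniform fallback when every indicator clips to zero).
    """
    x = np.asarray(features, dtype=float)
    if x.shape[1] != len(model.scaler.mean):
        raise ValueError(
            f"feature count {x.shape[1]} does not match model ({len(model.scaler.mean)})"
        )
    xs = apply_autoscale(x, model.scaler)
    if model.kind == "svc":
        proba = model.estimator.predict_proba(xs)
        col = list(model.estimator.classes_).index(model.positive_class())
        return proba[:, col]
    if model.kind == "plsda":
        yhat = np.clip(model.estimator.predict(xs), 0.0, None)
        total = yhat.sum(axis=1, keepdims=True)
        uniform = np.full_like(yhat, 1.0 / yhat.shape[1])
        probs = np.where(total > 0, yhat / np.where(total > 0, total, 1.0), uniform)
        col = list(model.classes).index(model.positive_class())
        return probs[:, col]
    raise ValueError(f"unknown model kind {model.kind!r}")


def predict_labels(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Per-row class prediction (argmax / sign of probability)."""
    xs = apply_autoscale(np.asarray(features, dtype=float), model.scaler)
    if model.kind == "svc":
        return model.estimator.predict(xs)
    if model.kind == "plsda":
        yhat = model.estimator.predict(xs)
        return np.asarray(model.classes, dtype=object)[np.argmax(yhat, axis=1)]
    raise ValueError(f"unknown model kind {model.kind!r}")


@dataclass
class ImageClassification:
    """Image-level decision from body-pixel class-1 probabilities."""

    image_id: str
    pixel_probs: np.ndarray
    median_prob: float
    decision: int  # 1 iff median_prob > 0.5 (strict), else 0; -1 when abstained
    abstained: bool

    @property
    def n_body_pixels(self) -> int:
        return len(self.pixel_probs)


def classify_image_median(
    probs: np.ndarray, image_id: str = "", min_pixels: int = 0
) -> ImageClassification:
    """Median-probability image rule with a minimum-pixel abstention gate.

    With fewer than ``min_pixels`` body pixels the image abstains (excluded
    from scoring). Otherwise the decision is class 1 iff median(P(1)) > 0.5,
    a strict inequality, so an exact 0.5 median falls to class 0. The median
    of an even count is the standard linear-interpolation midpoint.
    """
    probs = np.asarray(probs, dtype=float)
    if len(probs) < min_pixels or len(probs) == 0:
        return ImageClassification(
            image_id=image_id,
            pixel_probs=probs,
            median_prob=float(np.median(probs)) if len(probs) else float("nan"),
            decision=-1,
            abstained=True,
        )
    med = float(np.median(probs))
    return ImageClassification(
        image_id=image_id,
        pixel_probs=probs,
        median_prob=med,
        decision=int(med > 0.5),
        abstained=False,
    )


def classify_images(
    model: ClassifierModel,
    pixels: LabelledPixels,
    min_pixels: int = 0,
) -> list[ImageClassification]:
    """Apply the pixel classifier and median rule per image in ``pixels``."""
    probs = predict_pixel_probs(model, pixels.features)
    results = []
    for image_id in np.unique(pixels.image_ids):
        sel = pixels.image_ids == image_id
        results.append(
            classify_image_median(probs[sel], image_id=str(image_id), min_pixels=min_pixels)
        )
    return results
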