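"""Grouped splitting and the accuracy-vs-(wavebands x min-pixels) surface.

The dataset is split at the *image* level, roughly 50:50 per class, so that
no image contributes pixels to both sides (the grouped-split constraint).
One split is reused across the whole evaluation grid so its cells are
comparable. For each waveband count the body-pixel features are resampled,
a two-class SVC is fitted on the training images and scored on the test
images; image-level accuracy is then tabulated for each minimum-pixel
inclusion threshold, with abstaining images excluded from (not counted
against) the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import (
    LabelledPixels,
    classify_image_median,
    fit_svc_grouped,
    predict_pixel_probs,
)
from .segmentation import PixelSpectraTable
from .spectral_features import BandWindow, DEFAULT_WINDOW, make_scheme, resample_wavebands

__all__ = [
    "GroupedSplit",
    "grouped_split",
    "evaluate_grid",
    "accuracy_curves",
    "plot_accuracy_curves",
]

DEFAULT_MIN_PIXELS = (50, 100, 150, 200, 250)


@dataclass(frozen=True)
class GroupedSplit:
    """Disjoint train/test image-identifier sets covering all images."""

    train_image_ids: tuple
    test_image_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_image_ids), set(self.test_image_ids)
        if train & test:
            raise ValueError(f"split is not disjoint: {sorted(train & test)}")
        if not train or not test:
            raise ValueError("both sides of the split must be non-empty")


def grouped_split(
    image_ids, labels, fraction: float = 0.5, seed: int = 0
) -> GroupedSplit:
    """Seeded per-class image shuffle; first ceil(fraction * n) go to train.

    ``image_ids``/``labels`` are parallel per-image sequences (one entry per
    image). Every class must have at least 2 images so both sides of the
    split contain every class.
    """
    image_ids = np.asarray(image_ids)
    labels = np.asarray(labels)
    if len(image_ids) != len(labels):
        raise ValueError("image_ids and labels must be parallel")
    if len(np.unique(image_ids)) != len(image_ids):
        raise ValueError("image_ids must be unique (one entry per image)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in sorted(np.unique(labels).tolist()):
        members = image_ids[labels == c]
        if len(members) < 2:
            raise ValueError(f"class {c!r} has {len(members)} image(s); need >= 2 to split")
        order = rng.permutation(len(members))
        n_train = math.ceil(fraction * len(members))
        if n_train >= len(members):
            n_train = len(members) - 1  # keep at least one test image per class
        train.extend(members[order[:n_train]].tolist())
        test.extend(members[order[n_train:]].tolist())
    return GroupedSplit(
        train_image_ids=tuple(sorted(train)),
        test_image_ids=tuple(sorted(test)),
        seed=seed,
    )


def evaluate_grid(
    table: PixelSpectraTable,
    image_labels: dict,
    bands_list,
    min_pixels_list,
    split: GroupedSplit,
    seed: int = 0,
    window: BandWindow = DEFAULT_WINDOW,
    svc_kwargs: dict | None = None,
    max_train_pixels: int | None = 4000,
) -> pd.DataFrame:
    """Accuracy surface over waveband counts and minimum-pixel thresholds.

    ``table`` holds body-pixel spectra on the trimmed (and, if desired,
    median-filtered) wavelength axis; ``image_labels`` maps image_id ->
    class. Returns a tidy DataFrame with one row per (n_bands, min_pixels)
    cell: image accuracy (NaN when every test image abstains), the
    per-n_bands pixel accuracy, and scored/abstained counts.
    """
    svc_kwargs = svc_kwargs or {}
    labels_row = np.asarray([image_labels[i] for i in table.image_ids.tolist()], dtype=object)
    rows = []
    for n_bands in bands_list:
        scheme = make_scheme(window, int(n_bands))
        resampled = resample_wavebands(table, scheme)
        pixels = LabelledPixels(
            features=resampled.spectra, labels=labels_row, image_ids=table.image_ids
        )
        model = fit_svc_grouped(
            pixels, split, seed=seed, max_train_pixels=max_train_pixels, **svc_kwargs
        )
        in_test = np.isin(table.image_ids, split.test_image_ids)
        probs = predict_pixel_probs(model, resampled.spectra[in_test])
        test_ids = table.image_ids[in_test]
        truth_pos = labels_row[in_test] == model.positive_class()
        pixel_acc = float(np.mean((probs > 0.5) == truth_pos))

        per_image = {}
        for image_id in split.test_image_ids:
            per_image[image_id] = probs[test_ids == image_id]
        for min_pixels in min_pixels_list:
            correct = scored = abstained = 0
            for image_id in split.test_image_ids:
                res = classify_image_median(
                    per_image[image_id], image_id=str(image_id), min_pixels=int(min_pixels)
                )
                if res.abstained:
                    abstained += 1
                    continue
                scored += 1
                truth = int(image_labels[image_id] == model.positive_class())
                correct += int(res.decision == truth)
            rows.append(
                {
                    "n_bands": int(n_bands),
                    "min_pixels": int(min_pixels),
                    "image_accuracy": correct / scored if scored else float("nan"),
                    "pixel_accuracy": pixel_acc,
                    "images_scored": scored,
                    "images_abstained": abstained,
                }
            )
    return pd.DataFrame(rows)


def accuracy_curves(grid: pd.DataFrame) -> pd.DataFrame:
    """Per min_pixels summary: accuracy series over n_bands plus the plateau.

    The plateau is the smallest n_bands whose image accuracy is within one
    binomial standard error of the series maximum — the point beyond which
    more wavebands buy nothing.
    """
    if grid.empty:
        raise ValueError("empty evaluation grid")
    out = []
    for min_pixels, sub in grid.groupby("min_pixels"):
        sub = sub.sort_values("n_bands")
        scored = sub["images_scored"].to_numpy()
        acc = sub["image_accuracy"].to_numpy()
        valid = ~np.isnan(acc)
        if not valid.any():
            continue
        best = np.nanmax(acc)
        n_best = scored[valid][np.nanargmax(acc[valid])]
        se = math.sqrt(max(best * (1 - best), 1e-12) / max(int(n_best), 1))
        plateau_bands = int(
            sub["n_bands"].to_numpy()[valid][acc[valid] >= best - se].min()
        )
        out.append(
            {
                "min_pixels": int(min_pixels),
                "n_bands": sub["n_bands"].tolist(),
                "image_accuracy": acc.tolist(),
                "pixel_accuracy": sub["pixel_accuracy"].tolist(),
                "max_accuracy": float(best),
                "plateau_n_bands": plateau_bands,
            }
        )
    return pd.DataFrame(out)


def plot_accuracy_curves(grid: pd.DataFrame, path: str) -> None:
    """Export the accuracy surface as a line plot (one line per min_pixels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for min_pixels, sub in grid.groupby("min_pixels"):
        sub = sub.sort_values("n_bands")
        ax.plot(sub["n_bands"], sub["image_accuracy"], marker="o", label=f">= {min_pixels} px")
    first = grid[grid["min_pixels"] == grid["min_pixels"].min()].sort_values("n_bands")
    ax.plot(first["n_bands"], first["pixel_accuracy"], linestyle="--", color="k", label="pixel")
    ax.set_xlabel("number of wavebands")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
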