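"""End-to-end experiment drivers over synthetic scenes.

These functions wire the stages together the way the two laboratory
workflows do:

* benchtop leaf trial: OSAVI masking -> per-insect mean spectra ->
  autoscale -> PLS-DA with a fixed number of training insects per species;
* reference-imager trial: trim -> robust scale -> iPCA -> K-means
  segmentation (anatomy mapped by majority vote against truth) -> body-pixel
  extraction -> median filter -> waveband resampling -> grouped-split SVC ->
  median-probability image decisions over an (n_bands x min_pixels) grid.

They are the workhorses of the test-suite's statistical checks and of the
reproduction script; real-data use composes the same library calls with
manual anatomy mapping instead of truth voting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import LabelledPixels, fit_plsda, predict_labels
from .evaluation import GroupedSplit, evaluate_grid, grouped_split
from .masking import MaskParams, mask_insects
from .segmentation import (
    ANATOMY_BODY,
    PixelSpectraTable,
    SegmentationModel,
    concat_tables,
    cube_to_table,
    fit_segmentation_model,
    map_clusters_to_anatomy,
    segment_cube,
)
from .spectral_features import (
    BandWindow,
    DEFAULT_WINDOW,
    median_filter_spectra,
    trim_bands,
)
from .synthetic_data import SceneConfig, generate_scenes

__all__ = [
    "fit_segmentation_on_scenes",
    "segmentation_agreement",
    "extract_body_pixels",
    "run_waveband_experiment",
    "run_null_calibration",
    "run_leaf_trial",
]


def fit_segmentation_on_scenes(
    scenes,
    seed: int,
    window: BandWindow = DEFAULT_WINDOW,
    max_pixels_per_scene: int | None = 2048,
) -> SegmentationModel:
    """Fit a segmentation model on pooled (sub-sampled) scene pixels.

    Anatomy is attached by majority vote of each cluster against the scenes'
    truth maps — the synthetic stand-in for manual inspection of
    colour-coded cluster images.
    """
    rng = np.random.default_rng(seed)
    tables, truths = [], []
    for cube, truth in scenes:
        table = cube_to_table(trim_bands(cube, window))
        codes = truth.anatomy[table.coords[:, 0], table.coords[:, 1]]
        if max_pixels_per_scene is not None and table.n_pixels > max_pixels_per_scene:
            keep = rng.choice(table.n_pixels, size=max_pixels_per_scene, replace=False)
            table = PixelSpectraTable(
                spectra=table.spectra[keep],
                coords=table.coords[keep],
                image_ids=table.image_ids[keep],
                wavelengths=table.wavelengths,
            )
            codes = codes[keep]
        tables.append(table)
        truths.append(codes)
    pooled = concat_tables(tables)
    model, assignments = fit_segmentation_model(pooled, seed=seed)
    return map_clusters_to_anatomy(
        model, cluster_assignments=assignments, truth_anatomy=np.concatenate(truths)
    )


def segmentation_agreement(
    scenes, model: SegmentationModel, window: BandWindow = DEFAULT_WINDOW
) -> float:
    """Fraction of pixels whose predicted anatomy matches scene truth."""
    agree = total = 0
    for cube, truth in scenes:
        labels = segment_cube(trim_bands(cube, window), model)
        agree += int((labels == truth.anatomy).sum())
        total += labels.size
    return agree / total


def extract_body_pixels(
    scenes,
    window: BandWindow = DEFAULT_WINDOW,
    model: SegmentationModel | None = None,
    median_kernel: int = 5,
) -> tuple[PixelSpectraTable, dict]:
    """Pool body-pixel spectra from scenes, trimmed and median filtered.

    Body pixels come from the segmentation ``model`` when given, otherwise
    from the scenes' truth anatomy. Returns the pooled table and the
    image_id -> class-label mapping read from the scenes.
    """
    tables, labels = [], {}
    for cube, truth in scenes:
        trimmed = trim_bands(cube, window)
        if model is not None:
            body = segment_cube(trimmed, model) == ANATOMY_BODY
        else:
            body = truth.anatomy == ANATOMY_BODY
        if not body.any():
            continue
        tables.append(cube_to_table(trimmed, mask=body))
        labels[cube.image_id] = truth.species
    table = concat_tables(tables)
    if median_kernel > 1:
        table = median_filter_spectra(table, kernel=median_kernel)
    return table, labels


@dataclass
class WavebandExperiment:
    """Outputs of one seeded end-to-end run."""

    grid: pd.DataFrame
    split: GroupedSplit
    segmentation_model: SegmentationModel | None
    segmentation_agreement: float | None


def run_waveband_experiment(
    config: SceneConfig,
    n_scenes_per_class: int,
    bands_list,
    min_pixels_list,
    seed: int,
    window: BandWindow = DEFAULT_WINDOW,
    use_truth_segmentation: bool = False,
    median_kernel: int = 5,
    max_train_pixels: int | None = 4000,
) -> WavebandExperiment:
    """Generate scenes, segment, classify and tabulate the accuracy grid."""
    scenes = generate_scenes(config, n_scenes_per_class, seed=seed)
    image_ids = [cube.image_id for cube, _ in scenes]
    classes = [truth.species for _, truth in scenes]
    split = grouped_split(image_ids, classes, fraction=0.5, seed=seed)

    model = agreement = None
    if not use_truth_segmentation:
        train_scenes = [s for s in scenes if s[0].image_id in split.train_image_ids]
        model = fit_segmentation_on_scenes(train_scenes, seed=seed, window=window)
        agreement = segmentation_agreement(scenes, model, window=window)

    table, labels = extract_body_pixels(
        scenes, window=window, model=model, median_kernel=median_kernel
    )
    grid = evaluate_grid(
        table,
        labels,
        bands_list=bands_list,
        min_pixels_list=min_pixels_list,
        split=split,
        seed=seed,
        window=window,
        max_train_pixels=max_train_pixels,
    )
    return WavebandExperiment(
        grid=grid, split=split, segmentation_model=model, segmentation_agreement=agreement
    )


def run_null_calibration(
    config: SceneConfig,
    n_scenes_per_class: int,
    seeds,
    n_bands: int = 20,
    window: BandWindow = DEFAULT_WINDOW,
    median_kernel: int = 5,
    max_train_pixels: int | None = 4000,
) -> dict:
    """Null-calibration counts pooled over seeds (use with pigment depth 0).

    Pixel accuracy is tallied *per class* so the caller can form the
    class-balanced accuracy: with no class signal the classifier's
    prediction bias, multiplied by whatever pixel-count imbalance random
    insect sizes produce, would otherwise masquerade as miscalibration.
    Image accuracy is tallied directly (test images are balanced by
    construction). Returns correct/total counts for both levels.
    """
    from .classification import LabelledPixels, fit_svc_grouped
    from .spectral_features import make_scheme, resample_wavebands

    pixel_correct = {0: 0, 1: 0}
    pixel_total = {0: 0, 1: 0}
    image_correct = image_total = 0
    for seed in seeds:
        scenes = generate_scenes(config, n_scenes_per_class, seed=int(seed))
        split = grouped_split(
            [c.image_id for c, _ in scenes],
            [t.species for _, t in scenes],
            fraction=0.5,
            seed=int(seed),
        )
        table, labels = extract_body_pixels(scenes, window=window, median_kernel=median_kernel)
        resampled = resample_wavebands(table, make_scheme(window, n_bands))
        labels_row = np.asarray([labels[i] for i in table.image_ids.tolist()], dtype=object)
        pixels = LabelledPixels(
            features=resampled.spectra, labels=labels_row, image_ids=table.image_ids
        )
        model = fit_svc_grouped(pixels, split, seed=int(seed), max_train_pixels=max_train_pixels)
        from .classification import classify_image_median, predict_pixel_probs

        in_test = np.isin(table.image_ids, split.test_image_ids)
        probs = predict_pixel_probs(model, resampled.spectra[in_test])
        truth_pos = (labels_row[in_test] == model.positive_class()).astype(int)
        pred_pos = (probs > 0.5).astype(int)
        for cls in (0, 1):
            sel = truth_pos == cls
            pixel_correct[cls] += int((pred_pos[sel] == cls).sum())
            pixel_total[cls] += int(sel.sum())
        test_ids = table.image_ids[in_test]
        for image_id in split.test_image_ids:
            res = classify_image_median(probs[test_ids == image_id], str(image_id))
            truth = int(labels[image_id] == model.positive_class())
            image_correct += int(res.decision == truth)
            image_total += 1
    balanced = 0.5 * (
        pixel_correct[0] / max(pixel_total[0], 1) + pixel_correct[1] / max(pixel_total[1], 1)
    )
    return {
        "pixel_correct": pixel_correct,
        "pixel_total": pixel_total,
        "balanced_pixel_accuracy": balanced,
        "image_correct": image_correct,
        "image_total": image_total,
        "image_accuracy": image_correct / max(image_total, 1),
    }


def run_leaf_trial(
    config: SceneConfig,
    n_scenes_per_class: int,
    seed: int,
    n_train_per_class: int = 20,
    n_latent: int = 5,
    mask_params: MaskParams | None = None,
) -> dict:
    """Benchtop leaf-scene trial: mask insects, classify insects with PLS-DA.

    Each insect's sample is the mean spectrum of its masked pixels (true
    insect footprint intersected with the OSAVI mask). Returns the holdout
    accuracy over insects not drawn into the training set.
    """
    if config.background != "leaf":
        raise ValueError("leaf trial requires a leaf-background scene config")
    mask_params = mask_params or MaskParams()
    scenes = generate_scenes(config, n_scenes_per_class, seed=seed)
    samples, labels, ids = [], [], []
    for cube, truth in scenes:
        mask = mask_insects(cube, mask_params)
        for rec in truth.registry:
            member = (truth.insect_map == rec["insect_id"]) & mask
            if member.sum() < 3:
                continue  # insect lost by masking; excluded from sampling
            samples.append(cube.data[member].mean(axis=0))
            labels.append(rec["species"])
            ids.append(f"{cube.image_id}:insect{rec['insect_id']}")
    pixels = LabelledPixels(
        features=np.asarray(samples), labels=np.asarray(labels, dtype=object),
        image_ids=np.asarray(ids, dtype=object),
    )
    model = fit_plsda(
        pixels, n_latent=n_latent, n_train_per_class=n_train_per_class, seed=seed
    )
    holdout = ~np.isin(pixels.image_ids, model.split_train_ids)
    pred = predict_labels(model, pixels.features[holdout])
    accuracy = float(np.mean(pred == pixels.labels[holdout]))
    return {
        "model": model,
        "accuracy": accuracy,
        "n_holdout": int(holdout.sum()),
        "n_insects": len(samples),
    }
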