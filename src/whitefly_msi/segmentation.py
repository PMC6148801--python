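"""Semi-supervised anatomical segmentation of insect image cubes.

Every pixel spectrum is an observation (no spatial features). Pixels are
robust-scaled per band (median centre, IQR scale), reduced to 3 principal
components with incremental PCA, and clustered with K-means into exactly
three groups which, on whitefly scenes, correspond to insect body, insect
wing and background. The fitted scaler statistics, PCA basis and the three
cluster centroids are persisted as a :class:`SegmentationModel` so new
images can be labelled by nearest-centroid assignment without refitting or
manual annotation — only the one-off centroid -> anatomy mapping requires
inspection (or ground truth, for synthetic scenes).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import IncrementalPCA

from .cube_io import SpectralCube

logger = logging.getLogger(__name__)

__all__ = [
    "ANATOMY_BACKGROUND",
    "ANATOMY_BODY",
    "ANATOMY_WING",
    "ANATOMY_UNASSIGNED",
    "ANATOMY_NAMES",
    "PixelSpectraTable",
    "ScalerStats",
    "PCABasis",
    "SegmentationModel",
    "cube_to_table",
    "robust_center_spectra",
    "apply_scaler",
    "fit_incremental_pca",
    "project_pca",
    "fit_kmeans3",
    "assign_clusters_from_centroids",
    "map_clusters_to_anatomy",
    "fit_segmentation_model",
    "segment_cube",
]

# Integer anatomy codes used in label maps and synthetic ground truth.
ANATOMY_BACKGROUND = 0
ANATOMY_BODY = 1
ANATOMY_WING = 2
ANATOMY_UNASSIGNED = -1
ANATOMY_NAMES = {
    ANATOMY_BACKGROUND: "background",
    ANATOMY_BODY: "body",
    ANATOMY_WING: "wing",
    ANATOMY_UNASSIGNED: "unassigned",
}
_NAME_TO_CODE = {v: k for k, v in ANATOMY_NAMES.items()}


@dataclass
class PixelSpectraTable:
    """Per-pixel spectra pooled across one or more cubes.

    ``spectra`` is N x B; ``coords`` holds the (row, col) of each pixel in
    its source cube and ``image_ids`` which cube that was, so labels can be
    written back to image grids.
    """

    spectra: np.ndarray
    coords: np.ndarray
    image_ids: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.coords = np.asarray(self.coords)
        self.image_ids = np.asarray(self.image_ids)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n, b = self.spectra.shape
        if len(self.coords) != n or len(self.image_ids) != n:
            raise ValueError("coords/image_ids length must match spectrum count")
        if len(self.wavelengths) != b:
            raise ValueError("wavelength axis must match band count")
        if np.any(~np.isfinite(self.spectra)):
            raise ValueError("pixel spectra contain non-finite values")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def replace_spectra(self, spectra: np.ndarray, wavelengths=None) -> "PixelSpectraTable":
        return PixelSpectraTable(
            spectra=spectra,
            coords=self.coords,
            image_ids=self.image_ids,
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
        )


def cube_to_table(cube: SpectralCube, mask: np.ndarray | None = None) -> PixelSpectraTable:
    """Flatten a cube's pixels (optionally only those where ``mask``) to a table."""
    if mask is None:
        mask = np.ones(cube.data.shape[:2], dtype=bool)
    rows, cols = np.nonzero(mask)
    return PixelSpectraTable(
        spectra=cube.data[rows, cols, :],
        coords=np.stack([rows, cols], axis=1),
        image_ids=np.array([cube.image_id] * len(rows), dtype=object),
        wavelengths=cube.wavelengths,
    )


def concat_tables(tables: list[PixelSpectraTable]) -> PixelSpectraTable:
    """Stack tables that share a wavelength axis."""
    wl = tables[0].wavelengths
    for t in tables[1:]:
        if not np.allclose(t.wavelengths, wl):
            raise ValueError("cannot pool tables with differing wavelength axes")
    return PixelSpectraTable(
        spectra=np.concatenate([t.spectra for t in tables]),
        coords=np.concatenate([t.coords for t in tables]),
        image_ids=np.concatenate([t.image_ids for t in tables]),
        wavelengths=wl,
    )


@dataclass
class ScalerStats:
    """Per-band robust centre (median) and scale (IQR)."""

    center: np.ndarray
    scale: np.ndarray


@dataclass
class PCABasis:
    mean: np.ndarray
    components: np.ndarray  # (n_components, B)
    explained_variance_ratio: np.ndarray


def robust_center_spectra(
    table: PixelSpectraTable, with_scaling: bool = True
) -> tuple[PixelSpectraTable, ScalerStats]:
    """Centre each band by its median and (optionally) scale by its IQR.

    Quartiles use linear interpolation (the standard quantile rule). A band
    with zero IQR gets scale 1 so constant bands centre to zero instead of
    dividing by zero; this is logged, not fatal.
    """
    if table.n_pixels < 2:
        raise ValueError("robust scaling needs at least 2 pixels")
    center = np.median(table.spectra, axis=0)
    if with_scaling:
        q25, q75 = np.percentile(table.spectra, [25.0, 75.0], axis=0)
        scale = q75 - q25
        degenerate = scale == 0
        if np.any(degenerate):
            logger.warning(
                "robust scaler: %d band(s) have zero IQR; scale set to 1",
                int(degenerate.sum()),
            )
            scale = np.where(degenerate, 1.0, scale)
    else:
        scale = np.ones_like(center)
    stats = ScalerStats(center=center, scale=scale)
    return apply_scaler(table, stats), stats


def apply_scaler(table: PixelSpectraTable, stats: ScalerStats) -> PixelSpectraTable:
    """Apply stored robust-scaler statistics (e.g. to a new image's pixels)."""
    if len(stats.center) != table.n_bands:
        raise ValueError("scaler statistics do not match the table's band count")
    return table.replace_spectra((table.spectra - stats.center) / stats.scale)


def fit_incremental_pca(
    table: PixelSpectraTable, n_components: int = 3, batch_size: int = 4096
) -> PCABasis:
    """Fit PCA in mini-batches so arbitrarily many pixels can be decomposed.

    With a single batch this coincides (to numerical precision) with a
    full-batch eigendecomposition; across batches the incremental SVD update
    is a close approximation.
    """
    if table.n_pixels <= n_components:
        raise ValueError("need more pixels than components")
    if batch_size < n_components:
        raise ValueError("batch_size must be >= n_components")
    ipca = IncrementalPCA(n_components=n_components, batch_size=batch_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on final short batches
        ipca.fit(table.spectra)
    return PCABasis(
        mean=ipca.mean_.copy(),
        components=ipca.components_.copy(),
        explained_variance_ratio=ipca.explained_variance_ratio_.copy(),
    )


def project_pca(table_or_matrix, basis: PCABasis) -> np.ndarray:
    """Scores = (spectra - mean) @ components.T."""
    x = (
        table_or_matrix.spectra
        if isinstance(table_or_matrix, PixelSpectraTable)
        else np.asarray(table_or_matrix, dtype=float)
    )
    if x.shape[1] != basis.components.shape[1]:
        raise ValueError(
            f"band count {x.shape[1]} does not match PCA basis "
            f"({basis.components.shape[1]} bands)"
        )
    return (x - basis.mean) @ basis.components.T


def fit_kmeans3(
    scores: np.ndarray, seed: int, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """K-means with k = 3 on PC scores; best of ``n_restarts`` by WCSS.

    Deterministic given ``seed``. Returns ``(centroids (3, d), assignments (N,))``.
    """
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores, axis=0)) < 3:
        raise ValueError("K-means with k=3 needs at least 3 distinct points")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=int(seed))
    assignments = km.fit_predict(scores)
    return km.cluster_centers_.copy(), assignments


@dataclass
class SegmentationModel:
    """Persisted segmentation state: scaler + PCA basis + labelled centroids.

    ``anatomy`` maps centroid index -> anatomy code (a bijection onto
    {background, body, wing}); it may be absent on a freshly clustered model
    until :func:`map_clusters_to_anatomy` fills it in.
    """

    scaler: ScalerStats
    basis: PCABasis
    centroids: np.ndarray
    anatomy: dict[int, int] | None = None
    with_scaling: bool = True

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != 3:
            raise ValueError("segmentation model must hold exactly 3 centroids")
        evr = self.basis.explained_variance_ratio
        if np.any(evr < 0) or np.any(evr > 1) or np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance ratios must be non-increasing in [0, 1]")
        if self.anatomy is not None:
            vals = sorted(self.anatomy.values())
            if sorted(self.anatomy.keys()) != [0, 1, 2] or vals != [
                ANATOMY_BACKGROUND,
                ANATOMY_BODY,
                ANATOMY_WING,
            ]:
                raise ValueError("anatomy must be a bijection of centroids onto the 3 classes")

    def save(self, path: str) -> None:
        payload = {
            "scaler_center": self.scaler.center.tolist(),
            "scaler_scale": self.scaler.scale.tolist(),
            "pca_mean": self.basis.mean.tolist(),
            "pca_components": self.basis.components.tolist(),
            "explained_variance_ratio": self.basis.explained_variance_ratio.tolist(),
            "centroids": self.centroids.tolist(),
            "anatomy": {str(k): v for k, v in (self.anatomy or {}).items()} or None,
            "with_scaling": self.with_scaling,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "SegmentationModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            scaler=ScalerStats(
                center=np.array(p["scaler_center"]), scale=np.array(p["scaler_scale"])
            ),
            basis=PCABasis(
                mean=np.array(p["pca_mean"]),
                components=np.array(p["pca_components"]),
                explained_variance_ratio=np.array(p["explained_variance_ratio"]),
            ),
            centroids=np.array(p["centroids"]),
            anatomy={int(k): int(v) for k, v in p["anatomy"].items()}
            if p.get("anatomy")
            else None,
            with_scaling=bool(p.get("with_scaling", True)),
        )


def assign_clusters_from_centroids(
    scores: np.ndarray, model: SegmentationModel
) -> np.ndarray:
    """Nearest-centroid (Euclidean) cluster index per score row.

    Ties resolve to the lowest centroid index (``argmin`` semantics).
    """
    scores = np.asarray(scores, dtype=float)
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def map_clusters_to_anatomy(
    model: SegmentationModel,
    cluster_assignments: np.ndarray | None = None,
    truth_anatomy: np.ndarray | None = None,
    manual: dict[int, int | str] | None = None,
) -> SegmentationModel:
    """Attach the centroid -> anatomy mapping to a clustered model.

    Either supply ``manual`` (centroid index -> anatomy code or name, the
    analogue of inspecting colour-coded cluster images), or supply
    ``cluster_assignments`` together with per-pixel ``truth_anatomy`` codes
    and let each centroid take the majority true anatomy of its pixels. The
    majority vote must produce a bijection; a degenerate scene (e.g. only
    background present) is an error directing the user to the manual path.
    """
    if manual is not None:
        mapping = {
            int(k): (_NAME_TO_CODE[v] if isinstance(v, str) else int(v))
            for k, v in manual.items()
        }
    else:
        if cluster_assignments is None or truth_anatomy is None:
            raise ValueError("need either a manual mapping or assignments + truth")
        cluster_assignments = np.asarray(cluster_assignments)
        truth_anatomy = np.asarray(truth_anatomy)
        mapping = {}
        for k in range(3):
            members = truth_anatomy[cluster_assignments == k]
            if len(members) == 0:
                raise ValueError(
                    f"cluster {k} received no pixels; cannot vote — supply a manual mapping"
                )
            codes, counts = np.unique(members, return_counts=True)
            mapping[k] = int(codes[np.argmax(counts)])
    if sorted(mapping.values()) != [ANATOMY_BACKGROUND, ANATOMY_BODY, ANATOMY_WING]:
        raise ValueError(
            "anatomy mapping is not a bijection onto {background, body, wing}; "
            "supply a manual mapping"
        )
    return SegmentationModel(
        scaler=model.scaler,
        basis=model.basis,
        centroids=model.centroids,
        anatomy=mapping,
        with_scaling=model.with_scaling,
    )


def fit_segmentation_model(
    table: PixelSpectraTable,
    seed: int,
    with_scaling: bool = True,
    batch_size: int = 4096,
) -> tuple[SegmentationModel, np.ndarray]:
    """Scale -> iPCA(3) -> K-means(3) on pooled pixels.

    Returns the (anatomy-less) model and the training cluster assignments,
    ready for :func:`map_clusters_to_anatomy`.
    """
    scaled, stats = robust_center_spectra(table, with_scaling=with_scaling)
    basis = fit_incremental_pca(scaled, n_components=3, batch_size=batch_size)
    scores = project_pca(scaled, basis)
    centroids, assignments = fit_kmeans3(scores, seed=seed)
    model = SegmentationModel(
        scaler=stats, basis=basis, centroids=centroids, with_scaling=with_scaling
    )
    return model, assignments


def segment_cube(cube: SpectralCube, model: SegmentationModel) -> np.ndarray:
    """Label every pixel of ``cube`` with an anatomy code using a stored model.

    Returns a rows x cols int8 label map with values in
    {background, body, wing} codes (anatomy must be attached to the model).
    """
    if model.anatomy is None:
        raise ValueError("model has no anatomy mapping; run map_clusters_to_anatomy first")
    table = cube_to_table(cube)
    scores = project_pca(apply_scaler(table, model.scaler), model.basis)
    clusters = assign_clusters_from_centroids(scores, model)
    lut = np.array([model.anatomy[k] for k in range(3)], dtype=np.int8)
    labels = np.full(cube.data.shape[:2], ANATOMY_UNASSIGNED, dtype=np.int8)
    labels[table.coords[:, 0], table.coords[:, 1]] = lut[clusters]
    return labels
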