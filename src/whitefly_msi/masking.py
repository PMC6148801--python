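"""Leaf-background removal for insects imaged in situ on leaves.

Vegetation is suppressed with the Optimised Soil-Adjusted Vegetation Index
(OSAVI), a red/NIR reflectance ratio with an additive soil-adjustment
constant ``r`` in the denominator that damps the influence of light
reflected onto the leaf from non-plant surfaces::

    OSAVI = (1 + r) * (NIR - RED) / (NIR + RED + r),   r = 0.16

Green leaf tissue scores high (strong red edge), insect cuticle and neutral
backgrounds score near zero, so thresholding OSAVI *below* a cut retains
candidate insect pixels. Small retained components (speckles), which are
predominantly specular-reflectance artefacts, are then removed by
connected-component size filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects

from .cube_io import SpectralCube

__all__ = [
    "MaskParams",
    "compute_osavi",
    "apply_mask_threshold",
    "remove_speckles",
    "mask_insects",
]


@dataclass
class MaskParams:
    """Parameters of OSAVI masking and speckle exclusion.

    ``r`` is the unitless soil-adjustment constant; ``red_wl``/``nir_wl``
    are the index wavelengths in nm (nearest band within 25 nm is used);
    ``osavi_threshold`` separates vegetation (above) from candidate insect
    pixels (below); components smaller than ``min_object_px`` are discarded.
    """

    r: float = 0.16
    red_wl: float = 670.0
    nir_wl: float = 800.0
    osavi_threshold: float = 0.4
    min_object_px: int = 10
    band_tol_nm: float = 25.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("soil-adjustment parameter r must be positive")
        if self.red_wl >= self.nir_wl:
            raise ValueError("red_wl must be below nir_wl")
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")


def compute_osavi(cube: SpectralCube, params: MaskParams | None = None) -> np.ndarray:
    """Per-pixel OSAVI map for ``cube``.

    RED and NIR are taken from the bands nearest ``params.red_wl`` and
    ``params.nir_wl``; a requested wavelength farther than the tolerance from
    any band is an error. Values lie in ``[-(1+r), 1+r]`` and the additive
    ``r`` keeps dark pixels (RED = NIR = 0) finite at 0.
    """
    params = params or MaskParams()
    red = cube.data[:, :, cube.band_index(params.red_wl, params.band_tol_nm)]
    nir = cube.data[:, :, cube.band_index(params.nir_wl, params.band_tol_nm)]
    return (1.0 + params.r) * (nir - red) / (nir + red + params.r)


def apply_mask_threshold(
    index_map: np.ndarray, params: MaskParams | None = None
) -> np.ndarray:
    """Boolean mask retaining (True) pixels with OSAVI below the threshold.

    High-OSAVI (leaf) pixels are removed; neutral/insect pixels survive.
    """
    params = params or MaskParams()
    if not np.isfinite(params.osavi_threshold):
        raise ValueError("osavi_threshold must be finite")
    return np.asarray(index_map) < params.osavi_threshold


def remove_speckles(mask: np.ndarray, params: MaskParams | None = None) -> np.ndarray:
    """Drop 8-connected True components smaller than ``min_object_px``.

    8-connectivity keeps diagonal insect appendages attached to the body.
    Idempotent; components at or above the size cut are untouched.
    """
    params = params or MaskParams()
    mask = np.asarray(mask, dtype=bool)
    if params.min_object_px == 1:
        return mask.copy()
    # max_size removes components of size <= threshold, i.e. strictly below
    # min_object_px with the -1; components at the cut survive.
    return remove_small_objects(mask, connectivity=2, max_size=params.min_object_px - 1)


def mask_insects(cube: SpectralCube, params: MaskParams | None = None) -> np.ndarray:
    """OSAVI threshold then speckle exclusion: the full leaf-scene mask."""
    params = params or MaskParams()
    return remove_speckles(apply_mask_threshold(compute_osavi(cube, params), params), params)
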