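"""Spectral feature reduction: band trimming, median filtering, waveband resampling.

The full hyperspectral axis is first trimmed to the low-noise window
(default 420-900 nm; detector noise is inflated below 420 nm and above
900 nm). Pixel spectra are then median filtered along wavelength and
averaged into ``n`` equal-width wavebands — a flat-top simulation of the
information a low-cost LED/filter multispectral sensor would record. The
studied range is 4-60 wavebands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .cube_io import SpectralCube
from .segmentation import PixelSpectraTable

__all__ = [
    "BandWindow",
    "WavebandScheme",
    "DEFAULT_WINDOW",
    "trim_bands",
    "median_filter_spectra",
    "make_scheme",
    "resample_wavebands",
]


@dataclass(frozen=True)
class BandWindow:
    """An inclusive wavelength window [min_wl, max_wl] in nm."""

    min_wl: float
    max_wl: float

    def __post_init__(self) -> None:
        if not self.min_wl < self.max_wl:
            raise ValueError("window requires min_wl < max_wl")


DEFAULT_WINDOW = BandWindow(420.0, 900.0)


@dataclass(frozen=True)
class WavebandScheme:
    """``n`` contiguous equal-width wavebands given by ``n + 1`` edges (nm)."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        widths = np.diff(e)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-9):
            raise ValueError("wavebands must have equal widths")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    @property
    def centres(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges))

    def to_table(self) -> "np.ndarray":
        """(index, lower_nm, upper_nm, centre_nm) rows, for serialisation."""
        e = np.asarray(self.edges)
        return np.column_stack(
            [np.arange(self.n_bands), e[:-1], e[1:], self.centres]
        )


def make_scheme(
    window: BandWindow, n_bands: int, allow_out_of_range: bool = False
) -> WavebandScheme:
    """Equal-width contiguous waveband scheme over ``window``.

    ``n_bands`` outside the studied range [4, 60] is refused unless
    ``allow_out_of_range`` — e.g. window 400-1100 nm with 20 bands gives the
    35 nm bandwidth proposed for a fieldable sensor.
    """
    if not allow_out_of_range and not 4 <= n_bands <= 60:
        raise ValueError(
            f"n_bands = {n_bands} outside the studied range [4, 60]; "
            "pass allow_out_of_range=True to override"
        )
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    return WavebandScheme(
        edges=tuple(np.linspace(window.min_wl, window.max_wl, n_bands + 1))
    )


def _trim_indices(wavelengths: np.ndarray, window: BandWindow) -> np.ndarray:
    keep = (wavelengths >= window.min_wl) & (wavelengths <= window.max_wl)
    if not np.any(keep):
        raise ValueError(
            f"window [{window.min_wl}, {window.max_wl}] nm retains no bands of an "
            f"axis spanning {wavelengths[0]}-{wavelengths[-1]} nm"
        )
    return keep


def trim_bands(obj, window: BandWindow = DEFAULT_WINDOW):
    """Keep only bands with wavelength inside ``window`` (endpoints inclusive).

    Accepts a :class:`SpectralCube` or :class:`PixelSpectraTable` and returns
    the same kind with a consistently reduced wavelength axis.
    """
    if isinstance(obj, SpectralCube):
        keep = _trim_indices(obj.wavelengths, window)
        return SpectralCube(
            data=obj.data[:, :, keep],
            wavelengths=obj.wavelengths[keep],
            image_id=obj.image_id,
            pixel_size_um=obj.pixel_size_um,
        )
    if isinstance(obj, PixelSpectraTable):
        keep = _trim_indices(obj.wavelengths, window)
        return obj.replace_spectra(obj.spectra[:, keep], wavelengths=obj.wavelengths[keep])
    raise TypeError(f"cannot trim object of type {type(obj).__name__}")


def median_filter_spectra(table: PixelSpectraTable, kernel: int = 5) -> PixelSpectraTable:
    """Running median of width ``kernel`` along each pixel spectrum.

    Edges use replicate (zero-order) padding. ``kernel`` must be odd and no
    larger than the band count; kernel 1 is the identity.
    """
    if kernel % 2 == 0:
        raise ValueError("median-filter kernel must be odd")
    if not 1 <= kernel <= table.n_bands:
        raise ValueError("kernel must be in [1, n_bands]")
    if kernel == 1:
        return table.replace_spectra(table.spectra.copy())
    smoothed = median_filter(table.spectra, size=(1, kernel), mode="nearest")
    return table.replace_spectra(smoothed)


def resample_wavebands(
    table: PixelSpectraTable, scheme: WavebandScheme
) -> PixelSpectraTable:
    """Average source bands into the scheme's wavebands (flat-top sensor model).

    A source band belongs to waveband ``i`` when its centre lies in
    ``[edge_i, edge_{i+1})``; the final waveband is right-closed so the top
    edge is not dropped. Every waveband must contain at least one source band.
    The output wavelength axis is the waveband centres.
    """
    edges = np.asarray(scheme.edges)
    wl = table.wavelengths
    out = np.empty((table.n_pixels, scheme.n_bands), dtype=float)
    for i in range(scheme.n_bands):
        lo, hi = edges[i], edges[i + 1]
        if i == scheme.n_bands - 1:
            sel = (wl >= lo) & (wl <= hi)
        else:
            sel = (wl >= lo) & (wl < hi)
        if not np.any(sel):
            raise ValueError(
                f"waveband {i} ([{lo}, {hi}] nm) contains no source bands"
            )
        out[:, i] = table.spectra[:, sel].mean(axis=1)
    return table.replace_spectra(out, wavelengths=scheme.centres)
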