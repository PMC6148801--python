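"""ENVI-style spectral cube I/O and reflectance calibration.

Spectral image cubes are exchanged as flat binary files with an associated
plain-text header (the de-facto ENVI dialect written by line-scanning
spectral imagers): ``samples``/``lines``/``bands`` dimensions, an interleave
keyword (BIL, BIP or BSQ), a numeric data-type code and a wavelength list.
Raw detector counts are converted to reflectance against white (and
optionally dark) reference frames recorded from a barium-sulphate tile.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralCube",
    "CalibrationRefs",
    "CutOut",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
]

# ENVI numeric data-type codes -> numpy dtypes (little-endian assumed for
# byte order 0, the only order we write).
_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
    14: np.dtype("<i8"),
    15: np.dtype("<u8"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class SpectralCube:
    """A reflectance image cube: ``data[row, col, band]`` with a wavelength axis.

    Parameters
    ----------
    data
        3-D float array, rows x cols x bands. Reflectance is unitless,
        nominally in [0, ~1.2]; values above 1 are legitimate specular
        overshoot and are preserved.
    wavelengths
        Band centres in nm, strictly increasing, one per band.
    image_id
        Opaque identifier (typically the source filename stem).
    pixel_size_um
        Physical pixel pitch in micrometres (60 for the reference imager).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    image_id: str = ""
    pixel_size_um: float = 60.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        rows, cols, bands = self.data.shape
        if rows < 1 or cols < 1:
            raise ValueError("cube must have at least one row and one column")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != bands:
            raise ValueError(
                f"wavelength list length {len(self.wavelengths)} does not match "
                f"band count {bands}"
            )
        if bands > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float, tol_nm: float = 25.0) -> int:
        """Index of the band nearest ``wavelength_nm`` within ``tol_nm``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        if abs(self.wavelengths[i] - wavelength_nm) > tol_nm:
            raise ValueError(
                f"no band within {tol_nm} nm of {wavelength_nm} nm "
                f"(axis spans {self.wavelengths[0]}-{self.wavelengths[-1]} nm)"
            )
        return i


@dataclass
class CutOut:
    """A labelled sub-image cropped from a master frame.

    The class label is encoded in the source filename; ``source_offset`` is
    the (row, col) of the cut-out's origin in the master frame.
    """

    cube: SpectralCube
    label: str
    source_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("cut-out label must be non-empty")


@dataclass
class CalibrationRefs:
    """White/dark reference intensities for reflectance calibration.

    ``white`` and ``dark`` are either per-band vectors of shape ``(bands,)``
    or per-column arrays of shape ``(cols, bands)`` (line-scanner geometry,
    where each cross-track column has its own illumination profile).
    ``dark`` defaults to zero: whether a dark frame was subtracted upstream
    is instrument-dependent.
    """

    white: np.ndarray
    dark: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        if self.dark is None:
            self.dark = np.zeros_like(self.white)
        else:
            self.dark = np.asarray(self.dark, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("white and dark references must have identical shape")
        if np.any(self.white <= self.dark):
            raise ValueError("degenerate calibration: white <= dark in some band")


def _data_path_for_header(header_path: str) -> str:
    stem = re.sub(r"\.hdr$", "", header_path, flags=re.IGNORECASE)
    for cand in (stem + ".img", stem + ".bin", stem + ".dat", stem):
        if os.path.isfile(cand):
            return cand
    raise FileNotFoundError(f"no binary payload found next to header {header_path!r}")


def _parse_header(text: str) -> dict[str, str]:
    """Parse ENVI ``key = value`` pairs; brace-delimited values may span lines."""
    fields: dict[str, str] = {}
    # Collapse brace groups onto one line first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(header_path: str) -> SpectralCube:
    """Read an ENVI header + flat binary pair into a :class:`SpectralCube`.

    Bands are reordered so the wavelength axis is strictly increasing
    regardless of the order stored on disk. Headers giving wavelength units
    as micrometres are converted to nm.
    """
    with open(header_path, "r") as fh:
        fields = _parse_header(fh.read())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = _ENVI_DTYPES[code]
    offset = int(fields.get("header offset", "0"))

    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list; cannot build spectral axis")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise ValueError("malformed wavelength list (expected brace-delimited values)")
    wavelengths = np.array(
        [float(tok) for tok in wl_text[1:-1].replace(",", " ").split()], dtype=float
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"wavelength list has {len(wavelengths)} entries for {bands} bands"
        )
    units = fields.get("wavelength units", "nanometers").lower()
    if units.startswith("micro") or units in ("um", "µm"):
        wavelengths = wavelengths * 1000.0

    data_path = _data_path_for_header(header_path)
    expected = rows * cols * bands * dtype.itemsize + offset
    actual = os.path.getsize(data_path)
    if actual != expected:
        raise ValueError(
            f"binary payload {data_path!r} is {actual} bytes but header declares "
            f"{rows}x{cols}x{bands} {dtype.name} = {expected} bytes"
        )

    flat = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(rows, cols, bands)

    order = np.argsort(wavelengths, kind="stable")
    if not np.array_equal(order, np.arange(bands)):
        wavelengths = wavelengths[order]
        data = data[:, :, order]

    image_id = os.path.splitext(os.path.basename(header_path))[0]
    return SpectralCube(
        data=np.ascontiguousarray(data), wavelengths=wavelengths, image_id=image_id
    )


def write_envi(
    cube: SpectralCube, header_path: str, interleave: str = "bsq"
) -> None:
    """Write ``cube`` as an ENVI header (``.hdr``) + flat binary (``.img``) pair.

    The payload keeps the cube's float width (float32 or float64), so a
    write -> read round trip is bit-exact.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    cube.validate()
    data = cube.data
    if data.dtype not in (np.dtype("<f4"), np.dtype("<f8")):
        data = data.astype("<f8")
    code = _DTYPE_CODES[np.dtype(data.dtype.str.replace(">", "<"))]

    stem = re.sub(r"\.hdr$", "", header_path, flags=re.IGNORECASE)
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{whitefly-msi spectral cube: {cube.image_id}}}\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size um = {cube.pixel_size_um}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(stem + ".hdr", "w") as fh:
        fh.write(header)

    if interleave == "bsq":
        payload = data.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = data.transpose(0, 2, 1)
    else:
        payload = data
    np.ascontiguousarray(payload).tofile(stem + ".img")


def calibrate_reflectance(raw: SpectralCube, refs: CalibrationRefs) -> SpectralCube:
    """Convert raw counts to reflectance: ``(raw - dark) / (white - dark)``.

    References may be per band (``(bands,)``) or per column (``(cols, bands)``,
    line-scanner geometry). Negative results are clipped to 0; values above 1
    (specular highlights) are preserved for the downstream despeckler.
    """
    white, dark = refs.white, refs.dark
    if white.shape == (raw.n_bands,):
        white_b = white[None, None, :]
        dark_b = dark[None, None, :]
    elif white.shape == (raw.cols, raw.n_bands):
        white_b = white[None, :, :]
        dark_b = dark[None, :, :]
    else:
        raise ValueError(
            f"reference shape {white.shape} matches neither (bands,) = "
            f"({raw.n_bands},) nor (cols, bands) = ({raw.cols}, {raw.n_bands})"
        )
    refl = (raw.data.astype(float) - dark_b) / (white_b - dark_b)
    np.clip(refl, 0.0, None, out=refl)
    if np.any(~np.isfinite(refl)):
        raise ValueError("calibration produced non-finite reflectance")
    return SpectralCube(
        data=refl,
        wavelengths=raw.wavelengths.copy(),
        image_id=raw.image_id,
        pixel_size_um=raw.pixel_size_um,
    )
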