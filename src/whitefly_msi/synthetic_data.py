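"""Synthetic labelled hyperspectral scenes of whiteflies with ground truth.

Scenes emulate the statistical structure the analysis pipeline assumes,
without claiming any real insect's numbers:

* a spectrally flat grey-card background (benchtop petri-dish trials) or a
  leaf background with a red-edge profile (in-situ trials), optionally
  carrying saturated specular speckles;
* insects rendered as an elliptical body with two semi-transparent wing
  lobes (wing spectrum = alpha * background + (1 - alpha) * a bright flat
  membrane term);
* a species-specific pigment feature: the viral-vector-like class carries a
  configurable reflectance offset ``pigment_depth`` over a configurable
  wavelength window on top of the shared cuticle template;
* heteroscedastic Gaussian band noise, inflated below 420 nm and above
  900 nm where the reference detector was noisy;
* per-insect template jitter (a small random reflectance offset) standing
  in for within-species biological variation.

Every scene comes with exact per-pixel anatomy truth, a per-insect
registry, and is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import binary_dilation
from scipy.stats import norm

from .cube_io import SpectralCube, write_envi
from .segmentation import (
    ANATOMY_BACKGROUND,
    ANATOMY_BODY,
    ANATOMY_WING,
)
from .spectral_features import WavebandScheme

__all__ = [
    "SpectralTemplate",
    "SceneConfig",
    "SceneTruth",
    "make_template_spectra",
    "render_scene",
    "generate_scenes",
    "generate_dataset",
    "parse_label_from_filename",
    "bayes_pixel_accuracy",
]


@dataclass(frozen=True)
class SpectralTemplate:
    """A smooth reflectance spectrum through (wavelength nm, reflectance) knots.

    Interpolation is shape-preserving (monotone-segment cubic), so the curve
    stays within the knot range on every segment.
    """

    name: str
    control_points: tuple

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("template needs at least 2 control points")
        if np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > 1.2):
            raise ValueError(f"template {self.name!r}: reflectance outside [0, 1.2]")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("control-point wavelengths must be strictly increasing")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        pts = np.asarray(self.control_points, dtype=float)
        if len(pts) == 2 and pts[0, 1] == pts[1, 1]:
            return np.full(len(wavelengths), pts[0, 1])
        return PchipInterpolator(pts[:, 0], pts[:, 1])(np.asarray(wavelengths, dtype=float))


GREYCARD = SpectralTemplate("greycard", ((380.0, 0.4), (1000.0, 0.4)))
LEAF = SpectralTemplate(
    "leaf",
    (
        (380.0, 0.05),
        (500.0, 0.08),
        (550.0, 0.12),
        (620.0, 0.08),
        (670.0, 0.05),
        (700.0, 0.25),
        (750.0, 0.50),
        (850.0, 0.50),
        (900.0, 0.50),
        (1000.0, 0.45),
    ),
)
BODY_BASE = SpectralTemplate(
    "body-base",
    (
        (380.0, 0.08),
        (450.0, 0.12),
        (550.0, 0.25),
        (650.0, 0.32),
        (750.0, 0.36),
        (900.0, 0.39),
        (1000.0, 0.40),
    ),
)
WING_MEMBRANE_REFLECTANCE = 0.8


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one rendered scene family.

    The spectral axis spans 380-1000 nm; ``wl_step`` defaults to 2 nm (the
    reference instrument sampled at 0.74 nm — set ``wl_step`` accordingly
    for full-resolution scenes). The first species in ``species`` is the
    vector-like class carrying the pigment offset.
    """

    shape: tuple[int, int] = (64, 64)
    wl_start: float = 380.0
    wl_stop: float = 1000.0
    wl_step: float = 2.0
    background: str = "greycard"  # or "leaf"
    species: tuple[str, ...] = ("SSA1", "Other")
    pigment_window: tuple[float, float] = (540.0, 620.0)
    pigment_depth: float = 0.08
    wing_alpha: float = 0.5
    insects_per_scene: int = 1
    body_px_range: tuple[int, int] = (150, 450)
    template_jitter_sd: float = 0.0
    noise_sigma: float = 0.01
    noise_edge_factor: float = 5.0
    noise_edge_low: float = 420.0
    noise_edge_high: float = 900.0
    speckle_count: int = 0
    speckle_amplitude: float = 1.15
    speckle_max_px: int = 4
    max_placement_tries: int = 500
    pixel_size_um: float = 60.0

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop + 1e-9, self.wl_step)

    def noise_sigma_per_band(self) -> np.ndarray:
        wl = self.wavelengths
        edge = (wl < self.noise_edge_low) | (wl > self.noise_edge_high)
        return self.noise_sigma * np.where(edge, self.noise_edge_factor, 1.0)


def leaf_scene_config(**overrides) -> SceneConfig:
    """Default in-situ (leaf background) scene family: red-edge background
    plus a few saturated specular speckles for the despeckler to remove."""
    base = dict(background="leaf", speckle_count=3)
    base.update(overrides)
    return replace(SceneConfig(), **base)


@dataclass
class SceneTruth:
    """Exact per-pixel ground truth for a rendered scene."""

    anatomy: np.ndarray  # int8 anatomy codes, rows x cols
    insect_map: np.ndarray  # int16 insect id (0 = none), rows x cols
    registry: list  # per insect: dict(insect_id, species, centroid, body_px)
    species: str  # the scene's (cut-out's) class label


def make_template_spectra(config: SceneConfig) -> dict[str, np.ndarray]:
    """Evaluate all scene templates on the config's wavelength axis.

    Returns background, one body spectrum per species (the first species
    carries ``pigment_depth`` added inside ``pigment_window``, matching the
    offset exactly inside and not at all outside), and the wing membrane
    term mixed into wings at render time.
    """
    wl = config.wavelengths
    background = (GREYCARD if config.background == "greycard" else LEAF).evaluate(wl)
    base = BODY_BASE.evaluate(wl)
    lo, hi = config.pigment_window
    bump = np.where((wl >= lo) & (wl <= hi), config.pigment_depth, 0.0)
    out = {"background": background, "wing_membrane": np.full(len(wl), WING_MEMBRANE_REFLECTANCE)}
    for i, sp in enumerate(config.species):
        out[f"body_{sp}"] = base + (bump if i == 0 else 0.0)
        if np.any(out[f"body_{sp}"] > 1.2):
            raise ValueError("body template exceeds reflectance 1.2")
    return out


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _insect_footprint(shape, center, a, b, theta):
    """Body ellipse plus two wing lobes; returns (body_mask, wing_mask)."""
    body = _ellipse_mask(shape, center, a, b, theta)
    wing = np.zeros(shape, dtype=bool)
    # Lobes sit either side of the minor axis, trailing slightly rearwards.
    for sign in (-1.0, 1.0):
        off_r = 0.3 * a * np.cos(theta) + sign * 1.1 * b * -np.sin(theta)
        off_c = 0.3 * a * np.sin(theta) + sign * 1.1 * b * np.cos(theta)
        lobe_center = (center[0] + off_r, center[1] + off_c)
        wing |= _ellipse_mask(shape, lobe_center, 0.9 * a, 0.7 * b, theta)
    wing &= ~body
    return body, wing


def render_scene(
    config: SceneConfig, seed: int, species: str | None = None
) -> tuple[SpectralCube, SceneTruth]:
    """Render one scene of a single species with exact ground truth.

    Insects are placed by rejection sampling so footprints never overlap;
    a scene too crowded to place errors out rather than overlapping. With
    ``noise_sigma = 0``, no jitter and no speckles, every pixel equals its
    template exactly.
    """
    species = species if species is not None else config.species[0]
    if species not in config.species:
        raise ValueError(f"unknown species {species!r}")
    rng = np.random.default_rng(int(seed))
    rows, cols = config.shape
    wl = config.wavelengths
    templates = make_template_spectra(config)
    body_template = templates[f"body_{species}"]
    wing_template = (
        config.wing_alpha * templates["background"]
        + (1.0 - config.wing_alpha) * templates["wing_membrane"]
    )

    anatomy = np.full((rows, cols), ANATOMY_BACKGROUND, dtype=np.int8)
    insect_map = np.zeros((rows, cols), dtype=np.int16)
    occupied = np.zeros((rows, cols), dtype=bool)
    registry = []
    data = np.empty((rows, cols, len(wl)))
    data[:, :, :] = templates["background"]

    for insect_id in range(1, config.insects_per_scene + 1):
        target_px = int(rng.integers(config.body_px_range[0], config.body_px_range[1] + 1))
        aspect = rng.uniform(0.55, 0.8)
        a = np.sqrt(target_px / (np.pi * aspect))
        b = aspect * a
        theta = rng.uniform(0, np.pi)
        placed = False
        margin = 1.2 * a + 1
        if margin >= rows - margin - 1 or margin >= cols - margin - 1:
            raise RuntimeError(
                "could not place insect without overlap; use fewer/smaller insects "
                "or a larger scene"
            )
        for _ in range(config.max_placement_tries):
            center = (
                rng.uniform(margin, rows - margin - 1),
                rng.uniform(margin, cols - margin - 1),
            )
            body, wing = _insect_footprint((rows, cols), center, a, b, theta)
            footprint = body | wing
            if not footprint.any() or (footprint & binary_dilation(occupied)).any():
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place insect without overlap; use fewer/smaller insects "
                "or a larger scene"
            )
        jitter = rng.normal(0.0, config.template_jitter_sd) if config.template_jitter_sd else 0.0
        data[body] = np.clip(body_template + jitter, 0.0, 1.2)
        data[wing] = wing_template
        anatomy[body] = ANATOMY_BODY
        anatomy[wing] = ANATOMY_WING
        insect_map[body | wing] = insect_id
        occupied |= body | wing
        registry.append(
            {
                "insect_id": insect_id,
                "species": species,
                "centroid": (float(center[0]), float(center[1])),
                "body_px": int(body.sum()),
            }
        )

    sigma = config.noise_sigma_per_band()
    if config.noise_sigma > 0:
        data += rng.standard_normal(data.shape) * sigma
    if config.speckle_count > 0:
        allowed = ~binary_dilation(occupied, iterations=2)
        allowed[0, :] = allowed[-1, :] = allowed[:, 0] = allowed[:, -1] = False
        free = np.argwhere(allowed)
        for _ in range(config.speckle_count):
            if len(free) == 0:
                break
            r0, c0 = free[rng.integers(len(free))]
            size = int(rng.integers(1, config.speckle_max_px + 1))
            pts = [(int(r0), int(c0))]
            while len(pts) < size:
                r, c = pts[-1]
                dr, dc = rng.integers(-1, 2, size=2)
                r, c = int(np.clip(r + dr, 0, rows - 1)), int(np.clip(c + dc, 0, cols - 1))
                if allowed[r, c]:
                    pts.append((r, c))
                else:
                    break
            for r, c in pts:
                data[r, c, :] = config.speckle_amplitude
    np.clip(data, 0.0, None, out=data)

    cube = SpectralCube(
        data=data,
        wavelengths=wl,
        image_id=f"scene-seed{int(seed)}",
        pixel_size_um=config.pixel_size_um,
    )
    truth = SceneTruth(anatomy=anatomy, insect_map=insect_map, registry=registry, species=species)
    return cube, truth


def _scene_seeds(seed: int, n: int) -> list[int]:
    # Stable per-scene integer seeds below 2**31 derived from one master seed.
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def generate_scenes(
    config: SceneConfig, n_scenes_per_class: int, seed: int
) -> list[tuple[SpectralCube, SceneTruth]]:
    """Render ``n_scenes_per_class`` scenes for every configured species.

    Scene image_ids encode the class label (``<species>_<index>``), the
    in-memory analogue of label-encoded cut-out filenames.
    """
    total = n_scenes_per_class * len(config.species)
    seeds = _scene_seeds(seed, total)
    scenes = []
    k = 0
    for sp in config.species:
        for i in range(n_scenes_per_class):
            cube, truth = render_scene(config, seed=seeds[k], species=sp)
            cube.image_id = f"{sp}_{i:03d}"
            scenes.append((cube, truth))
            k += 1
    return scenes


def parse_label_from_filename(path: str) -> str:
    """Class label encoded in a cut-out filename: ``<label>_<index>.hdr``."""
    stem = os.path.splitext(os.path.basename(path))[0]
    stem = stem.removesuffix(".labels")
    label = stem.rsplit("_", 1)[0]
    if not label:
        raise ValueError(f"cannot parse class label from filename {path!r}")
    return label


def generate_dataset(
    config: SceneConfig,
    n_scenes_per_class: int,
    out_dir: str,
    seed: int,
    force: bool = False,
) -> str:
    """Write a labelled synthetic dataset of ENVI cut-outs to ``out_dir``.

    Layout: ``scenes/<species>/<scene_id>.hdr/.img``, single-band anatomy
    truth maps under ``truth/<scene_id>.labels.hdr``, and a ``manifest.tsv``
    listing every scene with its seed, so the dataset is regenerable
    bit-identically. Returns the manifest path.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"output directory {out_dir!r} is not empty (use force)")
    os.makedirs(os.path.join(out_dir, "truth"), exist_ok=True)
    total = n_scenes_per_class * len(config.species)
    seeds = _scene_seeds(seed, total)
    lines = ["scene_id\tspecies\tseed\tscene_header\ttruth_header\tn_insects\tbody_px"]
    k = 0
    for sp in config.species:
        sp_dir = os.path.join(out_dir, "scenes", sp)
        os.makedirs(sp_dir, exist_ok=True)
        for i in range(n_scenes_per_class):
            scene_id = f"{sp}_{i:03d}"
            cube, truth = render_scene(config, seed=seeds[k], species=sp)
            cube.image_id = scene_id
            hdr = os.path.join(sp_dir, scene_id + ".hdr")
            write_envi(cube, hdr)
            truth_cube = SpectralCube(
                data=truth.anatomy.astype("<f4")[:, :, None],
                wavelengths=np.array([0.0]),
                image_id=scene_id + ".labels",
            )
            truth_hdr = os.path.join(out_dir, "truth", scene_id + ".labels.hdr")
            write_envi(truth_cube, truth_hdr)
            body_px = sum(r["body_px"] for r in truth.registry)
            lines.append(
                f"{scene_id}\t{sp}\t{seeds[k]}\t{os.path.relpath(hdr, out_dir)}\t"
                f"{os.path.relpath(truth_hdr, out_dir)}\t{len(truth.registry)}\t{body_px}"
            )
            k += 1
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return manifest


def bayes_pixel_accuracy(
    config: SceneConfig, scheme: WavebandScheme, window=None
) -> float:
    """Analytic Bayes accuracy of the two-class body-pixel task after resampling.

    Under the generator's noise model (independent Gaussian band noise, no
    template jitter, no median filtering) the two classes are Gaussians with
    equal diagonal covariance whose means differ by the pigment offset
    averaged into each waveband. The optimal error rate is then
    ``1 - Phi(d'/2)`` with ``d'^2 = sum_j (delta_j / sigma_j)^2``.
    """
    wl = config.wavelengths
    sigma_src = config.noise_sigma_per_band()
    edges = np.asarray(scheme.edges)
    lo_w, hi_w = config.pigment_window
    d_prime_sq = 0.0
    for j in range(scheme.n_bands):
        lo, hi = edges[j], edges[j + 1]
        sel = (wl >= lo) & ((wl < hi) if j < scheme.n_bands - 1 else (wl <= hi))
        m = int(sel.sum())
        if m == 0:
            continue
        frac_in = float(((wl[sel] >= lo_w) & (wl[sel] <= hi_w)).mean())
        delta = config.pigment_depth * frac_in
        var = float((sigma_src[sel] ** 2).sum()) / m**2
        if var > 0:
            d_prime_sq += delta**2 / var
    return float(norm.cdf(np.sqrt(d_prime_sq) / 2.0))
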