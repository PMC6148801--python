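import dataclasses

import numpy as np
import pytest

import whitefly_msi as wm


@pytest.fixture
def small_cube():
    """A tiny deterministic 3x4x5 reflectance cube."""
    rng = np.random.default_rng(12345)
    return wm.SpectralCube(
        data=rng.random((3, 4, 5)),
        wavelengths=np.array([450.0, 550.0, 650.0, 750.0, 850.0]),
        image_id="tiny",
    )


@pytest.fixture(scope="session")
def default_config():
    return wm.SceneConfig()


@pytest.fixture(scope="session")
def greycard_scene():
    """One default grey-card scene with truth, shared across tests."""
    return wm.render_scene(wm.SceneConfig(), seed=2024, species="SSA1")


@pytest.fixture(scope="session")
def leaf_config():
    return wm.leaf_scene_config()


def make_table(spectra, wavelengths=None, image_ids=None):
    """Build a PixelSpectraTable from a bare matrix for unit tests."""
    spectra = np.asarray(spectra, dtype=float)
    n, b = spectra.shape
    return wm.PixelSpectraTable(
        spectra=spectra,
        coords=np.zeros((n, 2), dtype=int),
        image_ids=np.asarray(image_ids if image_ids is not None else ["img"] * n, dtype=object),
        wavelengths=np.arange(b, dtype=float) if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )
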