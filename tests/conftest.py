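import numpy as np
import pytest

from larvascreen import imaging
from larvascreen.layout import default_screen_layout
from larvascreen.simulate import (ArtifactModel, PlateGeometry, SizeModel,
                                  simulate_plate_image)

GEOMETRY = PlateGeometry()
GRID = imaging.GridSpec.from_geometry(GEOMETRY)


@pytest.fixture(scope="session")
def clean_plate():
    """One artifact-free rendered screen plate with its ground truth."""
    layout = default_screen_layout("FIX1", [(f"C{i:02d}", f"S{i:02d}")
                                            for i in range(80)])
    rng = np.random.default_rng(2024)
    img, truth = simulate_plate_image(layout, SizeModel(),
                                      ArtifactModel.none(), rng, GEOMETRY)
    return img, truth


@pytest.fixture(scope="session")
def artifact_plate():
    """A plate where half the wells carry the uneaten-food background blob."""
    layout = default_screen_layout("FIX2", [(f"C{i:02d}", f"S{i:02d}")
                                            for i in range(80)])
    art = ArtifactModel(p_high_background=0.5, p_low_dmso=0.0)
    rng = np.random.default_rng(2025)
    img, truth = simulate_plate_image(layout, SizeModel(), art, rng, GEOMETRY)
    return img, truth


@pytest.fixture(scope="session")
def clean_measurements(clean_plate):
    img, truth = clean_plate
    meas = imaging.measure_plate(img, GRID, "FIX1")
    return meas.merge(truth, on=["row", "col"])


def uniform_well_patch(level=0.75, radius=65, noise=0.0, seed=0):
    """Square well patch with uniform background (no rim)."""
    side = 2 * radius + 1
    patch = np.full((side, side), float(level))
    if noise:
        patch += np.random.default_rng(seed).normal(0.0, noise, patch.shape)
    return patch
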