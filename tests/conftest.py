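import numpy as np
import pytest

import protongrid as pg
from protongrid.dose import single_slice_grid


@pytest.fixture(scope="session")
def spec():
    return pg.CollimatorSpec()


@pytest.fixture(scope="session")
def holes(spec):
    return pg.layout_holes(spec)


@pytest.fixture(scope="session")
def default_mesh(spec, holes):
    return pg.build_mesh(spec, holes)


@pytest.fixture(scope="session")
def beam_model():
    return pg.BeamModel()


@pytest.fixture(scope="session")
def iso_grid(spec):
    """Single-slice grid at isocenter depth (10 cm)."""
    return single_slice_grid(spec, depth=100.0)


@pytest.fixture(scope="session")
def iso_plane(spec, beam_model, iso_grid):
    """Simulated GRID dose plane at isocenter for the nominal geometry."""
    dose = pg.simulate_dose(spec, beam_model, grid=iso_grid,
                            phantom_depth_range=(99.0, 101.0), mu=1000.0)
    return pg.extract_plane(dose, 100.0)


def make_plane(values, spacing=1.0, origin=None):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = [-(values.shape[0] - 1) / 2.0 * spacing,
                  -(values.shape[1] - 1) / 2.0 * spacing]
    return pg.DosePlane(origin=np.asarray(origin, dtype=float),
                        spacing=np.array([spacing, spacing]), values=values)
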