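import numpy as np
import pytest

from incellproc.stream_io import UnitCell
from incellproc.synthetic_data import simulate_scan
from incellproc.wedge_finder import ScanGeometry


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(15.0, 15.0, 15.0, 90.0, 90.0, 90.0, lattice_type="cubic")


@pytest.fixture(scope="session")
def hex_cell():
    return UnitCell(
        79.0, 79.0, 170.0, 90.0, 90.0, 120.0,
        lattice_type="hexagonal", unique_axis_label="c",
    )


@pytest.fixture(scope="session")
def small_scan():
    """A small noise-free simulated scan with its truth record."""
    geom = ScanGeometry(frames_per_line=50, n_lines=8, rot_per_frame=0.1)
    cell = UnitCell(15.0, 15.0, 15.0, 90.0, 90.0, 90.0, lattice_type="cubic")
    dataset, truth = simulate_scan(
        geom, n_crystals=10, cell=cell, noise_fraction=0.0, seed=2,
        d_min=3.0, reflections_per_frame=40,
    )
    return geom, dataset, truth


def random_cell_nm_rounded(rng: np.random.Generator) -> UnitCell:
    """A random triclinic-ish cell whose lengths are exact at the precision
    the stream writer prints (7 decimals in nm), so round trips are exact."""
    def nm7(x):
        return float(format(x, ".7f")) * 10.0

    a = nm7(rng.uniform(1.0, 5.0))
    b = nm7(rng.uniform(1.0, 5.0))
    c = nm7(rng.uniform(1.0, 5.0))
    al, be, ga = (float(format(x, ".7f")) for x in rng.uniform(80.0, 100.0, 3))
    return UnitCell(a, b, c, al, be, ga)
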