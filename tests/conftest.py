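import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from spatomix import phantom
from spatomix.grid import make_spot_grid
from spatomix.msi import MSICube


@pytest.fixture(scope="session")
def small_region_image():
    """Three-region phantom at reduced scale."""
    return phantom.make_phantom(
        2000, 2000, 50, {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}, seed=7
    )


@pytest.fixture(scope="session")
def three_region_programs():
    """Three disjoint metabolite archetypes, one per region, 4x contrast."""
    comps = [
        "glutamine", "glutamate", "arginine", "proline", "spermine",
        "histamine", "glucose", "taurine", "creatine",
    ]
    rows = [(phantom.BASELINE_REGION, c, "metabolite", 20.0, 0.0) for c in comps]
    for r in range(3):
        for c in comps[3 * r: 3 * r + 3]:
            rows.append((r, c, "metabolite", 20.0, 2.0))
    return pd.DataFrame(rows, columns=phantom.PROGRAM_COLUMNS)


@pytest.fixture(scope="session")
def small_cube(small_region_image, three_region_programs) -> MSICube:
    return phantom.simulate_msi_cube(
        small_region_image, 100.0, three_region_programs, seed=7
    )


@pytest.fixture(scope="session")
def small_grid():
    return make_spot_grid((2000, 2000), 100, 55, seed=7)


def toy_cube(intensities, mz=None, pitch=100.0) -> MSICube:
    """Small MSICube from a dense pixels x peaks array on a square-ish grid."""
    intensities = np.asarray(intensities, float)
    n_pix, n_peaks = intensities.shape
    n_cols = int(np.ceil(np.sqrt(n_pix)))
    rows = np.arange(n_pix) // n_cols
    cols = np.arange(n_pix) % n_cols
    coords = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "x": pitch / 2 + cols * pitch,
            "y": pitch / 2 + rows * pitch,
        }
    )
    if mz is None:
        mz = 100.0 + np.arange(n_peaks)
    return MSICube(coords, np.asarray(mz, float), intensities, pitch)
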