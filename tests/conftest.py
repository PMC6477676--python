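import numpy as np
import pandas as pd
import pytest

from stau_rnaloc import NoiseSpec, make_oocyte, simulate_rna_spots


@pytest.fixture(scope="session")
def oocyte():
    """Standard 100 x 50 µm elliptical oocyte, AP axis along x."""
    return make_oocyte(100.0, 50.0, n_vertices=64, seed=1)


@pytest.fixture()
def uniform_spots(oocyte):
    spots, truth = simulate_rna_spots(
        oocyte, 500, copy_geometric_p=0.8, noise=NoiseSpec(cv=0.2, seed=11)
    )
    return spots, truth


def brute_force_nn(rna_xy: np.ndarray, prot_xy: np.ndarray):
    """O(n*m) exhaustive nearest-neighbour oracle."""
    d = np.sqrt(
        ((rna_xy[:, None, :] - prot_xy[None, :, :]) ** 2).sum(axis=2)
    )
    idx = d.argmin(axis=1)
    return idx, d[np.arange(len(rna_xy)), idx]


@pytest.fixture(scope="session")
def brute_nn():
    return brute_force_nn


def spot_frame(xy: np.ndarray, intensity=1.0, channel="ch") -> pd.DataFrame:
    xy = np.atleast_2d(xy)
    return pd.DataFrame(
        {
            "id": np.arange(len(xy)),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "channel": channel,
            "intensity": np.broadcast_to(intensity, len(xy)).astype(float),
        }
    )
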