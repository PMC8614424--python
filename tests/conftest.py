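import numpy as np
import pandas as pd
import pytest

from nirscal.dataset import ReferenceTable, SpectraSet
from nirscal.simulate import (
    CORN_STOVER,
    GaussianBand,
    make_component_library,
    simulate_dataset,
)


@pytest.fixture()
def small_grid() -> np.ndarray:
    """A coarse 851-point grid (850-1700 nm at 1 nm) keeping tests quick."""
    return np.arange(850.0, 1700.5, 1.0)


@pytest.fixture()
def tiny_spectra() -> SpectraSet:
    wl = np.array([850.0, 850.5, 851.0, 851.5, 852.0])
    rng = np.random.default_rng(0)
    return SpectraSet(
        wavelengths=wl,
        absorbance=rng.uniform(0.2, 1.0, size=(4, 5)),
        sample_ids=[f"s{i}" for i in range(4)],
        species=["corn_stover"] * 4,
    )


@pytest.fixture(scope="session")
def corn_dataset():
    """120 synthetic corn-stover samples on the full instrument grid."""
    return simulate_dataset(CORN_STOVER.with_seed(11), 120)


@pytest.fixture(scope="session")
def small_library(small_grid_session=None):
    grid = np.arange(850.0, 1700.5, 1.0)
    bands = {
        "a": (GaussianBand(1100, 40, 0.01), GaussianBand(1500, 60, 0.004)),
        "b": (GaussianBand(1300, 50, 0.008), GaussianBand(1600, 30, 0.006)),
        "c": (GaussianBand(1000, 70, 0.005), GaussianBand(1450, 45, 0.007)),
    }
    return make_component_library(bands, grid)


def make_reference(values: dict[str, list[float]], ids=None) -> ReferenceTable:
    df = pd.DataFrame(values)
    n = len(df)
    df.index = pd.Index(ids or [f"s{i}" for i in range(n)], name="sample_id")
    return ReferenceTable(data=df)
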