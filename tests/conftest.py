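import numpy as np
import pytest

from dcmforge import fixtures, sop


@pytest.fixture(scope="session")
def ct_series():
    """Three-slice 16x16 axial CT series (patient frame of reference)."""
    return fixtures.generate_ct_series(
        fixtures.CtSeriesSpec(n_slices=3, rows=16, cols=16, seed=7))


@pytest.fixture(scope="session")
def sm_image():
    """4-tile 64x64 slide-microscopy image (slide frame of reference)."""
    return fixtures.generate_sm_image(fixtures.SmImageSpec(seed=7))


@pytest.fixture()
def roundtrip(tmp_path):
    """Write a dataset to a Part-10 file and read it back."""

    def _roundtrip(ds, name="object.dcm"):
        path = tmp_path / name
        sop.write_dataset(ds, path)
        return sop.read_dataset(path)

    return _roundtrip


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
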