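import numpy as np
import pytest

from mpmri.synthetic import CohortSpec, generate_patient


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest valid cohort: 2 + 2 patients, radius-2 ROI (33 voxels)."""
    return CohortSpec(n_responders=2, n_nonresponders=2, roi_radius=2, seed=7)


@pytest.fixture(scope="session")
def noiseless_spec():
    return CohortSpec(
        n_responders=2, n_nonresponders=2, roi_radius=3,
        noise_dce=0.0, snr_dwi=np.inf, seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_patient(noiseless_spec):
    rng = np.random.default_rng(10)
    return generate_patient(noiseless_spec, "P1", True, rng)


def make_selection_fixture():
    """24 x 20 table: 10 informative + 5 constant + 5 duplicated columns.

    Informative columns are the group step plus bounded cosine noise: even
    DCT modes over 24 points are mutually orthogonal and orthogonal to the
    half-split group vector, so informative pairs correlate ~0.76 (< 0.8)
    while min-max-scaled variance stays above 0.1.  Duplicates are
    lower-variance scaled copies of the first five informative columns.
    """
    import pandas as pd

    i = np.arange(24)
    group = np.array([0.0] * 12 + [1.0] * 12)
    cols = {}
    for k, j in enumerate(range(2, 22, 2)):
        cols[f"inf{k:02d}"] = group + 0.4 * np.cos(np.pi * j * (i + 0.5) / 24)
    for j in range(5):
        cols[f"const{j}"] = np.full(24, float(j))
    for j in range(5):
        cols[f"dup{j}"] = 0.5 * cols[f"inf0{j}"]
    return pd.DataFrame(cols)


def random_levels_image(rng, shape, ng):
    """Random discretised image + mask guaranteed non-trivial."""
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if mask.sum() < 4:  # ensure enough voxels for pairs/zones
        mask.flat[:4] = True
    return levels, mask
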