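from __future__ import annotations

import numpy as np
import pytest

from organoquant import simulate_organoid_stack


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_stack():
    """A desk-scale two-channel stack: 12 well-separated bright nuclei."""
    stack, truth = simulate_organoid_stack(
        shape=(24, 96, 96),
        n_nuclei=12,
        nucleus_radius=6.0,
        edu_fraction=0.25,
        snr=20.0,
        seed=7,
    )
    return stack, truth


@pytest.fixture(scope="session")
def jaccard_stack():
    """20 bright nuclei at high signal-to-noise for mask-overlap checks."""
    return simulate_organoid_stack(
        shape=(30, 128, 128),
        n_nuclei=20,
        nucleus_radius=6.0,
        edu_fraction=0.3,
        snr=30.0,
        seed=11,
    )


def truth_sphere_mask(truth, labeled_only: bool = False) -> np.ndarray:
    """Rasterize the ground-truth spheres into a boolean volume."""
    mask = np.zeros(truth.shape, dtype=bool)
    grids = np.ogrid[: truth.shape[0], : truth.shape[1], : truth.shape[2]]
    for (c, r, lab) in zip(truth.centers, truth.radii, truth.edu_labels):
        if labeled_only and not lab:
            continue
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        mask |= d2 <= r**2
    return mask
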