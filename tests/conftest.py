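"""Shared fixtures.

The expensive two-layer Monte-Carlo run (1e7 photons, annuli at
5..30 mm) is session-scoped: the scaled-down wMAPE validation and the
MC-vs-theory cross-checks all read from the same tally.
"""

import numpy as np
import pytest

from dtofsf.fixtures import benchmark_media, example_medium
from dtofsf.monte_carlo import McConfig, PhotonTally, simulate


@pytest.fixture(scope="session")
def media():
    return benchmark_media()


@pytest.fixture(scope="session")
def two_layer(media):
    return media["two_layer"]


@pytest.fixture(scope="session")
def five_layer(media):
    return media["five_layer"]


@pytest.fixture(scope="session")
def ten_layer(media):
    return media["ten_layer"]


@pytest.fixture(scope="session")
def example_two():
    return example_medium()


@pytest.fixture(scope="session")
def big_two_layer_tally(two_layer):
    """1e7-photon run of the two-layer benchmark, detectors at
    rho = 5, 10, ..., 30 mm (the scaled-down validation geometry)."""
    config = McConfig(n_photons=10_000_000, seed=20260919,
                      detector_radii=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0))
    return simulate(two_layer, config)


def make_tally(medium, records_l, weights, config=None) -> PhotonTally:
    """Build a PhotonTally from explicit per-photon pathlength rows and
    weights (single batch, single annulus) for estimator arithmetic tests."""
    from dtofsf.medium import C_VACUUM
    l = np.atleast_2d(np.asarray(records_l, dtype=float))
    w = np.asarray(weights, dtype=float)
    inv_c = medium.n / C_VACUUM
    t = l @ inv_c
    if config is None:
        config = McConfig(n_photons=len(w), detector_radii=(10.0,),
                          n_batches=1)
    N = medium.n_layers
    return PhotonTally(
        medium=medium, config=config,
        count=np.array([[len(w)]]),
        sum_w=np.array([[w.sum()]]),
        sum_lw=(w[:, None] * l).sum(0)[None, None, :],
        sum_llw=np.einsum("i,ij,ik->jk", w, l, l)[None, None],
        sum_lllw=np.einsum("i,ij,ik,im->jkm", w, l, l, l)[None, None],
        sum_tw=np.array([[np.sum(t * w)]]),
        sum_t2w=np.array([[np.sum(t ** 2 * w)]]),
        n_launched=len(w), n_detected=len(w), n_escaped=0, n_terminated=0)
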