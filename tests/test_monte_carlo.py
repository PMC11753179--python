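"""Monte-Carlo estimator arithmetic on hand-built tallies, simulator
bookkeeping/determinism, and the error metric."""

import numpy as np
import pytest

from conftest import make_tally
from dtofsf.medium import C_VACUUM, Layer, LayeredMedium
from dtofsf.monte_carlo import (McConfig, mc_mppl, mc_mtsf, mc_vsf,
                                reweighted_moments, simulate, wmape)


@pytest.fixture(scope="module")
def med2():
    return LayeredMedium([Layer(0.018, 1.9, 1.33, 5.0),
                          Layer(0.017, 2.3, 1.33, None)])


# -- estimator arithmetic on synthetic records ------------------------------

def test_single_record_mppl_is_the_record(med2):
    tally = make_tally(med2, [[3.0, 5.0]], [1.0])
    L, _ = mc_mppl(tally)
    assert np.allclose(L[0], [3.0, 5.0])


def test_two_record_mppl_hand_average(med2):
    tally = make_tally(med2, [[2.0, 0.0], [4.0, 0.0]], [1.0, 1.0])
    L, _ = mc_mppl(tally)
    assert np.allclose(L[0], [3.0, 0.0])


def test_single_record_mtsf_and_vsf_vanish(med2):
    tally = make_tally(med2, [[3.0, 5.0]], [2.0])
    m, _ = mc_mtsf(tally)
    v, _ = mc_vsf(tally)
    assert np.allclose(m, 0.0, atol=1e-10)
    assert np.allclose(v, 0.0, atol=1e-7)


def test_two_record_mtsf_hand_arithmetic(med2):
    c = C_VACUUM / 1.33
    l = np.array([[1.0, 0.0], [0.0, 1.0]])
    tally = make_tally(med2, l, [1.0, 1.0])
    m, _ = mc_mtsf(tally)
    # by hand: <l_j l_m> = diag(1/2), t_i = 1/c each, <t> = 1/c, L = (1/2,1/2)
    expect = -0.5 / c + 0.5 * (1.0 / c)
    assert np.allclose(m[0], [expect, expect])
    assert np.allclose(m[0], 0.0)  # equal times: mean-time insensitive


def test_three_record_estimators_match_brute_force(med2):
    rng = np.random.default_rng(5)
    l = rng.uniform(0.5, 30.0, size=(3, 2))
    w = rng.uniform(0.2, 1.0, size=3)
    tally = make_tally(med2, l, w)
    inv_c = med2.n / C_VACUUM
    t = l @ inv_c
    sw = w.sum()
    L_ref = (w[:, None] * l).sum(0) / sw
    t_mean = np.sum(t * w) / sw
    t2_mean = np.sum(t * t * w) / sw
    ll = np.einsum("i,ij,im->jm", w, l, l) / sw
    lll = np.einsum("i,ij,im,ik->jmk", w, l, l, l) / sw
    mtsf_ref = np.zeros(2)
    vsf_ref = np.zeros(2)
    for j in range(2):
        mtsf_ref[j] = -sum(ll[j, m] * inv_c[m] for m in range(2)) \
            + L_ref[j] * t_mean
        vsf_ref[j] = (-sum(lll[j, m, n] * inv_c[m] * inv_c[n]
                           for m in range(2) for n in range(2))
                      + 2 * t_mean * sum(ll[j, m] * inv_c[m] for m in range(2))
                      + L_ref[j] * (t2_mean - 2 * t_mean ** 2))
    L, _ = mc_mppl(tally)
    m, _ = mc_mtsf(tally)
    v, _ = mc_vsf(tally)
    assert np.allclose(L[0], L_ref)
    assert np.allclose(m[0], mtsf_ref)
    assert np.allclose(v[0], vsf_ref)


# -- simulator bookkeeping --------------------------------------------------

def test_conservation_and_determinism(med2):
    cfg = McConfig(n_photons=20_000, seed=7, detector_radii=(10.0,),
                   n_batches=4)
    t1 = simulate(med2, cfg)
    t2 = simulate(med2, cfg)
    assert (t1.n_detected + t1.n_escaped + t1.n_terminated
            == cfg.n_photons)
    assert np.array_equal(t1.sum_w, t2.sum_w)
    assert np.array_equal(t1.sum_lllw, t2.sum_lllw)
    assert t1.n_detected == t2.n_detected
    t3 = simulate(med2, McConfig(n_photons=20_000, seed=8,
                                 detector_radii=(10.0,), n_batches=4))
    assert not np.array_equal(t1.sum_w, t3.sum_w)


def test_zero_absorption_gives_unit_weights():
    med = LayeredMedium([Layer(0.0, 1.9, 1.33, 5.0),
                         Layer(0.0, 2.3, 1.33, None)])
    cfg = McConfig(n_photons=20_000, seed=3, detector_radii=(5.0,),
                   n_batches=2)
    tally = simulate(med, cfg)
    # every detected weight is exactly 1 -> sum_w equals the counts
    assert np.allclose(tally.sum_w, tally.count.astype(float))


def test_standard_errors_shrink_with_photon_budget(med2):
    """Quadrupling the photon budget should halve the batch-means standard
    errors (1/sqrt(n) convergence), within estimator noise."""
    cfg1 = McConfig(n_photons=100_000, seed=5, detector_radii=(10.0,),
                    n_batches=100)
    cfg4 = McConfig(n_photons=400_000, seed=5, detector_radii=(10.0,),
                    n_batches=100)
    _, se1 = mc_mppl(simulate(med2, cfg1))
    _, se4 = mc_mppl(simulate(med2, cfg4))
    ratio = np.linalg.norm(se1) / np.linalg.norm(se4)
    assert ratio == pytest.approx(2.0, rel=0.2)


def test_rejects_invalid_configuration(med2):
    with pytest.raises(ValueError):
        McConfig(n_photons=0)
    with pytest.raises(ValueError):
        McConfig(n_photons=10, g=1.0)
    with pytest.raises(ValueError):
        McConfig(n_photons=10, detector_radii=(10.0, 10.5))
    bounded = LayeredMedium([Layer(0.01, 1.0, 1.33, 5.0),
                             Layer(0.01, 1.0, 1.33, 5.0)])
    with pytest.raises(ValueError):
        simulate(bounded, McConfig(n_photons=10))


def test_empty_annulus_raises(med2):
    cfg = McConfig(n_photons=200, seed=1, detector_radii=(45.0,),
                   n_batches=1)
    tally = simulate(med2, cfg)
    if tally.count.sum() == 0:
        with pytest.raises(ValueError):
            mc_mppl(tally)
    else:  # extremely unlikely at 200 photons and 45 mm
        pytest.skip("photons reached the far annulus")


def test_record_reweighting_matches_native_weights(med2):
    cfg = McConfig(n_photons=100_000, seed=9, detector_radii=(10.0,),
                   n_batches=2, store_records=True)
    tally = simulate(med2, cfg)
    sw, t_mean, _ = reweighted_moments(tally, med2.mu_a)
    assert sw[0] == pytest.approx(tally.sum_w.sum(), rel=1e-12)
    assert t_mean[0] == pytest.approx(
        tally.sum_tw.sum() / tally.sum_w.sum(), rel=1e-12)


# -- error metric -----------------------------------------------------------

def test_wmape_identical_vectors_is_zero():
    assert wmape([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_wmape_hand_example():
    assert wmape([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0)


def test_wmape_rejects_degenerate_input():
    with pytest.raises(ValueError):
        wmape([1.0, 2.0], [1.0])
    with pytest.raises(ZeroDivisionError):
        wmape([0.0, 0.0], [1.0, 1.0])
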