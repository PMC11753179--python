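"""Forward model: spectral basis, Green's function, CW/TD reflectance and
analytic moments, checked against high-precision and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtofsf.forward_model import (alpha, bessel_basis, beta_gamma,
                                  cw_reflectance, green_g1,
                                  homogeneous_cw_reflectance,
                                  homogeneous_mean_time, moments,
                                  td_reflectance)
from dtofsf.medium import Layer, LayeredMedium, derive_optics
from oracles import j0_zero_mcmahon, mp_green_g1


def homogeneous(mu_a=0.01, mu_s=1.0, n_layers=3, d=5.0):
    layers = [Layer(mu_a, mu_s, 1.33, d) for _ in range(n_layers - 1)]
    layers.append(Layer(mu_a, mu_s, 1.33, None))
    return LayeredMedium(layers)


# -- spectral basis ---------------------------------------------------------

def test_bessel_basis_known_first_roots():
    basis = bessel_basis(1.0, 3)
    expect = [2.404825557695773, 5.520078110286311, 8.653727912911013]
    assert np.allclose(basis.s, expect, rtol=1e-12)
    halved = bessel_basis(2.0, 1)
    assert halved.s[0] == pytest.approx(expect[0] / 2.0, rel=1e-12)


def test_bessel_basis_tail_matches_mcmahon_expansion():
    basis = bessel_basis(1.0, 5000)
    assert np.all(np.diff(basis.s) > 0)
    for n in (1000, 2500, 5000):
        assert basis.s[n - 1] == pytest.approx(j0_zero_mcmahon(n), rel=1e-12)
    # asymptotic spacing pi / R_EB
    assert np.diff(basis.s)[-1] == pytest.approx(np.pi, rel=1e-6)


def test_bessel_basis_validates_count():
    with pytest.raises(ValueError):
        bessel_basis(1.0, 0)
    with pytest.raises(ValueError):
        bessel_basis(1.0, 5001)


# -- alpha ------------------------------------------------------------------

def test_alpha_direct_substitution():
    med = LayeredMedium([Layer(0.01, 1.0, 1.33, 5.0),
                         Layer(0.01, 1.0, 1.33, None)])
    a = alpha(0, med, s_n=0.0, omega=0.0)
    assert a == pytest.approx(np.sqrt(0.01 * 3.0), rel=1e-12)  # sqrt(0.03)


@given(st.floats(0.001, 0.05), st.floats(0.5, 2.5), st.floats(0.0, 2.0),
       st.floats(0.001, 0.1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_alpha_branch_properties(mu_a, mu_s, s_n, omega):
    med = LayeredMedium([Layer(mu_a, mu_s, 1.33, 5.0),
                         Layer(mu_a, mu_s, 1.33, None)])
    a0 = alpha(0, med, s_n, 0.0)
    assert np.imag(a0) == 0 and np.real(a0) > 0
    aw = alpha(0, med, s_n, omega)
    assert np.real(aw) > 0 and np.imag(aw) > 0
    assert alpha(0, med, s_n, -omega) == pytest.approx(np.conj(aw))


# -- beta/gamma recursion ---------------------------------------------------

def test_two_layer_convention():
    med = LayeredMedium([Layer(0.018, 1.9, 1.33, 5.0),
                         Layer(0.017, 2.3, 1.33, None)])
    b, g, ls = beta_gamma(med, 0.05)
    assert b == 1.0 and g == 1.0 and np.all(ls == 0)


def test_three_layer_seed_is_closed_form():
    med = LayeredMedium([Layer(0.018, 1.9, 1.33, 5.0),
                         Layer(0.016, 1.6, 1.33, 5.0),
                         Layer(0.002, 1.0, 1.33, None)])
    opt = derive_optics(med)
    s = 0.07
    a2 = alpha(1, med, s)
    a3 = alpha(2, med, s)
    n2 = 1.33 ** 2
    d2 = 5.0
    beta_exact = (opt.D[1] * a2 * n2 * np.cosh(a2 * d2)
                  + opt.D[2] * a3 * n2 * np.sinh(a2 * d2))
    gamma_exact = (opt.D[1] * a2 * n2 * np.sinh(a2 * d2)
                   + opt.D[2] * a3 * n2 * np.cosh(a2 * d2))
    b, g, ls = beta_gamma(med, s)
    assert b * np.exp(ls) == pytest.approx(beta_exact, rel=1e-12)
    assert g * np.exp(ls) == pytest.approx(gamma_exact, rel=1e-12)


def test_five_layer_recursion_against_high_precision(five_layer):
    for s in (0.01, 0.05, 0.5, 2.0):
        b, g, ls = beta_gamma(five_layer, s)
        b_mp, g_mp, _ = mp_green_g1(five_layer, s)
        assert b * np.exp(ls) == pytest.approx(b_mp.real, rel=1e-12)
        assert g * np.exp(ls) == pytest.approx(g_mp.real, rel=1e-12)


# -- Green's function -------------------------------------------------------

def test_green_matches_high_precision_oracle(five_layer, example_two):
    for med in (five_layer, example_two):
        for s in (0.01, 0.1, 1.0):
            _, _, G_mp = mp_green_g1(med, s)
            assert green_g1(med, s) == pytest.approx(G_mp.real, rel=1e-12)
        for omega in (0.002, 0.02):
            _, _, G_mp = mp_green_g1(med, 0.05, omega)
            got = complex(green_g1(med, 0.05, omega))
            assert abs(got - G_mp) / abs(G_mp) < 1e-12


def test_green_identical_layers_reduce_to_first_term():
    med = homogeneous()
    opt = derive_optics(med)
    a1 = alpha(0, med, 0.3)
    first = (np.exp(-a1 * opt.z0) - np.exp(-a1 * (opt.z0 + 2 * opt.z_b))) \
        / (2 * opt.D[0] * a1)
    assert green_g1(med, 0.3) == pytest.approx(first, rel=1e-12)


@given(st.floats(0.005, 0.05), st.floats(0.01, 1.0), st.floats(0.001, 0.05))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_green_hermitian_symmetry(mu_a, s, omega):
    med = LayeredMedium([Layer(mu_a, 1.9, 1.33, 5.0),
                         Layer(0.017, 2.3, 1.33, None)])
    g = complex(green_g1(med, s, omega))
    g_neg = complex(green_g1(med, s, -omega))
    assert g_neg == pytest.approx(np.conj(g), rel=1e-12)
    assert complex(green_g1(med, s, 0.0)).imag == 0


def test_green_renormalization_invariance(five_layer):
    """Scaling (beta, gamma) jointly cancels in G1: evaluating the medium
    with rescaled last-layer amplitudes via the homogeneity of the fraction
    is implicit; here we check G is insensitive to the recursion's internal
    scale by comparing against the unrenormalized high-precision value at an
    eigenvalue large enough to overflow naive cosh evaluation."""
    s = 50.0  # naive cosh recursion would accumulate ~e^{1000} and overflow
    _, _, G_mp = mp_green_g1(five_layer, s, dps=120)
    assert green_g1(five_layer, s) == pytest.approx(G_mp.real, rel=1e-10)


# -- CW reflectance ---------------------------------------------------------

def test_homogeneous_cw_matches_dipole_closed_form():
    med = homogeneous(0.01, 0.9, n_layers=4, d=4.0)
    for rho in (5.0, 10.0, 20.0, 30.0, 40.0):
        series = cw_reflectance(med, rho)
        dipole = homogeneous_cw_reflectance(0.01, 0.9, 1.33, 1.0, rho)
        assert series == pytest.approx(dipole, rel=5e-3)


def test_cw_monotone_decreasing_in_distance(media):
    for med in media.values():
        r = [cw_reflectance(med, rho) for rho in np.arange(5.0, 51.0, 5.0)]
        assert np.all(np.diff(r) < 0)
        assert np.all(np.asarray(r) > 0)


def test_cw_decreases_with_any_layer_absorption(five_layer):
    base = cw_reflectance(five_layer, 25.0)
    for j in range(five_layer.n_layers):
        mu = five_layer.mu_a.copy()
        mu[j] += 0.002
        assert cw_reflectance(five_layer.with_mu_a(mu), 25.0) < base


def test_cw_series_stable_under_zero_count_doubling(media):
    """The default 5000-zero cap is converged: doubling to 10000 zeros moves
    the CW value by < 1e-4 relative at rho <= 40 mm."""
    from scipy.special import jn_zeros
    from dtofsf.forward_model import SpectralBasis, bessel_basis
    zeros10k = jn_zeros(0, 10000)
    for med in media.values():
        opt = derive_optics(med)
        full = bessel_basis(opt.R_EB, 5000)
        double = SpectralBasis(zeros10k / opt.R_EB, opt.R_EB)
        for rho in (10.0, 40.0):
            a = cw_reflectance(med, rho, basis=full)
            b = cw_reflectance(med, rho, basis=double)
            assert abs(a / b - 1) < 1e-4


def test_cw_rejects_rho_outside_cylinder(two_layer):
    with pytest.raises(ValueError):
        cw_reflectance(two_layer, 260.0)


# -- time domain ------------------------------------------------------------

def test_dtof_normalization_and_shape(example_two):
    dtof = td_reflectance(example_two, 30.0)
    assert np.all(dtof.values >= 0)
    assert dtof.m0 == pytest.approx(cw_reflectance(example_two, 30.0), rel=5e-3)
    # single-peaked: rises then falls
    peak = np.argmax(dtof.values)
    nz = dtof.values > 1e-6 * dtof.values[peak]
    idx = np.nonzero(nz)[0]
    assert 0 < peak < len(dtof.t) - 1
    diffs = np.diff(dtof.values[idx[0]:idx[-1]])
    sign_changes = np.sum(np.diff(np.sign(diffs[np.abs(diffs) > 0])) != 0)
    assert sign_changes <= 2


def test_dtof_causality(example_two):
    dtof = td_reflectance(example_two, 30.0)
    c1 = 0.299792458 / 1.33
    early = dtof.t < 30.0 / c1
    assert np.all(dtof.values[early] < 1e-3 * dtof.values.max())


def test_dtof_moments_match_mu_a_derivative_path(example_two, two_layer):
    # example_two's deep layer absorbs weakly, so its DTOF tail needs a 20 ns window
    for med, rho, win in ((example_two, 30.0, dict(t_max=20000.0, nt=4096)),
                          (two_layer, 20.0, {})):
        dtof = td_reflectance(med, rho, **win)
        m0, mt, var = moments(med, rho)
        assert dtof.m0 == pytest.approx(m0, rel=1e-2)
        assert dtof.mean_time == pytest.approx(mt, rel=1e-2)
        assert dtof.variance == pytest.approx(var, rel=1e-2)
        assert var > 0


def test_homogeneous_mean_time_closed_form():
    med = homogeneous(0.01, 1.0, n_layers=2)
    _, mt, var = moments(med, 20.0)
    assert mt == pytest.approx(homogeneous_mean_time(0.01, 1.0, 1.33, 1.0, 20.0),
                               rel=5e-3)
    assert var > 0


def test_single_layer_dispatches_to_dipole():
    med = LayeredMedium([Layer(0.01, 1.0, 1.33, None)])
    assert cw_reflectance(med, 20.0) == pytest.approx(
        homogeneous_cw_reflectance(0.01, 1.0, 1.33, 1.0, 20.0), rel=1e-12)
    m0, mt, var = moments(med, 20.0)
    assert mt == pytest.approx(homogeneous_mean_time(0.01, 1.0, 1.33, 1.0, 20.0),
                               rel=5e-3)
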