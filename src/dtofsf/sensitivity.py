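"""Per-layer analytical sensitivity factors of the DTOF moments.

All three factors follow from mixed derivatives of the CW reflectance R(rho)
with respect to the layer absorption coefficients:

    L_j    = -(1/R) dR/dmu_a_j                       (mean partial pathlength)
    MTSF_j = d<t>/dmu_a_j
           = sum_k (1/c_k) [L_j L_k - (1/R) d2R/dmu_a_j dmu_a_k]
    VSF_j  = dV/dmu_a_j = d<t^2>/dmu_a_j - 2 <t> MTSF_j

with

    d<t^2>/dmu_a_j = sum_{k,l} 1/(c_k c_l R)
                     [d3R/dmu_a_j dmu_a_k dmu_a_l
                      - (1/R) dR/dmu_a_j d2R/dmu_a_k dmu_a_l].

The derivatives are exact: mu_a_j enters the layered Green's function only
through alpha_j, and the whole series evaluation is propagated in forward-
mode jet arithmetic (no finite differencing anywhere in this module).

Mean partial times use each layer's own light speed c_k, so media with
per-layer refractive indices are handled; the identity <t> = sum_k L_k/c_k
ties these factors to the moments of the synthesized DTOF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .forward_model import (SpectralBasis, cw_derivative_jet,
                            _transform_grid)
from .medium import DerivedOptics, LayeredMedium, derive_optics

__all__ = [
    "DerivativeTensor", "SensitivitySet", "cw_derivatives", "mppl",
    "mppl_td", "mtsf", "vsf", "sensitivity_set",
]

UNDERFLOW_MASK_FRACTION = 1e-12  # of DTOF peak, for time-dependent MPPLs


@dataclass(frozen=True)
class DerivativeTensor:
    """Mixed mu_a-derivatives of the CW reflectance at one distance."""

    rho: float
    value: float                       # R(rho) [1/mm^2]
    grad: np.ndarray                   # dR/dmu_a_j, shape (N,)
    hess: Optional[np.ndarray] = None  # (N, N)
    third: Optional[np.ndarray] = None  # (N, N, N)


@dataclass(frozen=True)
class SensitivitySet:
    """Per-layer L, MTSF, VSF at one source-detector distance.

    Units: L in mm, MTSF in ps mm, VSF in ps^2 mm (factors multiply a
    Delta mu_a in 1/mm to give the change of the respective moment).
    """

    rho: float
    L: np.ndarray
    MTSF: np.ndarray
    VSF: np.ndarray


def _split_single(medium: LayeredMedium):
    """Sensitivity path for N = 1: treat as two identical fictitious layers
    (partition invariance guarantees the sum is the physical total)."""
    lay = medium.layers[0]
    return medium.split_layer(0, max(1.0, 3.0 / lay.mu_s_prime))


def cw_derivatives(medium: LayeredMedium, rho: float, order: int = 3,
                   basis: Optional[SpectralBasis] = None,
                   optics: Optional[DerivedOptics] = None) -> DerivativeTensor:
    """Exact mixed partials of R(rho) w.r.t. each layer's mu_a, to ``order``."""
    if medium.n_layers == 1:
        raise ValueError("cw_derivatives needs N >= 2 (split a single layer "
                         "fictitiously to obtain total-pathlength output)")
    jet = cw_derivative_jet(medium, rho, order, basis=basis, optics=optics)
    return DerivativeTensor(
        rho=float(rho), value=float(jet.value), grad=np.asarray(jet.grad),
        hess=None if order < 2 else np.asarray(jet.hess),
        third=None if order < 3 else np.asarray(jet.third))


def mppl(medium: LayeredMedium, rho: float,
         basis: Optional[SpectralBasis] = None,
         optics: Optional[DerivedOptics] = None) -> np.ndarray:
    """Mean partial pathlengths L_j(rho) [mm], one entry per layer."""
    if medium.n_layers == 1:
        split = _split_single(medium)
        return np.array([mppl(split, rho, basis=basis).sum()])
    d = cw_derivatives(medium, rho, order=1, basis=basis, optics=optics)
    return -d.grad / d.value


def mtsf(medium: LayeredMedium, rho: float,
         basis: Optional[SpectralBasis] = None,
         optics: Optional[DerivedOptics] = None) -> np.ndarray:
    """Mean-time sensitivity factors d<t>/dmu_a_j [ps mm]."""
    if medium.n_layers == 1:
        split = _split_single(medium)
        return np.array([mtsf(split, rho, basis=basis).sum()])
    if optics is None:
        optics = derive_optics(medium)
    d = cw_derivatives(medium, rho, order=2, basis=basis, optics=optics)
    L = -d.grad / d.value
    dL = np.outer(L, L) - d.hess / d.value  # dL_k/dmu_a_j at [j, k]
    return dL @ (1.0 / optics.c)


def vsf(medium: LayeredMedium, rho: float,
        basis: Optional[SpectralBasis] = None,
        optics: Optional[DerivedOptics] = None) -> np.ndarray:
    """Variance sensitivity factors dV/dmu_a_j [ps^2 mm]."""
    if medium.n_layers == 1:
        split = _split_single(medium)
        return np.array([vsf(split, rho, basis=basis).sum()])
    return sensitivity_set(medium, rho, basis=basis, optics=optics).VSF


def sensitivity_set(medium: LayeredMedium, rho: float,
                    basis: Optional[SpectralBasis] = None,
                    optics: Optional[DerivedOptics] = None) -> SensitivitySet:
    """All three factors from a single order-3 derivative evaluation."""
    if medium.n_layers == 1:
        s = sensitivity_set(_split_single(medium), rho, basis=basis)
        return SensitivitySet(rho=s.rho, L=np.array([s.L.sum()]),
                              MTSF=np.array([s.MTSF.sum()]),
                              VSF=np.array([s.VSF.sum()]))
    if optics is None:
        optics = derive_optics(medium)
    d = cw_derivatives(medium, rho, order=3, basis=basis, optics=optics)
    R = d.value
    cinv = 1.0 / optics.c
    L = -d.grad / R
    dL = np.outer(L, L) - d.hess / R
    mtsf_v = dL @ cinv
    mean_t = L @ cinv
    # d<t^2>/dmu_a_j = sum_kl (third_jkl - grad_j hess_kl / R) / (c_k c_l R)
    w = np.outer(cinv, cinv)
    dt2 = (np.tensordot(d.third, w, axes=([1, 2], [0, 1]))
           - d.grad * np.sum(d.hess * w) / R) / R
    vsf_v = dt2 - 2.0 * mean_t * mtsf_v
    return SensitivitySet(rho=float(rho), L=L, MTSF=mtsf_v, VSF=vsf_v)


def mppl_td(medium: LayeredMedium, rho: float, t_grid: np.ndarray,
            basis: Optional[SpectralBasis] = None,
            optics: Optional[DerivedOptics] = None,
            chunk_omega: int = 64):
    """Time-dependent mean partial pathlengths L_j(rho, t) [mm].

    Differentiates the frequency synthesis termwise: the gradient of the
    spectrum w.r.t. mu_a is transformed with the same Hermitian-symmetric
    inverse used for the DTOF itself.  Returns ``(L, R_t)`` where ``L`` has
    shape (N, nt), masked (NaN) where the DTOF underflows below 1e-12 of
    its peak, and ``R_t`` is the synthesized reflectance.
    """
    if medium.n_layers == 1:
        medium = _split_single(medium)
        L, R_t = mppl_td(medium, rho, t_grid, basis=basis)
        return L.sum(axis=0, keepdims=True), R_t
    if optics is None:
        optics = derive_optics(medium)
    t_grid = np.asarray(t_grid, dtype=float)
    dt, nt, omega = _transform_grid(t_grid)

    from .forward_model import (_cw_series, _g1_core, _series_coeff,
                                bessel_basis, SERIES_RUN)
    if basis is None:
        basis = bessel_basis(optics.R_EB)
    _, n_used = _cw_series(medium, rho, basis, optics)
    sub = basis.truncated(min(basis.count, n_used + 4 * SERIES_RUN))
    coeff = _series_coeff(sub, rho)
    pref = 1.0 / (2.0 * np.pi * optics.A * sub.R_EB ** 2)

    N = medium.n_layers
    spec = np.empty(len(omega), dtype=complex)
    dspec = np.empty((N, len(omega)), dtype=complex)
    s2 = (sub.s ** 2)[None, :] + 0j
    for lo in range(0, len(omega), chunk_omega):
        om = omega[lo:lo + chunk_omega, None]
        gj = _g1_core(medium, optics, s2, om, order=1)
        spec[lo:lo + chunk_omega] = pref * (coeff * gj.value).sum(axis=-1)
        dspec[:, lo:lo + chunk_omega] = pref * (coeff * gj.grad).sum(axis=-1)

    phase = np.exp(1j * omega * t_grid[0])
    R_t = np.fft.irfft(spec * phase, n=nt) / dt
    dR_t = np.fft.irfft(dspec * phase[None, :], n=nt, axis=-1) / dt
    peak = R_t.max()
    mask = R_t > UNDERFLOW_MASK_FRACTION * peak
    L = np.full((N, nt), np.nan)
    L[:, mask] = -dR_t[:, mask] / R_t[mask]
    return L, R_t
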