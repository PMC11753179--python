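"""Diffuse reflectance of an N-layered turbid cylinder.

The time-domain reflectance at distance rho from a pencil-beam source on the
top face of an N-layer cylinder is expanded, under the diffusion
approximation with extrapolated-boundary conditions, in a finite-cylinder
Fourier-Bessel (Dini) series over the roots s_n of J0(s R_EB) = 0:

    R(rho, t) = 1 / (4 pi^2 A R_EB^2) * sum_n J0(s_n rho) / J1(s_n R_EB)^2
                * integral G1(z=0, omega, s_n) e^{i omega t} d omega

where G1 is the Hankel/frequency-space Green's function of the first layer.
G1 couples the layers through a downward recursion in two auxiliary
amplitudes (beta, gamma); hyperbolic functions are rewritten in factored
exponential form and the recursion is renormalized at every step so that no
argument is ever exponentiated with positive real part (the reflectance is a
ratio that is jointly homogeneous in (beta, gamma), so rescaling both by any
common factor - even a mu_a-dependent one - cancels exactly).

The omega = 0 member of the series is the CW reflectance; all statistical
moments of the DTOF follow from mixed mu_a-derivatives of it, which this
module propagates exactly with the jet arithmetic of :mod:`dtofsf.jets`.

Setting every layer identical collapses the series to the classical
semi-infinite extrapolated-boundary dipole solution, which is also provided
in closed form (and used for single-layer media).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.special import j0, j1, jn_zeros

from .jets import Jet, jet_variable
from .medium import C_VACUUM, DerivedOptics, LayeredMedium, derive_optics

__all__ = [
    "SpectralBasis", "DTOF", "bessel_basis", "alpha", "beta_gamma",
    "green_g1", "cw_reflectance", "td_reflectance", "moments",
    "cw_derivative_jet", "homogeneous_cw_reflectance",
    "homogeneous_mean_time", "ConvergenceError", "WindowError",
]

MAX_BESSEL_ZEROS = 5000
SERIES_RTOL = 1e-10      # relative size below which a term counts as spent
SERIES_RUN = 50          # consecutive spent terms required to stop
SERIES_FAIL_RTOL = 1e-6  # tail still above this at the cap -> error
DEFAULT_T_MAX = 10_000.0  # ps
DEFAULT_NT = 2048


class ConvergenceError(RuntimeError):
    """Bessel series not converged within the configured number of zeros."""


class WindowError(RuntimeError):
    """Time window too short (aliasing) or truncation ringing too large."""


# ---------------------------------------------------------------------------
# Spectral basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralBasis:
    """Eigenvalues s_n = j_{0,n} / R_EB of the cylinder expansion."""

    s: np.ndarray
    R_EB: float

    @property
    def count(self) -> int:
        return len(self.s)

    def truncated(self, count: int) -> "SpectralBasis":
        return SpectralBasis(self.s[:count], self.R_EB)


@lru_cache(maxsize=4)
def _j0_zeros(count: int) -> np.ndarray:
    return jn_zeros(0, count)


def bessel_basis(R_EB: float, count: int = MAX_BESSEL_ZEROS) -> SpectralBasis:
    """First ``count`` positive roots of J0(s R_EB), strictly increasing."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if count > MAX_BESSEL_ZEROS:
        raise ValueError(f"count exceeds configured maximum {MAX_BESSEL_ZEROS}")
    return SpectralBasis(_j0_zeros(count) / R_EB, float(R_EB))


# ---------------------------------------------------------------------------
# Green's function core (generic over plain arrays and jets)
# ---------------------------------------------------------------------------

def _exp(x):
    return x.exp() if isinstance(x, Jet) else np.exp(x)


def _sqrt(x):
    return x.sqrt() if isinstance(x, Jet) else np.sqrt(x)


def _val(x):
    return x.value if isinstance(x, Jet) else x


def _alpha_list(medium, optics, s2, omega, order):
    """Per-layer transverse wavenumbers alpha_j = sqrt(mu_a_j/D_j + s^2 +
    i omega/(D_j c_j)); jets seeded in mu_a_j when order >= 1."""
    N = medium.n_layers
    mu_a = medium.mu_a
    out = []
    for jl in range(N):
        base = mu_a[jl] / optics.D[jl] + s2
        if np.any(omega != 0):
            base = base + 1j * omega / (optics.D[jl] * optics.c[jl])
        if order == 0:
            out.append(np.sqrt(base + 0.0))
        else:
            out.append(jet_variable(np.asarray(base + 0.0), jl, N, order,
                                    scale=1.0 / optics.D[jl]).sqrt())
    return out


def _beta_gamma_core(alphas, medium, optics, track_scale=False):
    """Renormalized downward recursion for (beta_3, gamma_3).

    Returns ``(beta, gamma, log_scale)``: the true amplitudes are
    ``beta * exp(log_scale)`` (log_scale tracked at value level only and
    meaningful only for the non-jet path; the reflectance never needs it).
    """
    N = medium.n_layers
    d = medium.thicknesses
    n2 = medium.n ** 2
    P = [optics.D[jl] * n2[jl] * alphas[jl] for jl in range(N)]

    shape = np.shape(_val(alphas[0]))
    log_scale = np.zeros(shape, dtype=np.asarray(_val(alphas[0])).dtype)
    if N == 2:
        one = 1.0
        return one, one, log_scale

    # seed from the two deepest layers (0-based N-2, N-1), argument
    # alpha_{N-2} d_{N-2}; common factor e^{x} dropped at every level
    x = alphas[N - 2] * d[N - 2]
    em = _exp(-2.0 * x)
    ch, sh = 0.5 * (1.0 + em), 0.5 * (1.0 - em)
    beta = P[N - 2] * ch + P[N - 1] * sh
    gamma = P[N - 2] * sh + P[N - 1] * ch
    if track_scale:
        log_scale = log_scale + _val(x)

    for m in range(N - 3, 0, -1):  # layer pairs (m, m+1), arg alpha_m d_m
        x = alphas[m] * d[m]
        em = _exp(-2.0 * x)
        ch, sh = 0.5 * (1.0 + em), 0.5 * (1.0 - em)
        beta, gamma = (P[m] * (ch * beta) + P[m + 1] * (sh * gamma),
                       P[m] * (sh * beta) + P[m + 1] * (ch * gamma))
        if track_scale:
            log_scale = log_scale + _val(x)
        scale = np.maximum(np.abs(_val(beta)), np.abs(_val(gamma)))
        beta, gamma = beta / scale, gamma / scale
        if track_scale:
            log_scale = log_scale + np.log(scale)
    return beta, gamma, log_scale


def _g1_core(medium, optics, s2, omega, order):
    """G1(z=0) for every (omega, s) in the broadcast of the inputs."""
    N = medium.n_layers
    if N < 2:
        raise ValueError("series Green's function requires N >= 2 layers")
    alphas = _alpha_list(medium, optics, s2, omega, order)
    beta, gamma, _ = _beta_gamma_core(alphas, medium, optics)

    a1 = alphas[0]
    z0, zb = optics.z0, optics.z_b
    d1 = medium.thicknesses[0]
    D1a1 = optics.D[0] * a1
    n2 = medium.n ** 2

    term1 = (_exp(a1 * (-z0)) - _exp(a1 * (-(z0 + 2.0 * zb)))) / (2.0 * D1a1)

    P1 = D1a1 * n2[0]
    P2 = (optics.D[1] * n2[1]) * alphas[1]
    num = P1 * beta - P2 * gamma
    q = _exp(a1 * (-2.0 * (d1 + zb)))
    den = P1 * (beta * (1.0 + q)) + P2 * (gamma * (1.0 - q))
    # sinh(a1(z0+zb)) sinh(a1 zb) / e^{a1(d1+zb)} expanded in decaying
    # exponentials (exponents nonpositive whenever z0 <= 2 d1)
    S = (_exp(a1 * (z0 - 2.0 * d1))
         - _exp(a1 * (z0 - 2.0 * d1 - 2.0 * zb))
         - _exp(a1 * (-z0 - 2.0 * d1 - 2.0 * zb))
         + _exp(a1 * (-z0 - 2.0 * d1 - 4.0 * zb)))
    g = term1 + (S * num) / ((2.0 * D1a1) * den)
    return g


# -- scalar convenience wrappers -----------------------------------------------

def alpha(layer_index: int, medium: LayeredMedium, s_n: float,
          omega: float = 0.0, optics: Optional[DerivedOptics] = None):
    """Wavenumber alpha_j = sqrt(mu_a_j/D_j + s_n^2 + i omega/(D_j c_j))."""
    if not 0 <= layer_index < medium.n_layers:
        raise IndexError("layer_index out of range")
    if optics is None:
        optics = derive_optics(medium)
    jl = layer_index
    val = medium.mu_a[jl] / optics.D[jl] + np.asarray(s_n) ** 2
    if np.any(np.asarray(omega) != 0):
        val = val + 1j * np.asarray(omega) / (optics.D[jl] * optics.c[jl])
    return np.sqrt(val + 0.0)


def beta_gamma(medium: LayeredMedium, s_n, omega: float = 0.0,
               optics: Optional[DerivedOptics] = None):
    """Renormalized recursion amplitudes ``(beta_3, gamma_3, log_scale)``.

    The unrenormalized amplitudes of the textbook recursion are
    ``beta_3 * exp(log_scale)`` and ``gamma_3 * exp(log_scale)``.  For
    two-layer media the convention (1, 1, 0) is returned, under which the
    Green's function reduces to the standard two-layer solution.
    """
    if medium.n_layers < 2:
        raise ValueError("beta/gamma recursion requires N >= 2")
    if optics is None:
        optics = derive_optics(medium)
    s2 = np.asarray(s_n, dtype=float) ** 2
    if np.any(np.asarray(omega) != 0):
        s2 = s2 + 0j
    alphas = _alpha_list(medium, optics, s2, omega, order=0)
    b, g, ls = _beta_gamma_core(alphas, medium, optics, track_scale=True)
    if not (np.all(np.isfinite(_val(b))) and np.all(np.isfinite(_val(g)))):
        raise OverflowError("beta/gamma recursion overflowed")
    return b, g, ls


def green_g1(medium: LayeredMedium, s_n, omega: float = 0.0,
             optics: Optional[DerivedOptics] = None):
    """G1(z=0, omega, s_n) of the layered cylinder (N >= 2)."""
    if optics is None:
        optics = derive_optics(medium)
    s2 = np.asarray(s_n, dtype=float) ** 2
    om = np.asarray(omega)
    if np.any(om != 0):
        s2 = s2 + 0j
    g = _g1_core(medium, optics, s2, om, order=0)
    if not np.all(np.isfinite(g)):
        raise OverflowError("Green's function evaluation overflowed")
    return g


# ---------------------------------------------------------------------------
# Series summation
# ---------------------------------------------------------------------------

def _series_coeff(basis: SpectralBasis, rho: float) -> np.ndarray:
    return j0(basis.s * rho) / j1(basis.s * basis.R_EB) ** 2


def _adaptive_count(terms: np.ndarray, total: complex) -> int:
    """Index after which SERIES_RUN consecutive terms are below SERIES_RTOL
    of the final sum; raises if the tail never settles."""
    mag = np.abs(terms)
    thresh = SERIES_RTOL * max(abs(total), mag.max() * SERIES_RTOL)
    alive = np.nonzero(mag >= thresh)[0]
    n_used = 0 if len(alive) == 0 else int(alive[-1]) + 1
    if n_used > len(terms) - SERIES_RUN:
        tail = mag[-SERIES_RUN:].max() / max(abs(total), 1e-300)
        if tail > SERIES_FAIL_RTOL:
            raise ConvergenceError(
                f"series tail still contributing {tail:.2e} relative "
                f"after {len(terms)} zeros")
        n_used = len(terms)
    return n_used


def _cw_series(medium: LayeredMedium, rho: float, basis: SpectralBasis,
               optics: DerivedOptics):
    """CW reflectance and the adaptively determined series length."""
    coeff = _series_coeff(basis, rho)
    g = _g1_core(medium, optics, basis.s ** 2, 0.0, order=0)
    terms = coeff * g
    total = terms.sum()
    n_used = _adaptive_count(terms, total)
    pref = 1.0 / (2.0 * np.pi * optics.A * basis.R_EB ** 2)
    return pref * total, n_used


def cw_reflectance(medium: LayeredMedium, rho: float,
                   basis: Optional[SpectralBasis] = None,
                   optics: Optional[DerivedOptics] = None) -> float:
    """Time-integrated (CW) diffuse reflectance R(rho) [1/mm^2]."""
    if medium.n_layers == 1:
        lay = medium.layers[0]
        return homogeneous_cw_reflectance(lay.mu_a, lay.mu_s_prime, lay.n,
                                          medium.n_external, rho)
    if optics is None:
        optics = derive_optics(medium)
    if not 0 <= rho < medium.radius:
        raise ValueError("rho must satisfy 0 <= rho < radius")
    if basis is None:
        basis = bessel_basis(optics.R_EB)
    val, _ = _cw_series(medium, rho, basis, optics)
    return float(val)


def cw_derivative_jet(medium: LayeredMedium, rho: float, order: int,
                      basis: Optional[SpectralBasis] = None,
                      optics: Optional[DerivedOptics] = None,
                      chunk: int = 512) -> Jet:
    """CW reflectance as a jet: value plus exact mixed mu_a-derivatives up
    to ``order`` (<= 3).  The series length is fixed by a scalar prepass."""
    if not 1 <= order <= 3:
        raise ValueError("order must be 1, 2 or 3")
    if optics is None:
        optics = derive_optics(medium)
    if basis is None:
        basis = bessel_basis(optics.R_EB)
    _, n_used = _cw_series(medium, rho, basis, optics)
    # derivatives weight the series towards low s the same way the value
    # does; a fixed safety margin covers the difference
    n_keep = min(basis.count, n_used + 4 * SERIES_RUN)
    sub = basis.truncated(n_keep)
    coeff = _series_coeff(sub, rho)

    N = medium.n_layers
    acc = None
    for lo in range(0, n_keep, chunk):
        hi = min(lo + chunk, n_keep)
        gj = _g1_core(medium, optics, sub.s[lo:hi] ** 2, 0.0, order)
        red = gj.sum_weighted(coeff[lo:hi])
        acc = red if acc is None else acc + red
    pref = 1.0 / (2.0 * np.pi * optics.A * sub.R_EB ** 2)
    out = acc * pref
    if not np.all([np.all(np.isfinite(c)) for c in out.c]):
        raise OverflowError("derivative series overflowed")
    return out


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DTOF:
    """Sampled distribution of times of flight at one source-detector
    distance, with its first statistical moments (trapezoid-integrated)."""

    rho: float
    t: np.ndarray          # ps, uniform
    values: np.ndarray     # 1/(mm^2 ps), nonnegative

    @property
    def m0(self) -> float:
        """Zeroth moment = CW reflectance [1/mm^2]."""
        return float(np.trapezoid(self.values, self.t))

    @property
    def mean_time(self) -> float:
        return float(np.trapezoid(self.t * self.values, self.t) / self.m0)

    @property
    def variance(self) -> float:
        t2 = np.trapezoid(self.t ** 2 * self.values, self.t) / self.m0
        return float(t2 - self.mean_time ** 2)


def _transform_grid(t_grid: np.ndarray):
    dt = t_grid[1] - t_grid[0]
    if not np.allclose(np.diff(t_grid), dt, rtol=1e-9):
        raise ValueError("t_grid must be uniform")
    nt = len(t_grid)
    omega = 2.0 * np.pi * np.fft.rfftfreq(nt, d=dt)
    return dt, nt, omega


def transform_spectrum(medium: LayeredMedium, rho: float, omega: np.ndarray,
                       basis: Optional[SpectralBasis] = None,
                       optics: Optional[DerivedOptics] = None,
                       chunk_omega: int = 128) -> np.ndarray:
    """Frequency response R-hat(rho, omega) of the reflectance (the CW value
    at omega = 0); Hermitian in omega."""
    if optics is None:
        optics = derive_optics(medium)
    if basis is None:
        basis = bessel_basis(optics.R_EB)
    _, n_used = _cw_series(medium, rho, basis, optics)
    sub = basis.truncated(min(basis.count, n_used + 4 * SERIES_RUN))
    coeff = _series_coeff(sub, rho)
    pref = 1.0 / (2.0 * np.pi * optics.A * sub.R_EB ** 2)

    omega = np.asarray(omega, dtype=float)
    out = np.empty(omega.shape, dtype=complex)
    s2 = (sub.s ** 2)[None, :] + 0j
    for lo in range(0, len(omega), chunk_omega):
        om = omega[lo:lo + chunk_omega, None]
        g = _g1_core(medium, optics, s2, om, order=0)
        out[lo:lo + chunk_omega] = pref * (coeff[None, :] * g).sum(axis=1)
    return out


def td_reflectance(medium: LayeredMedium, rho: float,
                   t_grid: Optional[np.ndarray] = None,
                   basis: Optional[SpectralBasis] = None,
                   t_max: float = DEFAULT_T_MAX, nt: int = DEFAULT_NT,
                   ringing_tol: float = 1e-3,
                   alias_tol: float = 1e-3) -> DTOF:
    """Time-resolved reflectance R(rho, t) via Hermitian-symmetric synthesis
    of the frequency response on a uniform grid (default 10 ns, 2048
    samples).  Small negative truncation ringing is clipped to zero; larger
    ringing or non-negligible amplitude at the end of the window raises
    :class:`WindowError`."""
    if t_grid is None:
        t_grid = np.arange(nt) * (t_max / nt)
    t_grid = np.asarray(t_grid, dtype=float)
    dt, nt, omega = _transform_grid(t_grid)
    spec = transform_spectrum(medium, rho, omega, basis=basis)
    # shift so sample k of the inverse transform lands on t_grid[k]
    spec = spec * np.exp(1j * omega * t_grid[0])
    vals = np.fft.irfft(spec, n=nt) / dt
    peak = vals.max()
    if peak <= 0:
        raise WindowError("synthesized DTOF has no positive support")
    if vals.min() < -ringing_tol * peak:
        raise WindowError(
            f"negative ringing {vals.min() / peak:.2e} of peak; widen the "
            "time window or increase nt")
    if abs(vals[-1]) > alias_tol * peak:
        raise WindowError("non-negligible amplitude at the last time sample "
                          "(aliasing); enlarge t_max")
    return DTOF(rho=float(rho), t=t_grid, values=np.clip(vals, 0.0, None))


def moments(medium: LayeredMedium, rho: float,
            basis: Optional[SpectralBasis] = None,
            optics: Optional[DerivedOptics] = None):
    """Analytical DTOF moments ``(m0, mean_time, variance)`` from CW
    mu_a-derivatives: <t> = sum_k L_k / c_k and
    <t_k t_l> = (1/(c_k c_l R)) d^2R / dmu_a_k dmu_a_l."""
    if medium.n_layers == 1:
        lay = medium.layers[0]
        medium = medium.split_layer(0, max(1.0, 3.0 / lay.mu_s_prime))
    if optics is None:
        optics = derive_optics(medium)
    jet = cw_derivative_jet(medium, rho, order=2, basis=basis, optics=optics)
    R = jet.value
    L = -jet.grad / R
    mean_t = float(np.sum(L / optics.c))
    t2 = float(np.sum(jet.hess / np.outer(optics.c, optics.c)) / R)
    return float(R), mean_t, t2 - mean_t ** 2


# ---------------------------------------------------------------------------
# Homogeneous (semi-infinite) closed form
# ---------------------------------------------------------------------------

def _dipole_terms(mu_a, mu_s_prime, n, n_ext, rho, A=None):
    from .medium import boundary_factor_A
    D = 1.0 / (3.0 * mu_s_prime)
    if A is None:
        A = boundary_factor_A(n, n_ext)
    z0 = 1.0 / mu_s_prime
    zb = 2.0 * A * D
    mu_eff = np.sqrt(mu_a / D)
    r1 = np.sqrt(rho ** 2 + z0 ** 2)
    r2 = np.sqrt(rho ** 2 + (z0 + 2.0 * zb) ** 2)
    return D, A, mu_eff, r1, r2


def homogeneous_cw_reflectance(mu_a, mu_s_prime, n=1.33, n_ext=1.0, rho=30.0,
                               A=None):
    """Closed-form semi-infinite CW reflectance: surface fluence of the
    extrapolated-boundary dipole divided by 2A (the same convention the
    layered series uses)."""
    D, A, mu_eff, r1, r2 = _dipole_terms(mu_a, mu_s_prime, n, n_ext, rho, A)
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4 * np.pi * D)
    return phi / (2.0 * A)


def homogeneous_mean_time(mu_a, mu_s_prime, n=1.33, n_ext=1.0, rho=30.0,
                          A=None):
    """Closed-form mean time of flight of the semi-infinite dipole DTOF:
    <t> = -(1/c) d ln R / d mu_a."""
    D, A, mu_eff, r1, r2 = _dipole_terms(mu_a, mu_s_prime, n, n_ext, rho, A)
    c = C_VACUUM / n
    e1, e2 = np.exp(-mu_eff * r1), np.exp(-mu_eff * r2)
    dmu_eff = 1.0 / (2.0 * D * mu_eff)
    return dmu_eff * (e1 - e2) / (e1 / r1 - e2 / r2) / c
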