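"""Forward-mode truncated Taylor (jet) arithmetic up to third order.

A :class:`Jet` carries the value of a function of ``nvars`` scalar parameters
together with its gradient, Hessian and third-derivative tensor, all
vectorized over a trailing axis of arbitrary shape (here: the Bessel-series
index, or a frequency x series grid).  Propagating jets through an analytic
computation yields exact (machine-precision) mixed partial derivatives,
without symbolic work and without finite-difference truncation error.

Only the operations needed by the layered diffuse-reflectance Green's
function are provided: +, -, *, /, sqrt, exp, and scaling by constants.
Derivative tensors are stored dense and unsymmetrized (``hess[j, k]`` is the
true mixed partial, symmetric by construction).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Jet", "jet_variable", "jet_constant"]


class Jet:
    """Truncated Taylor expansion of order ``order`` in ``nvars`` variables.

    Parameters
    ----------
    coeffs
        Sequence ``[value, grad, hess, third][: order + 1]`` where ``value``
        has shape ``S`` (the vector axis), ``grad`` has ``(nvars,) + S``,
        ``hess`` ``(nvars, nvars) + S`` and ``third`` ``(nvars,)*3 + S``.
    """

    __slots__ = ("c",)

    def __init__(self, coeffs):
        self.c = list(coeffs)

    @property
    def order(self) -> int:
        return len(self.c) - 1

    @property
    def nvars(self) -> int:
        return self.c[1].shape[0] if self.order >= 1 else 0

    @property
    def value(self):
        return self.c[0]

    @property
    def grad(self):
        return self.c[1]

    @property
    def hess(self):
        return self.c[2]

    @property
    def third(self):
        return self.c[3]

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, Jet):
            return Jet([a + b for a, b in zip(self.c, other.c)])
        out = [np.asarray(self.c[0] + other)] + [a.copy() for a in self.c[1:]]
        return Jet(out)

    __radd__ = __add__

    def __neg__(self):
        return Jet([-a for a in self.c])

    def __sub__(self, other):
        if isinstance(other, Jet):
            return Jet([a - b for a, b in zip(self.c, other.c)])
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Jet):
            return Jet([a * other for a in self.c])
        a, b = self.c, other.c
        k = len(a) - 1
        out = [a[0] * b[0]]
        if k >= 1:
            out.append(a[0] * b[1] + b[0] * a[1])
        if k >= 2:
            h = a[0] * b[2] + b[0] * a[2]
            h = h + a[1][:, None] * b[1][None, :] + b[1][:, None] * a[1][None, :]
            out.append(h)
        if k >= 3:
            t = a[0] * b[3] + b[0] * a[3]
            t = t + _sym_gh(a[1], b[2]) + _sym_gh(b[1], a[2])
            out.append(t)
        return Jet(out)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Jet):
            return self * (1.0 / other)
        return _div(self, other)

    def __rtruediv__(self, other):
        return _div(jet_constant(other, self.nvars, self.order,
                                 like=self.c[0]), self)

    def sqrt(self):
        a = self.c
        k = len(a) - 1
        v = np.sqrt(a[0])
        out = [v]
        if k >= 1:
            g = a[1] / (2.0 * v)
            out.append(g)
        if k >= 2:
            h = (a[2] - 2.0 * g[:, None] * g[None, :]) / (2.0 * v)
            out.append(h)
        if k >= 3:
            t = (a[3] - 2.0 * _sym_gh(g, h)) / (2.0 * v)
            out.append(t)
        return Jet(out)

    def exp(self):
        a = self.c
        k = len(a) - 1
        v = np.exp(a[0])
        out = [v]
        if k >= 1:
            out.append(v * a[1])
        if k >= 2:
            gg = a[1][:, None] * a[1][None, :]
            out.append(v * (a[2] + gg))
        if k >= 3:
            ggg = a[1][:, None, None] * a[1][None, :, None] * a[1][None, None, :]
            out.append(v * (a[3] + _sym_gh(a[1], a[2]) + ggg))
        return Jet(out)

    def conj(self):
        return Jet([np.conj(a) for a in self.c])

    def sum_weighted(self, w, axis=-1):
        """Reduce the vector axis: ``sum(w * coeff, axis)`` per coefficient."""
        return Jet([np.sum(w * a, axis=axis) for a in self.c])


def _sym_gh(g, h):
    """Symmetrized grad (x) hess contribution to a third-order coefficient:
    ``g_j h_kl + g_k h_jl + g_l h_jk``."""
    return (g[:, None, None] * h[None, :, :]
            + g[None, :, None] * h[:, None, :]
            + g[None, None, :] * h[:, :, None])


def _div(a: Jet, b: Jet) -> Jet:
    """Forward substitution for c = a / b (solve c * b = a order by order)."""
    k = a.order
    inv = 1.0 / b.c[0]
    out = [a.c[0] * inv]
    if k >= 1:
        out.append((a.c[1] - out[0] * b.c[1]) * inv)
    if k >= 2:
        h = a.c[2] - out[0] * b.c[2]
        h = h - out[1][:, None] * b.c[1][None, :] - out[1][None, :] * b.c[1][:, None]
        out.append(h * inv)
    if k >= 3:
        t = a.c[3] - out[0] * b.c[3]
        t = t - _sym_gh(out[1], b.c[2])
        t = (t - out[2][:, :, None] * b.c[1][None, None, :]
             - out[2][:, None, :] * b.c[1][None, :, None]
             - out[2][None, :, :] * b.c[1][:, None, None])
        out.append(t * inv)
    return Jet(out)


def jet_variable(value, index: int, nvars: int, order: int, scale=1.0):
    """Jet for ``value + scale * x_index`` (seed of one independent variable).

    ``value`` may be any array (the vector axis); ``scale`` is the constant
    d(value)/d(x_index), e.g. 1/D_j when seeding mu_a/D through alpha^2.
    """
    v = np.asarray(value)
    coeffs = [v]
    if order >= 1:
        g = np.zeros((nvars,) + v.shape, dtype=v.dtype)
        g[index] = scale
        coeffs.append(g)
    for k in range(2, order + 1):
        coeffs.append(np.zeros((nvars,) * k + v.shape, dtype=v.dtype))
    return Jet(coeffs)


def jet_constant(value, nvars: int, order: int, like=None):
    """Jet with all derivatives zero."""
    v = np.asarray(value, dtype=None if like is None else np.asarray(like).dtype)
    coeffs = [v]
    for k in range(1, order + 1):
        coeffs.append(np.zeros((nvars,) * k + v.shape, dtype=v.dtype))
    return Jet(coeffs)
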