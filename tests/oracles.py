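"""Independent high-precision and closed-form oracles used by the tests.

Everything here is deliberately written without reusing the package's
evaluation code paths: mpmath arbitrary-precision arithmetic with the
textbook (unrenormalized) hyperbolic recursion, and plain-text formulas.
"""

import mpmath as mp
import numpy as np

from dtofsf.medium import derive_optics

C_VACUUM = "0.299792458"


def mp_green_g1(medium, s, omega=0.0, dps=50):
    """Direct arbitrary-precision evaluation of the layered Green's function
    G1(z=0, omega, s), including the unrenormalized beta/gamma recursion.
    Returns (beta_3, gamma_3, G1) as Python complex."""
    mp.mp.dps = dps
    N = medium.n_layers
    D = [mp.mpf(1) / (3 * mp.mpf(str(l.mu_s_prime))) for l in medium.layers]
    c = [mp.mpf(C_VACUUM) / mp.mpf(str(l.n)) for l in medium.layers]
    al = [mp.sqrt(mp.mpf(str(l.mu_a)) / D[j] + mp.mpf(str(s)) ** 2
                  + mp.mpc(0, omega) / (D[j] * c[j]))
          for j, l in enumerate(medium.layers)]
    n2 = [mp.mpf(str(l.n)) ** 2 for l in medium.layers]
    dd = [mp.mpf(str(l.thickness)) for l in medium.layers[:-1]]
    P = [D[j] * al[j] * n2[j] for j in range(N)]

    if N == 2:
        b = g = mp.mpf(1)
    else:
        x = al[N - 2] * dd[N - 2]
        b = P[N - 2] * mp.cosh(x) + P[N - 1] * mp.sinh(x)
        g = P[N - 2] * mp.sinh(x) + P[N - 1] * mp.cosh(x)
        for m in range(N - 3, 0, -1):
            x = al[m] * dd[m]
            b, g = (P[m] * mp.cosh(x) * b + P[m + 1] * mp.sinh(x) * g,
                    P[m] * mp.sinh(x) * b + P[m + 1] * mp.cosh(x) * g)

    opt = derive_optics(medium)
    z0 = mp.mpf(1) / mp.mpf(str(medium.layers[0].mu_s_prime))
    zb = 2 * mp.mpf(str(opt.A)) * D[0]
    a1 = al[0]
    term1 = (mp.e ** (-a1 * z0) - mp.e ** (-a1 * (z0 + 2 * zb))) / (2 * D[0] * a1)
    num = P[0] * b - P[1] * g
    den = (P[0] * b * mp.cosh(a1 * (dd[0] + zb))
           + P[1] * g * mp.sinh(a1 * (dd[0] + zb)))
    G = term1 + (mp.sinh(a1 * (z0 + zb)) * mp.sinh(a1 * zb)
                 / (D[0] * a1 * mp.e ** (a1 * (dd[0] + zb)))) * num / den
    return complex(b), complex(g), complex(G)


def j0_zero_mcmahon(n):
    """McMahon asymptotic expansion for the n'th positive zero of J0."""
    beta = (n - 0.25) * np.pi
    return (beta + 1.0 / (8 * beta) - 124.0 / (3 * (8 * beta) ** 3)
            + 120928.0 / (15 * (8 * beta) ** 5))
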