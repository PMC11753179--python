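"""Layered-medium description and derived diffusion-theory constants.

Units throughout the package: lengths in mm, times in ps, absorption and
reduced scattering coefficients in 1/mm.  The speed of light in vacuum is
0.299792458 mm/ps, so DTOF widths come out in the convenient O(10^2-10^3 ps)
range typical of time-domain NIRS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import quad

C_VACUUM = 0.299792458  # mm/ps

__all__ = [
    "C_VACUUM", "Layer", "LayeredMedium", "DerivedOptics",
    "boundary_factor_A", "derive_optics", "load_medium", "save_medium",
]


class ValidationError(ValueError):
    """Raised for non-physical medium parameters."""


@dataclass(frozen=True)
class Layer:
    """One layer: absorption mu_a [1/mm], reduced scattering mu_s' [1/mm],
    refractive index n, thickness d [mm] (None = semi-infinite last layer)."""

    mu_a: float
    mu_s_prime: float
    n: float = 1.33
    thickness: Optional[float] = None

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValidationError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValidationError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if self.n < 1:
            raise ValidationError(f"refractive index must be >= 1, got {self.n}")
        if self.thickness is not None and self.thickness <= 0:
            raise ValidationError(f"thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class LayeredMedium:
    """An N-layer turbid cylinder; the first layer is the illuminated one.

    ``radius`` is the physical cylinder radius R [mm] used for the
    finite-cylinder Bessel expansion (default 250 mm, large enough that the
    lateral boundary is invisible at source-detector distances <= 50 mm).
    """

    layers: tuple
    radius: float = 250.0
    n_external: float = 1.0

    def __init__(self, layers: Sequence[Layer], radius: float = 250.0,
                 n_external: float = 1.0):
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "radius", float(radius))
        object.__setattr__(self, "n_external", float(n_external))
        if len(self.layers) < 1:
            raise ValidationError("need at least one layer")
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.n_external < 1:
            raise ValidationError("n_external must be >= 1")
        for j, lay in enumerate(self.layers[:-1]):
            if lay.thickness is None:
                raise ValidationError(
                    f"layer {j} is not last and must have finite thickness")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def mu_a(self) -> np.ndarray:
        return np.array([l.mu_a for l in self.layers])

    @property
    def mu_s_prime(self) -> np.ndarray:
        return np.array([l.mu_s_prime for l in self.layers])

    @property
    def n(self) -> np.ndarray:
        return np.array([l.n for l in self.layers])

    @property
    def thicknesses(self) -> np.ndarray:
        """Finite thicknesses d_1..d_{N-1} [mm]."""
        return np.array([l.thickness for l in self.layers[:-1]], dtype=float)

    def with_mu_a(self, mu_a: Sequence[float]) -> "LayeredMedium":
        """Copy of the medium with replaced per-layer absorption."""
        mu_a = np.asarray(mu_a, dtype=float)
        if mu_a.shape != (self.n_layers,):
            raise ValidationError("mu_a vector length must equal layer count")
        new = [Layer(a, l.mu_s_prime, l.n, l.thickness)
               for a, l in zip(mu_a, self.layers)]
        return LayeredMedium(new, self.radius, self.n_external)

    def split_layer(self, index: int, depth: float) -> "LayeredMedium":
        """Split layer ``index`` into two sublayers with identical optical
        properties; ``depth`` is the thickness of the upper sublayer.  Used
        by partition-invariance checks and by the N=1 sensitivity path."""
        lay = self.layers[index]
        if lay.thickness is not None and not (0 < depth < lay.thickness):
            raise ValidationError("split depth must lie inside the layer")
        upper = Layer(lay.mu_a, lay.mu_s_prime, lay.n, depth)
        rest = None if lay.thickness is None else lay.thickness - depth
        lower = Layer(lay.mu_a, lay.mu_s_prime, lay.n, rest)
        new = self.layers[:index] + (upper, lower) + self.layers[index + 1:]
        return LayeredMedium(new, self.radius, self.n_external)


@dataclass(frozen=True)
class DerivedOptics:
    """Auxiliary diffusion-theory constants for a medium."""

    D: np.ndarray          # per-layer diffusion coefficient [mm]
    c: np.ndarray          # per-layer light speed [mm/ps]
    z0: float              # isotropization depth 1/mu_s'_1 [mm]
    z_b: float             # extrapolation length 2*A*D_1 [mm]
    A: float               # refractive-index-mismatch boundary factor
    R_EB: float            # extrapolated cylinder radius [mm]


def _fresnel_unpolarized(cos_i: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for light hitting the boundary from
    inside (relative index n_rel = n_in/n_out >= 1), as a function of the
    cosine of the internal incidence angle.  Total internal reflection
    beyond the critical angle."""
    cos_i = np.asarray(cos_i, dtype=float)
    sin_i2 = 1.0 - cos_i ** 2
    sin_t2 = n_rel ** 2 * sin_i2
    r = np.ones_like(cos_i)
    ok = sin_t2 < 1.0
    cos_t = np.sqrt(1.0 - sin_t2[ok])
    ci = cos_i[ok]
    rs = (n_rel * ci - cos_t) / (n_rel * ci + cos_t)
    rp = (n_rel * cos_t - ci) / (n_rel * cos_t + ci)
    r[ok] = 0.5 * (rs ** 2 + rp ** 2)
    return r


def boundary_factor_A(n_in: float, n_out: float = 1.0) -> float:
    """Boundary mismatch factor A from the angular Fresnel-reflectance
    moments (effective-reflection-coefficient form):

        R_phi = int_0^{pi/2} 2 sin(t) cos(t)   R_F(t) dt
        R_j   = int_0^{pi/2} 3 sin(t) cos^2(t) R_F(t) dt
        R_eff = (R_phi + R_j) / (2 - R_phi + R_j),  A = (1+R_eff)/(1-R_eff)

    A = 1 for matched indices.  n_in < n_out is accepted (R_F without TIR).
    """
    n_rel = n_in / n_out
    if abs(n_rel - 1.0) < 1e-12:
        return 1.0

    def rf(theta):
        cos_i = np.cos(theta)
        if n_rel >= 1.0:
            return float(_fresnel_unpolarized(np.array([cos_i]), n_rel)[0])
        # from optically rarer side: no TIR; use Snell directly
        sin_t = n_rel * np.sin(theta)
        cos_t = np.sqrt(1.0 - sin_t ** 2)
        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
        rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
        return 0.5 * (rs ** 2 + rp ** 2)

    r_phi, _ = quad(lambda t: 2.0 * np.sin(t) * np.cos(t) * rf(t), 0, np.pi / 2,
                    limit=200)
    r_jay, _ = quad(lambda t: 3.0 * np.sin(t) * np.cos(t) ** 2 * rf(t), 0,
                    np.pi / 2, limit=200)
    r_eff = (r_phi + r_jay) / (2.0 - r_phi + r_jay)
    return (1.0 + r_eff) / (1.0 - r_eff)


def derive_optics(medium: LayeredMedium, A: Optional[float] = None) -> DerivedOptics:
    """Diffusion coefficients, layer light speeds, extrapolation length and
    extended radius for ``medium``.  ``A`` overrides the computed boundary
    factor when supplied (e.g. to match another code's convention)."""
    musp = medium.mu_s_prime
    D = 1.0 / (3.0 * musp)
    c = C_VACUUM / medium.n
    z0 = 1.0 / musp[0]
    if A is None:
        A = boundary_factor_A(medium.layers[0].n, medium.n_external)
    z_b = 2.0 * A * D[0]
    return DerivedOptics(D=D, c=c, z0=z0, z_b=z_b, A=float(A),
                         R_EB=medium.radius + z_b)


# -- structured-text I/O ----------------------------------------------------

def load_medium(path) -> LayeredMedium:
    """Read a medium description from YAML/JSON.

    Schema: ``layers: [{mu_a, mu_sp, n, d}, ...]`` (last layer omits ``d``),
    ``radius_mm``, ``n_external``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    layers = [Layer(mu_a=float(l["mu_a"]), mu_s_prime=float(l["mu_sp"]),
                    n=float(l.get("n", 1.33)),
                    thickness=None if l.get("d") is None else float(l["d"]))
              for l in doc["layers"]]
    return LayeredMedium(layers, radius=float(doc.get("radius_mm", 250.0)),
                         n_external=float(doc.get("n_external", 1.0)))


def save_medium(medium: LayeredMedium, path) -> None:
    doc = {
        "layers": [
            {"mu_a": float(l.mu_a), "mu_sp": float(l.mu_s_prime),
             "n": float(l.n),
             **({} if l.thickness is None else {"d": float(l.thickness)})}
            for l in medium.layers
        ],
        "radius_mm": medium.radius,
        "n_external": medium.n_external,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
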