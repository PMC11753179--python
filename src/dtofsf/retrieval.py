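"""Layer-resolved absorption-change retrieval from DTOF moment changes.

With two (or more) source-detector distances and the per-layer sensitivity
factors held at baseline optical properties, small absorption changes in a
chosen subset of layers follow from the linear model

    [ dM(rho_1) ]   [ SF_U(rho_1)  SF_L(rho_1) ] [ dmu_a_U ]
    [ dM(rho_2) ] = [ SF_U(rho_2)  SF_L(rho_2) ] [ dmu_a_L ]

where dM is the attenuation change dA = -ln(R/R_b) (natural log, so that
dA = L . dmu_a with no ln 10 factor), the mean-time change d<t>, or the
variance change dV, and SF is the matching factor (L, MTSF or VSF).  Square
systems are solved by direct inversion behind a conditioning guard; tall
systems by ordinary least squares.  Layers not declared as changing are
deliberately absent from the matrix - their contribution becomes model
error, as in a two-distance scalp/cortex separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward_model import DTOF
from .medium import LayeredMedium
from .sensitivity import sensitivity_set

__all__ = [
    "MomentChangeSeries", "RetrievalProblem", "attenuation_change",
    "moment_changes", "build_sf_matrix", "retrieve_dmua",
    "CONDITION_THRESHOLD",
]

CONDITION_THRESHOLD = 1e8
MOMENT_TYPES = ("attenuation", "mean_time", "variance")


@dataclass
class MomentChangeSeries:
    """Per-frame, per-distance moment changes; arrays shaped (frames, K)."""

    distances: np.ndarray
    dA: np.ndarray
    dt: np.ndarray
    dV: np.ndarray

    def moment(self, which: str) -> np.ndarray:
        if which == "attenuation":
            return self.dA
        if which == "mean_time":
            return self.dt
        if which == "variance":
            return self.dV
        raise ValueError(f"unknown moment type {which!r}")


@dataclass
class RetrievalProblem:
    """Sensitivity matrix for chosen (distances x changing layers)."""

    distances: np.ndarray
    layer_indices: tuple
    moment: str
    matrix: np.ndarray         # (K, P)
    condition_number: float
    ill_conditioned: bool


def attenuation_change(R, R_baseline):
    """dA = -ln(R / R_b); natural logarithm."""
    R = np.asarray(R, dtype=float)
    Rb = np.asarray(R_baseline, dtype=float)
    if np.any(R <= 0) or np.any(Rb <= 0):
        raise ValueError("reflectance values must be positive")
    return -np.log(R / Rb)


def moment_changes(dtof: DTOF, dtof_baseline: DTOF):
    """Baseline-referenced changes (dA, d<t>, dV) of two sampled DTOFs."""
    if dtof.rho != dtof_baseline.rho or not np.array_equal(
            dtof.t, dtof_baseline.t):
        raise ValueError("DTOFs must share rho and time grid")
    dA = float(attenuation_change(dtof.m0, dtof_baseline.m0))
    return (dA, dtof.mean_time - dtof_baseline.mean_time,
            dtof.variance - dtof_baseline.variance)


def build_sf_matrix(medium: LayeredMedium, distances: Sequence[float],
                    layers: Sequence[int], moment: str) -> RetrievalProblem:
    """Sensitivity matrix at baseline optical properties.

    Rows follow ``distances``, columns the (0-based) ``layers``.  The
    attenuation rows carry +L (so that dA = L . dmu_a); mean-time and
    variance rows carry the signed MTSF / VSF.
    """
    if moment not in MOMENT_TYPES:
        raise ValueError(f"moment must be one of {MOMENT_TYPES}")
    distances = np.asarray(distances, dtype=float)
    layers = tuple(int(j) for j in layers)
    if len(distances) < len(layers):
        raise ValueError("need at least as many distances as layers")
    rows = []
    for rho in distances:
        s = sensitivity_set(medium, rho)
        full = {"attenuation": s.L, "mean_time": s.MTSF, "variance": s.VSF}
        rows.append(full[moment][list(layers)])
    mat = np.asarray(rows)
    cond = float(np.linalg.cond(mat))
    return RetrievalProblem(distances=distances, layer_indices=layers,
                            moment=moment, matrix=mat,
                            condition_number=cond,
                            ill_conditioned=not np.isfinite(cond)
                            or cond > CONDITION_THRESHOLD)


def retrieve_dmua(problem: RetrievalProblem,
                  changes: MomentChangeSeries) -> np.ndarray:
    """Per-frame retrieved absorption changes, shape (frames, P).

    Square systems are inverted exactly; a singular or ill-conditioned
    square matrix raises instead of falling back to a pseudo-inverse.
    Tall systems use ordinary least squares.
    """
    dm = np.atleast_2d(changes.moment(problem.moment))
    mat = problem.matrix
    k, p = mat.shape
    if dm.shape[1] != k:
        raise ValueError("changes and matrix disagree on distance count")
    if k == p:
        if problem.ill_conditioned:
            raise np.linalg.LinAlgError(
                f"sensitivity matrix condition number "
                f"{problem.condition_number:.3g} exceeds "
                f"{CONDITION_THRESHOLD:.0e}")
        return np.linalg.solve(mat, dm.T).T
    sol, *_ = np.linalg.lstsq(mat, dm.T, rcond=None)
    return sol.T
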