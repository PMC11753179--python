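"""Benchmark media and the synthetic absorption-change experiment.

``benchmark_media`` returns the 2-, 5- and 10-layer head-like benchmark media
(absorption and reduced scattering per layer, uniform n = 1.33, anisotropy
0.9 for MC, 250 mm cylinder radius) used throughout validation.

``run_experiment`` emulates a slow hemodynamic episode: raised-cosine
absorption bumps in two layers of a five-layer head model (scalp = layer 1,
gray matter = layer 4), frame-by-frame moment signals at two source-detector
distances, and linear retrieval of the per-layer absorption changes with
each of the three sensitivity factors.  Signals come either from re-running
the analytical forward model with the perturbed absorption (noiseless,
exact nonlinear response) or from re-weighting a single baseline Monte-Carlo
tally (microscopic Beer-Lambert), never from per-frame re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .forward_model import moments
from .medium import Layer, LayeredMedium
from .monte_carlo import McConfig, reweighted_moments, simulate
from .retrieval import (MomentChangeSeries, attenuation_change,
                        build_sf_matrix, retrieve_dmua, MOMENT_TYPES)

__all__ = ["benchmark_media", "example_medium", "ExperimentSpec",
           "ExperimentResult", "dmua_waveform", "run_experiment"]

ANISOTROPY = 0.9


def benchmark_media() -> Dict[str, LayeredMedium]:
    """The three benchmark media (keys: two_layer, five_layer, ten_layer)."""

    def build(mu_a, mu_sp, d):
        layers = [Layer(a, s, 1.33, t) for a, s, t in
                  zip(mu_a[:-1], mu_sp[:-1], d)]
        layers.append(Layer(mu_a[-1], mu_sp[-1], 1.33, None))
        return LayeredMedium(layers, radius=250.0, n_external=1.0)

    return {
        "two_layer": build((0.018, 0.017), (1.9, 2.3), (5.0,)),
        "five_layer": build((0.018, 0.016, 0.002, 0.036, 0.014),
                            (1.9, 1.6, 1.0, 2.2, 4.1),
                            (5.0, 5.0, 2.0, 4.0)),
        "ten_layer": build((0.002, 0.02, 0.01, 0.016, 0.004, 0.008, 0.014,
                            0.018, 0.012, 0.006),
                           (2.0, 1.12, 0.81, 0.50, 0.88, 0.96, 0.73, 1.04,
                            0.57, 0.65),
                           (2.0,) * 9),
    }


def example_medium() -> LayeredMedium:
    """Two-layer example medium: mu_a = (0.01, 0.002)/mm,
    mu_s' = (0.9, 1.1)/mm, n = 1.33, d1 = 10 mm."""
    return LayeredMedium([Layer(0.01, 0.9, 1.33, 10.0),
                          Layer(0.002, 1.1, 1.33, None)], radius=250.0)


@dataclass(frozen=True)
class ExperimentSpec:
    """Synthetic two-layer absorption-change experiment.

    Amplitudes default to 10% of each perturbed layer's baseline mu_a
    (linear-response regime); onsets/durations are staggered so the two
    layers' episodes overlap but are distinguishable.  ``engine`` is
    "analytic" (noiseless forward-model re-evaluation) or "mc"
    (re-weighting of one stored baseline tally).
    """

    medium: LayeredMedium
    perturbed_layers: Tuple[int, ...] = (0, 3)
    amplitudes: Optional[Tuple[float, ...]] = None  # 1/mm; None = 10% of mu_a
    onsets: Tuple[int, ...] = (10, 20)
    durations: Tuple[int, ...] = (30, 24)
    n_frames: int = 60
    distance_pairs: Tuple[Tuple[float, float], ...] = ((5.0, 15.0),
                                                       (10.0, 30.0))
    engine: str = "analytic"
    noise_level: float = 0.0     # fraction of each signal's peak magnitude
    seed: int = 0
    n_photons: int = 2_000_000   # MC engine only

    def amplitude_vector(self) -> np.ndarray:
        base = self.medium.mu_a
        if self.amplitudes is not None:
            amp = np.asarray(self.amplitudes, dtype=float)
        else:
            amp = 0.1 * base[list(self.perturbed_layers)]
        if np.any(base[list(self.perturbed_layers)] + np.minimum(amp, 0) <= 0):
            raise ValueError("amplitude drives total mu_a non-positive")
        return amp


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    truth: np.ndarray                      # (frames, P) true dmu_a
    signals: MomentChangeSeries            # at all distances used
    retrieved: dict                        # {(pair, moment): (frames, P)}
    residuals: dict                        # retrieved - truth, same keys


def dmua_waveform(spec: ExperimentSpec) -> np.ndarray:
    """True per-frame absorption changes, shape (n_frames, P).

    Each perturbed layer gets a raised-cosine bump
    a * (1 - cos(2 pi u)) / 2 with u = (frame - onset)/duration in [0, 1];
    the maximum equals the amplitude exactly at the midpoint frame.
    """
    amp = spec.amplitude_vector()
    frames = np.arange(spec.n_frames)
    out = np.zeros((spec.n_frames, len(spec.perturbed_layers)))
    for p, (a, onset, dur) in enumerate(zip(amp, spec.onsets, spec.durations)):
        u = (frames - onset) / dur
        inside = (u >= 0) & (u <= 1)
        out[inside, p] = a * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside]))
    return out


def _analytic_signals(spec: ExperimentSpec, truth: np.ndarray,
                      distances: np.ndarray) -> MomentChangeSeries:
    medium = spec.medium
    base = medium.mu_a
    baseline = [moments(medium, rho) for rho in distances]
    dA = np.zeros((spec.n_frames, len(distances)))
    dt = np.zeros_like(dA)
    dV = np.zeros_like(dA)
    cache = {}
    for f in range(spec.n_frames):
        key = tuple(np.round(truth[f], 12))
        if key not in cache:
            mu = base.copy()
            mu[list(spec.perturbed_layers)] += truth[f]
            med_f = medium.with_mu_a(mu)
            cache[key] = [moments(med_f, rho) for rho in distances]
        for k, ((m0b, tb, vb), (m0f, tf, vf)) in enumerate(
                zip(baseline, cache[key])):
            dA[f, k] = attenuation_change(m0f, m0b)
            dt[f, k] = tf - tb
            dV[f, k] = vf - vb
    return MomentChangeSeries(distances=distances, dA=dA, dt=dt, dV=dV)


def _mc_signals(spec: ExperimentSpec, truth: np.ndarray,
                distances: np.ndarray) -> MomentChangeSeries:
    medium = spec.medium
    config = McConfig(n_photons=spec.n_photons, seed=spec.seed,
                      g=ANISOTROPY, detector_radii=tuple(distances),
                      store_records=True)
    tally = simulate(medium, config)
    base = medium.mu_a
    sw_b, t_b, v_b = reweighted_moments(tally, base)
    dA = np.zeros((spec.n_frames, len(distances)))
    dt = np.zeros_like(dA)
    dV = np.zeros_like(dA)
    for f in range(spec.n_frames):
        mu = base.copy()
        mu[list(spec.perturbed_layers)] += truth[f]
        sw, t_m, v_m = reweighted_moments(tally, mu)
        dA[f] = -np.log(sw / sw_b)
        dt[f] = t_m - t_b
        dV[f] = v_m - v_b
    return MomentChangeSeries(distances=distances, dA=dA, dt=dt, dV=dV)


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Generate signals, optionally add seeded Gaussian noise, and retrieve
    the per-layer absorption changes with all three moment types at every
    configured distance pair."""
    truth = dmua_waveform(spec)
    distances = np.unique(np.concatenate(
        [np.asarray(p, dtype=float) for p in spec.distance_pairs]))
    if spec.engine == "analytic":
        signals = _analytic_signals(spec, truth, distances)
    elif spec.engine == "mc":
        signals = _mc_signals(spec, truth, distances)
    else:
        raise ValueError("engine must be 'analytic' or 'mc'")

    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        for arr in (signals.dA, signals.dt, signals.dV):
            scale = spec.noise_level * np.max(np.abs(arr), axis=0)
            arr += rng.normal(0.0, 1.0, arr.shape) * scale[None, :]

    retrieved, residuals = {}, {}
    for pair in spec.distance_pairs:
        idx = [int(np.nonzero(distances == r)[0][0]) for r in pair]
        sub = MomentChangeSeries(distances=np.asarray(pair, dtype=float),
                                 dA=signals.dA[:, idx], dt=signals.dt[:, idx],
                                 dV=signals.dV[:, idx])
        for moment in MOMENT_TYPES:
            problem = build_sf_matrix(spec.medium, pair,
                                      spec.perturbed_layers, moment)
            got = retrieve_dmua(problem, sub)
            retrieved[(pair, moment)] = got
            residuals[(pair, moment)] = got - truth
    return ExperimentResult(spec=spec, truth=truth, signals=signals,
                            retrieved=retrieved, residuals=residuals)
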