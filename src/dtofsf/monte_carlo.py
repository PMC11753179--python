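"""Layered photon-transport Monte Carlo with per-layer pathlength tallies.

The simulator propagates photons through laterally infinite layers
(Henyey-Greenstein scattering with mu_s = mu_s'/(1-g), Fresnel reflection
and refraction at the external and any index-mismatched internal boundary)
and records, for every photon detected in an annulus on the top surface,
its per-layer partial pathlengths l_ij.  Absorption is applied purely as a
microscopic Beer-Lambert weight at detection,

    W_i = exp(-sum_j mu_a_j l_ij),

so one simulation serves any small mu_a perturbation by re-weighting.  The
estimators mirror the analytical factors term by term:

    L_j    =  sum_i l_ij W_i / sum_i W_i
    MTSF_j = -sum_m <l_j l_m>/c_m + L_j <t>
    VSF_j  = -sum_{m,n} <l_j l_m l_n>/(c_m c_n)
             + 2 <t> sum_m <l_j l_m>/c_m + L_j (<t^2> - 2 <t>^2)

with <.> the W-weighted detected-photon average and t_i = sum_j l_ij / c_j.
Standard errors come from batch means (photons split into independent
batches).  Russian roulette (applied to the Beer-Lambert weight at the
baseline mu_a) and a maximum flight time bound the work per photon; the
roulette survival factor is carried into W_i so the estimators stay
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .medium import C_VACUUM, LayeredMedium

__all__ = [
    "McConfig", "PhotonTally", "McSensitivitySet", "simulate", "mc_mppl",
    "mc_mtsf", "mc_vsf", "wmape", "reweighted_moments",
]


@dataclass(frozen=True)
class McConfig:
    """Simulation controls.

    ``detector_radii`` are annulus centers [mm] (width ``annulus_width``);
    ``roulette_threshold`` acts on the baseline Beer-Lambert weight;
    ``max_time`` [ps] bounds each photon's flight.  ``store_records`` keeps
    the per-layer pathlengths of detected photons (needed for re-weighting).
    """

    n_photons: int
    seed: int = 0
    g: float = 0.9
    detector_radii: tuple = (10.0, 30.0)
    annulus_width: float = 1.0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_time: float = 10_000.0
    n_batches: int = 20
    store_records: bool = False
    record_cap: int = 2_000_000

    def __post_init__(self):
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must be in [0, 1)")
        r = np.sort(np.asarray(self.detector_radii, dtype=float))
        if len(r) > 1 and np.any(np.diff(r) < self.annulus_width):
            raise ValueError("detector annuli overlap")


@dataclass
class PhotonTally:
    """Batched accumulators of the detected-photon sums, per annulus."""

    medium: LayeredMedium
    config: McConfig
    count: np.ndarray      # (B, K)
    sum_w: np.ndarray      # (B, K)
    sum_lw: np.ndarray     # (B, K, N)
    sum_llw: np.ndarray    # (B, K, N, N)
    sum_lllw: np.ndarray   # (B, K, N, N, N)
    sum_tw: np.ndarray     # (B, K)
    sum_t2w: np.ndarray    # (B, K)
    n_launched: int
    n_detected: int        # exited the top surface into any annulus
    n_escaped: int         # exited the top surface elsewhere
    n_terminated: int      # roulette-killed or timed out
    record_l: Optional[np.ndarray] = None       # (n_rec, N) pathlengths
    record_logw: Optional[np.ndarray] = None    # (n_rec,) roulette log-factor
    record_annulus: Optional[np.ndarray] = None  # (n_rec,)

    def merge(self, other: "PhotonTally") -> "PhotonTally":
        """Pool two tallies of the same medium/geometry (batches stack)."""
        if other.medium != self.medium:
            raise ValueError("tallies describe different media")
        recs = {}
        if self.record_l is not None and other.record_l is not None:
            recs = dict(
                record_l=np.vstack([self.record_l, other.record_l]),
                record_logw=np.concatenate([self.record_logw, other.record_logw]),
                record_annulus=np.concatenate([self.record_annulus,
                                               other.record_annulus]))
        return PhotonTally(
            medium=self.medium, config=self.config,
            count=np.vstack([self.count, other.count]),
            sum_w=np.vstack([self.sum_w, other.sum_w]),
            sum_lw=np.vstack([self.sum_lw, other.sum_lw]),
            sum_llw=np.vstack([self.sum_llw, other.sum_llw]),
            sum_lllw=np.vstack([self.sum_lllw, other.sum_lllw]),
            sum_tw=np.vstack([self.sum_tw, other.sum_tw]),
            sum_t2w=np.vstack([self.sum_t2w, other.sum_t2w]),
            n_launched=self.n_launched + other.n_launched,
            n_detected=self.n_detected + other.n_detected,
            n_escaped=self.n_escaped + other.n_escaped,
            n_terminated=self.n_terminated + other.n_terminated,
            **recs)


@dataclass(frozen=True)
class McSensitivitySet:
    """MC sensitivity factors with batch-means standard errors;
    arrays have shape (n_annuli, n_layers)."""

    rho: np.ndarray
    L: np.ndarray
    L_se: np.ndarray
    MTSF: np.ndarray
    MTSF_se: np.ndarray
    VSF: np.ndarray
    VSF_se: np.ndarray


@njit(inline="always")
def _rng_next(s):
    """xorshift64* step: returns (uniform in (0,1), new state)."""
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    u = np.float64(s * np.uint64(0x2545F4914F6CDD1D) >> np.uint64(11)) \
        * (1.0 / 9007199254740992.0) + 5.421010862427522e-20
    return u, s


@njit(inline="always")
def _scatter(ux, uy, uz, g, state):
    if g > 0.0:
        u, state = _rng_next(state)
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    else:
        u, state = _rng_next(state)
        cost = 2.0 * u - 1.0
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    sint = np.sqrt(1.0 - cost * cost)
    # azimuth by rejection on the unit disc (no trig calls)
    while True:
        ua, state = _rng_next(state)
        ub, state = _rng_next(state)
        a = 2.0 * ua - 1.0
        b = 2.0 * ub - 1.0
        r2 = a * a + b * b
        if 1e-12 < r2 <= 1.0:
            break
    inv = 1.0 / r2
    cosp = (a * a - b * b) * inv
    sinp = 2.0 * a * b * inv
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz >= 0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        invden = 1.0 / den
        nx = sint * (ux * uz * cosp - uy * sinp) * invden + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) * invden + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * norm, ny * norm, nz * norm, state


@njit(inline="always")
def _fresnel(cos_i, n_rel):
    """Unpolarized reflectance crossing from index-n_rel side to 1 side."""
    sin_t2 = n_rel * n_rel * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=False, fastmath=True)
def _kernel(n_photons, n_batches, seed, mu_s, mu_a, inv_c, g, z_if, n_layer,
            n_ext, det_lo, det_hi, ln_thresh, survival, max_time,
            store_records, record_cap):
    # splitmix64 scramble of the seed into the xorshift64* state
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) \
        * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0x94D049BB133111EB)
    state = z ^ (z >> np.uint64(31)) | np.uint64(1)
    N = len(mu_s)
    K = len(det_lo)
    B = n_batches
    count = np.zeros((B, K), dtype=np.int64)
    sum_w = np.zeros((B, K))
    sum_lw = np.zeros((B, K, N))
    sum_llw = np.zeros((B, K, N, N))
    sum_lllw = np.zeros((B, K, N, N, N))
    sum_tw = np.zeros((B, K))
    sum_t2w = np.zeros((B, K))
    rec_l = np.zeros((record_cap if store_records else 1, N))
    rec_logw = np.zeros(record_cap if store_records else 1)
    rec_ann = np.zeros(record_cap if store_records else 1, dtype=np.int64)
    n_rec = 0
    n_detected = 0
    n_escaped = 0
    n_terminated = 0

    l = np.zeros(N)
    per_batch = n_photons // B
    extra = n_photons - per_batch * B
    ln_surv = np.log(1.0 / survival)

    for b in range(B):
        nb = per_batch + (1 if b < extra else 0)
        for _ in range(nb):
            x = 0.0
            y = 0.0
            z = 0.0
            ux = 0.0
            uy = 0.0
            uz = 1.0
            layer = 0
            for j in range(N):
                l[j] = 0.0
            att = 0.0
            lw = 0.0
            t = 0.0
            alive = True
            exited = False
            while alive:
                u, state = _rng_next(state)
                tau = -np.log(u)
                while tau > 0.0 and alive:
                    mus = mu_s[layer]
                    step = tau / mus
                    # distance to the layer boundary along the direction
                    if uz > 0.0:
                        if layer == N - 1:
                            db = 1e30
                        else:
                            db = (z_if[layer] - z) / uz
                    elif uz < 0.0:
                        zlo = 0.0 if layer == 0 else z_if[layer - 1]
                        db = (z - zlo) / (-uz)
                    else:
                        db = 1e30
                    if step < db:
                        x += step * ux
                        y += step * uy
                        z += step * uz
                        l[layer] += step
                        att += mu_a[layer] * step
                        t += step * inv_c[layer]
                        tau = 0.0
                    else:
                        x += db * ux
                        y += db * uy
                        z += db * uz
                        l[layer] += db
                        att += mu_a[layer] * db
                        t += db * inv_c[layer]
                        tau -= db * mus
                        if uz < 0.0 and layer == 0:
                            # top surface
                            z = 0.0
                            n_rel = n_layer[0] / n_ext
                            rf, cos_t = _fresnel(-uz, n_rel)
                            u, state = _rng_next(state)
                            if u < rf:
                                uz = -uz
                            else:
                                alive = False
                                exited = True
                        else:
                            nxt = layer + 1 if uz > 0.0 else layer - 1
                            if n_layer[nxt] == n_layer[layer]:
                                layer = nxt
                            else:
                                n_rel = n_layer[layer] / n_layer[nxt]
                                rf, cos_t = _fresnel(abs(uz), n_rel)
                                u, state = _rng_next(state)
                                if u < rf:
                                    uz = -uz
                                else:
                                    ux *= n_rel
                                    uy *= n_rel
                                    uz = cos_t * (1.0 if uz > 0.0 else -1.0)
                                    layer = nxt
                if not alive:
                    break
                ux, uy, uz, state = _scatter(ux, uy, uz, g, state)
                if t > max_time:
                    alive = False
                    n_terminated += 1
                    break
                if att - lw > ln_thresh:
                    u, state = _rng_next(state)
                    if u < survival:
                        lw += ln_surv
                    else:
                        alive = False
                        n_terminated += 1
                        break
            if exited:
                rho = np.sqrt(x * x + y * y)
                hit = -1
                for k in range(K):
                    if det_lo[k] <= rho < det_hi[k]:
                        hit = k
                        break
                if hit < 0:
                    n_escaped += 1
                else:
                    n_detected += 1
                    w = np.exp(lw - att)
                    count[b, hit] += 1
                    sum_w[b, hit] += w
                    sum_tw[b, hit] += t * w
                    sum_t2w[b, hit] += t * t * w
                    for j in range(N):
                        ljw = l[j] * w
                        sum_lw[b, hit, j] += ljw
                        for m in range(N):
                            ljmw = ljw * l[m]
                            sum_llw[b, hit, j, m] += ljmw
                            for n in range(N):
                                sum_lllw[b, hit, j, m, n] += ljmw * l[n]
                    if store_records and n_rec < record_cap:
                        for j in range(N):
                            rec_l[n_rec, j] = l[j]
                        rec_logw[n_rec] = lw
                        rec_ann[n_rec] = hit
                        n_rec += 1
    return (count, sum_w, sum_lw, sum_llw, sum_lllw, sum_tw, sum_t2w,
            n_detected, n_escaped, n_terminated, rec_l, rec_logw, rec_ann,
            n_rec)


def simulate(medium: LayeredMedium, config: McConfig) -> PhotonTally:
    """Run the layered MC and return the accumulated tally.

    Bit-reproducible for identical (medium, config).  The last layer must be
    semi-infinite.  When ``config.store_records`` is set the per-layer
    pathlengths of the first ``record_cap`` detected photons are kept (an
    unbiased subsample, photons being i.i.d.).
    """
    if medium.layers[-1].thickness is not None:
        raise ValueError("last layer must be semi-infinite (thickness None)")
    mu_s = medium.mu_s_prime / (1.0 - config.g)
    inv_c = medium.n / C_VACUUM
    z_if = np.cumsum(medium.thicknesses) if medium.n_layers > 1 else np.empty(0)
    radii = np.asarray(config.detector_radii, dtype=float)
    det_lo = radii - 0.5 * config.annulus_width
    det_hi = radii + 0.5 * config.annulus_width

    out = _kernel(
        config.n_photons, config.n_batches, config.seed, mu_s, medium.mu_a,
        inv_c, config.g, z_if, medium.n.astype(float), medium.n_external,
        det_lo, det_hi, np.log(1.0 / config.roulette_threshold),
        config.roulette_survival, config.max_time, config.store_records,
        config.record_cap)
    (count, sum_w, sum_lw, sum_llw, sum_lllw, sum_tw, sum_t2w, n_det,
     n_esc, n_term, rec_l, rec_logw, rec_ann, n_rec) = out
    recs = {}
    if config.store_records:
        recs = dict(record_l=rec_l[:n_rec], record_logw=rec_logw[:n_rec],
                    record_annulus=rec_ann[:n_rec])
    return PhotonTally(
        medium=medium, config=config, count=count, sum_w=sum_w,
        sum_lw=sum_lw, sum_llw=sum_llw, sum_lllw=sum_lllw, sum_tw=sum_tw,
        sum_t2w=sum_t2w, n_launched=config.n_photons, n_detected=int(n_det),
        n_escaped=int(n_esc), n_terminated=int(n_term), **recs)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _check_detected(tally: PhotonTally, minimum: int = 1):
    pooled = tally.count.sum(axis=0)
    if np.any(pooled < minimum):
        bad = np.nonzero(pooled < minimum)[0]
        raise ValueError(f"annulus index {bad.tolist()} holds fewer than "
                         f"{minimum} detected photons")


def _mppl_from_sums(sum_w, sum_lw):
    return sum_lw / sum_w[..., None]


def _mtsf_from_sums(sum_w, sum_lw, sum_llw, sum_tw, inv_c):
    L = sum_lw / sum_w[..., None]
    llm = sum_llw / sum_w[..., None, None]
    t_mean = sum_tw / sum_w
    return -llm @ inv_c + L * t_mean[..., None]


def _vsf_from_sums(sum_w, sum_lw, sum_llw, sum_lllw, sum_tw, sum_t2w, inv_c):
    L = sum_lw / sum_w[..., None]
    llm = sum_llw / sum_w[..., None, None]
    lll = sum_lllw / sum_w[..., None, None, None]
    t_mean = sum_tw / sum_w
    t2_mean = sum_t2w / sum_w
    term1 = -np.einsum("...jmn,m,n->...j", lll, inv_c, inv_c)
    term2 = 2.0 * t_mean[..., None] * (llm @ inv_c)
    term3 = L * (t2_mean - 2.0 * t_mean ** 2)[..., None]
    return term1 + term2 + term3


def _batch_se(batch_estimates: np.ndarray) -> np.ndarray:
    """Std error of the mean over the batch axis (axis 0)."""
    import warnings
    B = batch_estimates.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(batch_estimates, axis=0, ddof=1) / np.sqrt(B)


def mc_mppl(tally: PhotonTally):
    """Pooled MC mean partial pathlengths, shape (K, N), with batch SEs."""
    _check_detected(tally)
    L = _mppl_from_sums(tally.sum_w.sum(0), tally.sum_lw.sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_batch = _mppl_from_sums(tally.sum_w, tally.sum_lw)
    return L, _batch_se(per_batch)


def mc_mtsf(tally: PhotonTally, medium: Optional[LayeredMedium] = None):
    """Pooled MC mean-time sensitivity factors, shape (K, N), with SEs."""
    _check_detected(tally)
    medium = medium or tally.medium
    inv_c = medium.n / C_VACUUM
    v = _mtsf_from_sums(tally.sum_w.sum(0), tally.sum_lw.sum(0),
                        tally.sum_llw.sum(0), tally.sum_tw.sum(0), inv_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_batch = _mtsf_from_sums(tally.sum_w, tally.sum_lw, tally.sum_llw,
                                    tally.sum_tw, inv_c)
    return v, _batch_se(per_batch)


def mc_vsf(tally: PhotonTally, medium: Optional[LayeredMedium] = None):
    """Pooled MC variance sensitivity factors, shape (K, N), with SEs."""
    _check_detected(tally)
    medium = medium or tally.medium
    inv_c = medium.n / C_VACUUM
    v = _vsf_from_sums(tally.sum_w.sum(0), tally.sum_lw.sum(0),
                       tally.sum_llw.sum(0), tally.sum_lllw.sum(0),
                       tally.sum_tw.sum(0), tally.sum_t2w.sum(0), inv_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_batch = _vsf_from_sums(tally.sum_w, tally.sum_lw, tally.sum_llw,
                                   tally.sum_lllw, tally.sum_tw,
                                   tally.sum_t2w, inv_c)
    return v, _batch_se(per_batch)


def mc_sensitivity_set(tally: PhotonTally) -> McSensitivitySet:
    L, L_se = mc_mppl(tally)
    m, m_se = mc_mtsf(tally)
    v, v_se = mc_vsf(tally)
    return McSensitivitySet(
        rho=np.asarray(tally.config.detector_radii, dtype=float),
        L=L, L_se=L_se, MTSF=m, MTSF_se=m_se, VSF=v, VSF_se=v_se)


def wmape(sf_mc: np.ndarray, sf_theory: np.ndarray) -> float:
    """Weighted mean absolute percentage error over a distance grid [%]:
    sum_k |MC_k - T_k| / sum_k |MC_k| * 100."""
    sf_mc = np.asarray(sf_mc, dtype=float)
    sf_theory = np.asarray(sf_theory, dtype=float)
    if sf_mc.shape != sf_theory.shape:
        raise ValueError("vectors must have equal length")
    denom = np.sum(np.abs(sf_mc))
    if denom == 0:
        raise ZeroDivisionError("all-zero MC sensitivity vector")
    return float(np.sum(np.abs(sf_mc - sf_theory)) / denom * 100.0)


def reweighted_moments(tally: PhotonTally, mu_a: Sequence[float]):
    """DTOF moments per annulus from stored photon records under a replaced
    absorption vector: returns (sum_W, <t>, V) arrays of length K.

    Implements the microscopic Beer-Lambert re-weighting: pathlengths are
    fixed by the (absorption-free) trajectories, only the weights change.
    """
    if tally.record_l is None:
        raise ValueError("tally was run without store_records")
    mu_a = np.asarray(mu_a, dtype=float)
    w = np.exp(tally.record_logw - tally.record_l @ mu_a)
    inv_c = tally.medium.n / C_VACUUM
    t = tally.record_l @ inv_c
    K = len(tally.config.detector_radii)
    sw = np.zeros(K)
    mean_t = np.zeros(K)
    var_t = np.zeros(K)
    for k in range(K):
        sel = tally.record_annulus == k
        if not np.any(sel):
            raise ValueError(f"no records in annulus {k}")
        wk, tk = w[sel], t[sel]
        sw[k] = wk.sum()
        mean_t[k] = np.sum(tk * wk) / sw[k]
        var_t[k] = np.sum(tk ** 2 * wk) / sw[k] - mean_t[k] ** 2
    return sw, mean_t, var_t
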