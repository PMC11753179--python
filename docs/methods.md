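# Methods

## Model

`dtofsf` computes the diffuse reflectance of an N-layered turbid cylinder
under the diffusion approximation (DA) with extrapolated-boundary
conditions, and from it the per-layer *sensitivity factors* that link small
absorption changes Δμ_a,j to changes of the statistical moments of the
distribution of times of flight (DTOF) measured at a source–detector
distance ρ:

- ΔA(ρ)   = Σ_j L_j(ρ) Δμ_a,j      (attenuation / 0th moment),
- Δ⟨t⟩(ρ) = Σ_j MTSF_j(ρ) Δμ_a,j   (mean time of flight),
- ΔV(ρ)   = Σ_j VSF_j(ρ) Δμ_a,j    (variance).

The time-domain reflectance is expanded in a finite-cylinder Fourier–Bessel
(Dini) series over the roots s_n of J0(s R_EB) = 0,

    R(ρ, t) = 1/(4π² A R_EB²) Σ_n J0(s_n ρ)/J1²(s_n R_EB)
              ∫ G1(z=0, ω, s_n) e^{iωt} dω ,

where G1 is the Hankel/frequency-space Green's function of the illuminated
layer. Within each layer the transverse wavenumber is
α_j = sqrt(μ_a,j/D_j + s_n² + iω/(D_j c_j)) with D_j = 1/(3 μ'_s,j) and
c_j the layer light speed; the layers couple through a downward two-term
recursion in auxiliary amplitudes (β, γ) seeded at the deepest pair of
layers. For N = 2 the amplitudes are (1, 1), under which the expression
reduces to the classical two-layer solution; an N = 1 medium dispatches to
the closed-form extrapolated-boundary dipole solution.

The ω = 0 member of the series is the CW reflectance R(ρ). All DTOF
moments follow analytically from mixed μ_a-derivatives of R(ρ):

    L_j    = −(1/R) ∂R/∂μ_a,j
    ⟨t⟩    = Σ_k L_k / c_k
    ⟨t_k t_l⟩ = (1/(c_k c_l R)) ∂²R/∂μ_a,k ∂μ_a,l ,   V = ⟨t²⟩ − ⟨t⟩²
    MTSF_j = Σ_k (1/c_k) [L_j L_k − (1/R) ∂²R/∂μ_a,j ∂μ_a,k]
    VSF_j  = ∂⟨t²⟩/∂μ_a,j − 2⟨t⟩ MTSF_j ,

with the third mixed derivative of R entering ∂⟨t²⟩/∂μ_a,j. The product
identity for ⟨t_k t_l⟩ is adopted as exact; the test suite verifies it
implicitly by comparing every factor against central finite differences of
the forward model's moments and against Monte-Carlo estimates.

### Derivatives

μ_a,j enters the Green's function only through α_j, so all mixed partials
up to third order are propagated *exactly* with forward-mode truncated
Taylor (jet) arithmetic through the entire series evaluation (`dtofsf.jets`).
No finite differencing is used in the implementation; the finite-difference
oracles in the tests are therefore fully independent checks.

### Numerical choices

- Units: mm, ps, 1/mm; c_vacuum = 0.299792458 mm/ps.
- Boundary factor A from the Fresnel-reflectance angular moments
  (effective reflection coefficient R_eff = (R_φ + R_j)/(2 − R_φ + R_j),
  A = (1 + R_eff)/(1 − R_eff)); A(n=1.33 vs air) ≈ 2.515. A user override
  is accepted because published A conventions differ at the few-percent
  level; L/MTSF/VSF are only weakly sensitive to it. z_b = 2 A D_1,
  z_0 = 1/μ'_s,1, R_EB = R + z_b, default cylinder radius R = 250 mm.
- Overflow safety: all hyperbolics are rewritten as decaying exponentials
  and the (β, γ) recursion is renormalized at every step. The reflectance
  is a ratio jointly homogeneous of degree one in (β, γ), so the rescaling
  (even by μ_a-dependent factors, relevant for the jet path) cancels
  exactly. No argument with positive real part is ever exponentiated as
  long as z_0 ≤ 2 d_1 (violated only for sub-mean-free-path first layers,
  outside DA validity anyway).
- Series truncation: up to 5000 Bessel zeros; a term-magnitude scan picks
  the point after which 50 consecutive terms contribute < 1e-10 relative.
  If the cap is reached, an error is raised only when the tail still
  contributes > 1e-6 relative; around ρ = 45–50 mm for the 10-layer
  benchmark the tail sits between these bounds (the known slow-convergence
  corner of the expansion), which is still ~1e-9-accurate.
- Inverse transform: uniform time grid (default 10 ns, 2048 samples),
  Hermitian-symmetric synthesis with one `irfft`; the Fourier kernel sign
  follows from α² containing +iω/(Dc), and is validated by the
  zeroth-moment identity ∫R dt = R_CW and by ⟨t⟩ > 0. Negative truncation
  ringing below 1e-3 of the peak is clipped to zero; larger ringing, or
  tail amplitude above 1e-3 of the peak at the window end, raises a window
  error. Media with very weakly absorbing deep layers (e.g. the example
  two-layer medium with μ_a,2 = 0.002/mm) need a 20 ns window for
  percent-accurate variances.
- Time-dependent MPPLs mask samples where the DTOF is below 1e-12 of its
  peak (the log-derivative is meaningless in the ringing floor).

## Monte-Carlo oracle

A layered photon-transport simulator (numba-compiled) validates the DA
factors. Geometry: laterally infinite layers (no cylinder wall — invisible
at ρ ≤ 50 mm), pencil beam, annular detectors of width 1 mm on the top
surface, every transmitted photon counted regardless of exit angle.
Scattering is Henyey–Greenstein with g = 0.9 (μ_s = μ'_s/(1−g)); the
external boundary applies unpolarized Fresnel reflection for n = 1.33
against air; index-matched internal interfaces are transparent (Fresnel
refraction is implemented for mismatched ones but unused by the benchmark
media). Absorption is handled purely by microscopic Beer–Lambert weighting
W_i = exp(−Σ_j μ_a,j l_ij) at detection, which (i) matches the estimator
forms term by term and (ii) lets one stored trajectory set serve any small
μ_a perturbation by re-weighting. Russian roulette (threshold 1e-4 on the
baseline weight, survival 0.1, the survival factor carried into W_i) and a
10 ns flight-time cap bound the work per photon. The RNG is a seeded
xorshift64* stream, so runs are bit-reproducible. Standard errors come
from batch means (default 20 batches).

Estimator identities on hand-built photon records (including exact
single-photon degeneracies) are enumerated in the tests; agreement with the
analytical factors is quantified with the weighted mean absolute percentage
error wMAPE = Σ_k |SF_MC − SF_T| / Σ_k |SF_MC| over a distance grid.

## Synthetic experiment

`dtofsf.fixtures` emulates a slow hemodynamic episode on the five-layer
head-like benchmark: raised-cosine Δμ_a bumps in layer 1 (scalp) and
layer 4 (gray matter), default amplitude 10% of each baseline μ_a (the
linear-response regime), 60 frames, staggered onsets. Signals (ΔA, Δ⟨t⟩,
ΔV) at two distances are produced either by re-evaluating the analytic
forward model per frame (noiseless, exact nonlinear response) or by
re-weighting a single baseline MC tally (adds transport-model realism and
stochastic noise, at the cost of one simulation only). Retrieval inverts
the 2×2 sensitivity matrix held at baseline for each moment type;
contributions from undeclared layers and all nonlinearity become model
error by design. The generator does not emulate instrument response
functions, source drift, or physiological superficial oscillations, so
passing tests demonstrate the linear-inversion machinery and the relative
depth sensitivity of the moments — not performance on raw instrument data.

With MC-generated signals at the short distance pair (5, 15) mm the
deep-layer retrieval error decreases from attenuation- to mean-time- to
variance-based inversion (higher moments see depth better); with the wide
pair (10, 30) mm all three stay within 10% (superficial) / 15% (deep) of
the peak change in the noiseless configuration.

## Problem sizes

Validation problem sizes were chosen for a single desktop CPU: 1e7 photons
for the two-layer wMAPE comparison over ρ = 5…30 mm (≈10 min), 1.5–2e6
photons for the retrieval experiments, 10⁵–4×10⁵ for convergence and
consistency spot checks. MC uncertainty bands scale as 1/√n and the
comparisons use the computed standard errors, so the same checks hold at
larger budgets with proportionally tighter bands.

## Known limitations

- The DA underestimates early-photon effects; the first-layer MTSF/VSF of
  thin-top-layer media disagree with transport by up to ~10% at short ρ.
- Only absorption sensitivity is provided (no μ'_s factors), reflectance
  geometry only, no instrument-response convolution.
- The A-factor convention may differ from other codes at the few-percent
  level; supply `A` explicitly to `derive_optics` to match another tool.
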