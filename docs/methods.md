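# Methods

This note documents the models, numerical choices and limitations behind
`mslab`, in the order the pipeline uses them.

## RF pulse design (`mslab.pulses`)

Selective pulses are designed with the Shinnar–Le Roux transform. The
Cayley–Klein β polynomial is an equiripple FIR low-pass (Parks–McClellan,
`scipy.signal.remez`) whose fractional transition width follows the
standard empirical `d∞(δ1, δ2)` formula; ripples are mapped from
magnetization to β-domain per pulse class (excitation: δ1→√(δ1/2),
δ2→δ2/√2; spin-echo refocusing: δ1→δ1/4, δ2→√δ2; defaults δ1 = δ2 = 0.01).
β is scaled by sin(flip/2), α is completed as the minimum-phase spectral
factor of √(1−|β|²) via the cepstral method, and the hard-pulse sequence
is recovered by the inverse SLR recursion. Frequency responses are
evaluated with the same hard-pulse propagation used implicitly by the
design, so design and simulation cannot drift apart. Validation: the
small-tip profile of a 5° design matches the Fourier transform of the
waveform to <1% at band center, |α|²+|β|² = 1 to machine precision, and
the measured FWHM of the default 90° design (TBW 20, 7.18 ms) is 2775 Hz
against the nominal TBW/duration = 2786 Hz.

The protocol pair is a TBW-20 excitation (7.18 ms) and a TBW-8 refocusing
pulse (10.24 ms), both 256 samples; the composite excitation × refocusing²
profile is what defines the slab.

## Steady-state crosstalk simulation (`mslab.bloch`)

Each slab firing (selective 90° + crushed selective 180°, imaging echo at
TE = 78 ms) is treated as an instantaneous composite event. Ideal
crushers are assumed: transverse magnetization is destroyed after each
readout and only longitudinal magnetization carries between events, so
crosstalk is purely T1 saturation. Per firing, Mz is scaled by
(1 − 2|β_ex|²)(1 − 2|β_ref|²) at each position, and the recorded echo
amplitude is Mz·|2ᾱβ_ex·β_ref²|·e^(−TE/T2). Events are placed at
j·TR/n_slabs; interleaved ordering fires odd-numbered slabs (ascending)
then even-numbered ones, which reproduces the alternating 2/3·TR, 1/3·TR
excitation gaps a boundary spin experiences in a 3-slab acquisition.

Isochromats sample z position only: 600 per reconstructed slice
(convergence: doubling to 1200 changes profiles by <0.5%), uniformly
spread across the voxel; the voxel signal is the complex isochromat sum at
the echo, magnitude afterwards. The simulated region extends one slab FOV
beyond the reconstructed FOV on each side so edge slabs see realistic
fully-relaxed magnetization; nothing wraps in the simulation — aliasing
enters only through the k-space sampling operator downstream. Steady
state is declared when the per-TR Mz change falls below 10⁻⁶ (checked
after a burn-in of min(50, ⌈5·T1/TR⌉) TRs, hard cap 200); failure raises
a `SteadyStateWarning` and flags the profile rather than truncating
silently.

**Excitation width.** The pulse bandwidth must be mapped to a spatial
width by the slab-select gradient, which the protocol leaves open. Two
conventions are provided. `fov_mode="slab"` maps the bandwidth onto the
phase-encoded slab FOV (15 mm); adjacent slabs then excite their 3-mm
overlap at near-full flip, and without saturation the profile
root-sum-of-squares has ≈ +25% bands at the overlaps. `fov_mode="rss"`
(default for multislab) instead chooses the width so the composite
profiles of adjacent slabs cross at 1/√2 of the center amplitude midway
between slab centers — the tiling design that makes the profile
sum-of-squares approximately flat in the absence of saturation (≈12.8 mm
for 12-mm spacing with the default pulses). The reconstruction
experiments use "rss", because only under a flat unsaturated
sum-of-squares does calibrated linear inversion degrade specifically at
short TR, which is the regime this package exists to study; the
diffusion-bias reference uses "slab" as that analysis' stated
configuration. Both are one keyword away.

## Partial-volume diffusion bias (`mslab.diffusion`)

A boundary voxel's diffusion signal is modeled as a two-compartment sum
`M(b,v) = Σᵢ M0ᵢ(loc) fᵢ exp(−b vᵀDᵢv)` with Σfᵢ = 1. Compartment
tensors: WM [1.4, 0.35, 0.35]×10⁻³ mm²/s (FA = 0.707, principal axis
along x by default), GM 0.7 and CSF 3.0 isotropic. The b=0 amplitudes
M0ᵢ come from the Bloch simulation: per tissue, the **center** value is
the slab's center slice and the **boundary** value is the minimum of the
slab-combination profile (plain average of the covering slabs) between
adjacent slab centers. The combination is used because every overlap
slice in a reconstructed volume carries signal from both slabs — a single
slab's outermost slice is never observed in isolation; the single-slab
minimum is available as `center_boundary_m0` for comparison (it gives
~10% larger bias maxima).

Tensors are fitted by unweighted log-linear least squares on six
noncollinear directions (the dual-gradient scheme {(1,±1,0),(1,0,±1),
(0,1,±1)}/√2, configurable) plus b=0; MD is the eigenvalue mean and FA
the standard normalized eigenvalue dispersion. Because a single
compartment's M0 is purely multiplicative, the fit absorbs it in the
intercept: bias surfaces vanish identically at fractions 0 and 1, and the
grid maxima are invariant to rescaling either tissue's M0 at both
locations simultaneously — only the ratio of boundary dips between the
two tissues matters. The default grid is 0–100% WM in 1% steps and
b ∈ {1, 100, …, 10000} s/mm².

Under the ideal-crusher assumption CSF (T1 = 3 s) always saturates more
than WM at the boundary, so the FA-error surface peaks at high WM
fraction. Non-ideal crushing of very-long-T2 CSF (stimulated-echo
pathways) would shallow the CSF dip and can move the peak to low WM
fractions; such pathways are deliberately out of this model's scope. The
peak *values* are robust: max |ΔFA| ≈ 0.051 (WM/CSF, at b ≤ 1000 s/mm²),
≈ 0.022 (WM/GM), and max relative MD error ≈ 9.1% (WM/CSF), with WM/GM MD
error below 0.4%.

## Phantom and encoding (`mslab.phantom`, `mslab.forward`)

The synthetic phantom is a nested-ellipsoid brain: CSF rim, GM ribbon, WM
core, two CSF ventricles and four seeded GM nuclei, smoothed by a 1-voxel
Gaussian into partial-volume transitions (fractions clipped to [0,1],
per-voxel sum ≤ 1). Intensities are T2-weighted at TE = 78 ms with
proton densities 0.70/0.85/1.0 (WM/GM/CSF), times a ±5% smooth seeded
texture field; pure-voxel intensities order CSF > GM > WM. Everything is
deterministic in the seed. In-plane matrices of 48×48 are used for the
desk-scale experiments (32×32 in the fast CLI tests); the physics along
z, where the artifact lives, is at full protocol resolution (74 slices at
1.5 mm for 9 slabs).

Tissue profiles enter the encoding center-normalized per tissue, so a
pure voxel at a slab center has weight 1 regardless of tissue and the
encoded data keep the phantom's T2 contrast; what remains in the profiles
is the boundary structure (RF roll-off, side lobes, T1-dependent dips).
The integrated profile of a mixed voxel is the PV-weighted average of the
tissue profiles (background voxels get zero).

The forward operator is `d_s = P F C S_s u` per slab: profile and coil
weighting, unitary FFT, and kz sampling at spacing 1/(slab FOV) —
implemented exactly as folding the weighted image into the slab window
with period `slices_per_slab` (the aliasing mechanism), verified against
a brute-force periodic-summation oracle and by an adjoint inner-product
test at 10⁻¹⁰. Calibration data double the kz count (2× slice FOV),
giving essentially alias-free zero-padded slab images. A single uniform
coil is the default; smooth synthetic multi-coil maps are supported and
covered by the adjoint test. Optional complex Gaussian k-space noise is
off by default.

## Reconstructions (`mslab.recon`)

**WA** inverse-transforms each slab, weights slices with a 1D Fermi
window w(j) = 1/(1+exp((|j−c|−r)/width)) (default radius n/2 − overlap,
width 1 slice) and averages overlapping slabs with weight normalization.

**PEN** solves min‖E_S u − d‖² by conjugate gradients on the normal
equations, with profiles from calibration: each zero-padded slab image
divided by the root-sum-of-squares of all slabs, then low-passed in-plane
with a full-extent 2D Hamming window in k-space (a constant profile is
unchanged). A Tikhonov floor ε = 10⁻⁶·‖EᴴE‖ (power-iteration estimate)
guards conditioning; on exactly consistent toys it is set to 0 in tests
and CG matches the dense pseudo-inverse to 10⁻⁸. Because SoS-normalized
profiles satisfy E_est(u·sos) = d exactly, the PEN image is the truth
modulated by the profile sum-of-squares — flat at long TR, dipped at
short TR.

**NPEN** treats x = [u, S] as unknowns of the bilinear model
E(x) = (P F C s_i u)ᵢ and applies an iteratively regularized Gauss–Newton
scheme. The profile block is stored Sobolev-preconditioned,
y = W_s F_xy S with W_s = (1 + a‖k_xy‖²)^(ℓ/2) (a = 220/k_max², ℓ = 16),
so the Tikhonov term α‖x_n + Δx − x₀‖² enforces in-plane smoothness of S;
x₀ = [0, y₀] anchors the profiles to the calibration-derived 1D guess
(masked slice average, normalized at the slab center slice, broadcast
in-plane) and the image to zero. A second penalty β‖W_u F_z (u_n+Δu)‖²
suppresses the periodic artifact: W_u is a sum of Gaussian bumps at
kz = ±m/d_slab (all harmonics below Nyquist by default) of width
σ_k = 0.2/d_slab, with the DC weight required below 10⁻³ of the peak so
global intensity is never penalized. Each subproblem is solved by CG
(default 30 iterations, relative normal-equation tolerance 10⁻⁴); the
data are normalized to unit norm internally so α₀ = 0.2 and β₀ = 0.4 are
scale-free, both decay by 1.5× per outer iteration, and β is floored at
0.03. `tune_initial_regularization` grid-searches (α₀, β₀) for a
first-iteration residual ratio closest to 3/4. Divergence (residual
growth over three consecutive iterations) aborts with diagnostics.

Stopping: ‖Δu‖ falls to a minimum after the first ~3 iterations and rises
again; the returned iterate is the post-burn-in ‖Δu‖ minimum (earliest on
ties), with all iterates exposed for inspection. On the desk-scale study
this stopping iterate lies within three iterations of the minimum
full-image RMSE in a valley <3% deep, and the WM-specific RMSE minimum
occurs earlier than the full-image one — consistent with the T1
dependence of the profiles. Profile nonnegativity is not enforced
(profiles may be complex); magnitudes are taken for reporting only.

## Evaluation (`mslab.evaluate`)

RMSE against ground truth is computed on the brain mask (PV sum > 0.5)
and per tissue on strict PV > 0.8 masks; an empty mask reports NaN, not
zero. The truth is scaled to unit mean over the brain mask; the
reconstruction magnitude is scaled to the same mean by default
(`match_scale=True`), because each method carries its own arbitrary
global scale and RMSE should measure structure. Scan-time efficiency is
1/(1+f) for a fraction f of extra kz encodings (f = 0.4 → 71.4%).

Desk-scale results (48×48×74, TR = 2 s, seed 7): WM RMSE 0.113 (WA),
0.050 (PEN), 0.027 (NPEN); NPEN's largest residuals sit in CSF. Over
TR ∈ {2, 4, 7} s PEN's WM RMSE falls monotonically (0.050, 0.029, 0.018)
while NPEN's stays within 0.025–0.031.

## What the synthetic study does and does not show

The generator reproduces the artifact-relevant structure — tissue-tiered
T2 contrast, smooth partial-volume boundaries, CSF-adjacent WM, and full
protocol resolution along z — so passing tests demonstrate that the
encoding model and all three solvers behave as designed under realistic
crosstalk. It does not emulate EPI distortion, T2* blurring, motion phase
errors, B1 inhomogeneity, noise-limited calibration, or anatomical
fidelity of a real atlas; conclusions about absolute RMSE levels in vivo,
eddy-current behavior, or navigator-based phase correction are out of
scope. Non-ideally-crushed long-T2 pathways (relevant to CSF) are
excluded by the ideal-spoiling assumption, which affects where the FA
bias surface peaks along the fraction axis (see above).
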