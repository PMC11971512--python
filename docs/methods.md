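# Methods

## Signal model

The sequence is modeled by a 1D Bloch simulation of the longitudinal
magnetization only, assuming perfect spoiling of transverse magnetization
after every excitation.  One repetition covers five heartbeats with the
preparations (IR, none, spin-lock, T2-prep, none); each heartbeat plays a
segmented spoiled-GRE train of `segments_per_hb` excitations (default 16,
TR = 6.71 ms, FA = 8°).  Per TR the signal is `Mz sin(FA)`; the pulse leaves
`Mz cos(FA)`, which then relaxes toward M0 with T1.  Preparations are
instantaneous maps on Mz: inversion `Mz → −Mz`, spin-lock
`Mz → Mz exp(−TSL/T1ρ)`, T2-prep `Mz → Mz exp(−Tprep/T2)`; T1 recovery
during the 40 ms preparation pulses and all B0/B1 imperfections are
neglected, and the spin-lock amplitude is metadata only (no dispersion
model).  The inversion pulse is placed TI = 250 ms before the first readout
excitation (centric ordering puts the k-space centre there); the trigger
delay defaults to RR − 300 ms, capped so the readout window stays inside
the RR interval.  Recovery between heartbeats is pure T1 relaxation; the
low-flip navigator excitations are assumed negligible.

Three 5-heartbeat cycles are simulated, the first two as burn-in toward the
periodic steady state; convergence is geometric with the cycle count
(relative change ≈ 1e-4 per cycle at T1 = 2000 ms, RR = 1000 ms — the tests
assert this rate rather than an absolute steady-state claim at 3 cycles).
Each contrast point is the mean of the first `round(0.3·16) = 5` per-TR
signals, matching centric reordering where the earliest echoes carry the
k-space centre.  The fifth heartbeat by default acquires the fifth
(no-preparation) contrast; a flag (`idle_fifth`) instead treats it as a pure
recovery beat whose dictionary point copies the second contrast, for
sensitivity analysis.

Dictionary atoms are the signed 5-point signals on the Cartesian product of
the printed T1/T1ρ/T2 lists (duplicated boundary values removed), filtered
by T2 ≤ T1ρ ≤ T1 (276 688 entries) and normalized to unit L2 norm; signs are
kept so that the inversion contrast can be negative, and matching therefore
requires polarity-restored inputs.

## Digital phantom and forward model

Vial phantoms are cylinders on a signal-free background; all parameters are
constant within a labeled region, so the Bloch simulation runs once per
region.  The default nine vials span the myocardial/blood range
(T1 300–1500 ms, T1ρ 35–100 ms, T2 26–80 ms) and sit exactly on the
dictionary grid so that the lossless pipeline limit is exact.  Coil
sensitivities are Gaussian lobes on a ring with smooth low-order phase,
normalized to Σ|S|² = 1.  The fat model is a single spectral peak at
−220 Hz, making TE1 = 2.38 ms approximately out-of-phase and TE2 = 4.76 ms
approximately in-phase at 1.5 T; the fat compartment shares its region's
relaxation parameters (maps are matched on water images only).  The
per-voxel echo image is `S · w_c · ((1−ff) + ff e^{iθ_e}) · M0` with `w_c`
the 5-point Bloch weight; bipolar-readout phase errors, eddy currents and
B0 maps beyond the fat shift are not simulated.

Respiratory motion is rigid in-plane (RL, FH) translation per heartbeat,
applied in k-space as an exact linear phase.  The trace is
`A sin²(πh/period) + drift·h + jitter` with FH amplitude 8 mm, RL = 0.3·FH,
jitter SD 0.3 mm and period 4.3 heartbeats (~14 breaths/min at 60 bpm) —
deliberately incommensurate with the 5-heartbeat preparation cycle, since a
commensurate period would freeze every contrast at a single respiratory
phase.  iNAVs are coronal projections of the shifted proton-density volume,
block-averaged ×4 (8 mm navigator pixels at 2 mm voxels).  Complex Gaussian
k-space noise is set from a target object SNR (default 70 dB, defined as
mean object magnitude of the no-prep in-phase image over the per-component
noise SD; the unitary FFT and Σ|S|²=1 coil combination preserve the level).

What the generator does *not* emulate: anatomy and through-plane motion,
cardiac (intra-beat) motion, B0/B1 inhomogeneity, multi-peak fat, flow, and
scanner artifacts.  Passing the stressed test therefore demonstrates the
correctness and stability of the estimation chain under controlled motion,
undersampling and noise — not in-vivo performance.

## Sampling

Each (contrast, heartbeat) shot is an approximate Archimedean spiral
interleaf in the (ky, kz) phase-encode plane, rotated by the golden angle
(137.508°) between shots and offset by golden/5 across contrasts, with an
additional per-contrast stagger of the radius schedule (a second increment)
that keeps the central rings incoherent across contrasts.  Radii follow the
inverse CDF of a density ∝ r^(−vd_exponent) (default 1).  Samples snap to
the Cartesian grid (DC at `n//2`); within a contrast each cell is owned by
the first heartbeat that acquires it, and proposals landing on owned cells
are re-drawn at the nearest free cell.  The DC cell is re-acquired at the
start of every shot (centric contract) but owned by the first; new cells
stop being added once the per-contrast coverage target `N/accel` is reached.
This de-duplication keeps the realized acceleration within a few percent of
the request and makes respiratory-bin masks an exact partition of the
contrast mask.

## Motion compensation

Beat-to-beat (RL, FH) translation is estimated from the iNAVs by normalized
cross-correlation over integer shifts with 3-point parabolic sub-pixel
refinement (measured accuracy ≈ 0.2 mm median on the default navigator
resolution).  Heartbeats are grouped into B = 4 equal-count (quantile) bins
of the FH displacement — robust to outliers, unlike equal-width bins — with
the reference bin chosen as minimal |median FH| (end-expiration for a trace
referenced to end-expiration).  Every sample is phase-corrected to its bin
centre (per-bin median of both components).  Bin images are reconstructed
from the 4th-contrast in-phase echo (T2-prepared, brightest signal; the
in-phase echo avoids fat cancellation) by CG-SENSE with soft binning
(neighbouring bins at weight 0.5).

Inter-bin motion is estimated by multi-resolution B-spline free-form
registration (SimpleITK, mean-squared metric, L-BFGS-B, 32 mm control-point
spacing, deterministic 20 % metric sampling).  At desk scale the per-bin
images are ~24× undersampled and their aliasing is *stationary*, which
biases any intensity metric toward the identity: unconstrained refinement
underestimated a 7 mm inter-bin shift by several millimetres.  The pipeline
therefore anchors the registration with a fixed translation equal to the
navigator-implied bin-centre difference and box-bounds the B-spline
coefficients at ±0.5 mm around it — the B-spline models only the residual
non-rigid component.  On clean images the unconstrained path recovers known
shifts and synthetic smooth deformations (tested separately).

The encoding operator applies, per bin, warp → coil weighting → centred
unitary FFT → binned mask.  Warps are sparse interpolation matrices (Keys
cubic convolution by default; trilinear optional), row-normalized so
constants are preserved, and the adjoint is the exact matrix transpose — the
standard motion-compensated-reconstruction choice, not the inverse warp.
Cubic interpolation was chosen because trilinear warping of sub-voxel
translations attenuates high spatial frequencies enough to leave a visible
model-mismatch floor in the data residual.

## Reconstruction (HD-PROST)

All C = 10 contrast/echo volumes are reconstructed jointly by ADMM on

    ||EX − K||² + λ Σ_v ||T_v||_* + (μ/2) Σ_v w_v ||T_v − P_v X − Y_v/μ||²

with λ = 0.04, μ = 0.1, 5 outer iterations.  P_v stacks the 20 most similar
5×5×5 patches (L2 distance on the channel-averaged magnitude, searched in a
20×20×20 window on a stride-4 reference grid, ties broken in raster order)
across all channels into a (125 × 20 × 10) tensor.  Patch positions are
selected once from the zero-filled adjoint and kept fixed so the multipliers
stay aligned with their tensors.  Windows are clipped to valid in-volume
patch positions at the borders (equivalent to, and simpler than, reflective
padding).

The data-consistency subproblem is solved by 5 CG iterations on the normal
equations with coverage weights `w_v = 1/count`, for which `PᴴWP` is exactly
the identity: the patch term then enters as `(μ/2)I` and overlap-averaged
re-aggregation on the right-hand side.  With unnormalized counts (~27 at
these settings) the patch term would outweigh `EᴴE` (whose spectrum scales
with the sampled fraction, ~1/6 per contrast) by an order of magnitude and
the reconstruction would no longer be data consistent in the fully sampled
limit.  The denoising subproblem is solved per tensor by truncated HOSVD:
mode bases from Gram-matrix eigendecompositions, dropping mode singular
values below λ·σ_max (classical multilinear-rank truncation).  An
alternative rule that hard-thresholds individual core coefficients at
λ·max|core| is available (`rule="core"`); it denoises more aggressively but
violates the fully-determined limit at these settings, so rank truncation
is the default.  The multiplier update is `Y ← Y + μ(P(X) − T)`.  The whole
reconstruction is deterministic given (K, E, config).

## Water/fat separation and mapping

With the single-peak model the echoes obey `IP = W + F e^{iθ2}`,
`OP = (W + F e^{iθ1}) e^{iφ}` after folding the TE2 background phase into
(W, F), where `φ = ψ(TE1) − ψ(TE2)` is the inter-echo background (B0)
phase.  φ is estimated from the magnitude-weighted, unwrapped, Gaussian-
smoothed (SD 3 voxels) relative phase `arg(OP·conj(IP))` — a smooth-phase
surrogate for published field-map estimators, adequate for smooth B0 and
invariant to a global phase.  The per-voxel 2×2 complex system is then
solved exactly with both θ taken from the configured fat shift and echo
times (θ1 ≈ −1.05π, θ2 ≈ −0.09π at the defaults), so no in/out-of-phase
idealisation is needed.  In the pipeline φ is estimated once from the
4th-contrast echoes and reused for all contrasts, so the π phase of the
(possibly negative) inversion contrast is not absorbed into the field map
before polarity restoration.  **Known limitation:** a spatially extended
pure-fat region is indistinguishable from a B0 offset with two echoes under
this surrogate (the classic Dixon ambiguity) and will be swapped into
water; mixed fat fractions up to ~0.5 are recovered to ≈0.01–0.02 absolute
on noise-free phantoms.

Polarity is restored by multiplying each water contrast with
`e^{−i·arg(ref)}`, ref being the 4th-contrast in-phase echo image, and
taking the real part; voxels with zero reference are flagged.  Voxels whose
5-point signal norm is below 5 % of the volume's 95th-percentile norm are
masked out.  Matching maximizes the signed inner product of the normalized
signal with the unit-norm atoms; for large dictionaries the argmax is found
exactly via a KD-tree (on unit vectors, max inner product ≡ Euclidean
nearest neighbour), otherwise by blocked matrix products with ties to the
lowest atom index.  The IR-SE reference fit uses
`S = M0(1 − 2e^{−TI/T1} + e^{−TR/T1})` by trust-region-reflective least
squares (bounds T1 ∈ [1, 5000] ms require TRF rather than plain
Levenberg–Marquardt); T1ρ/T2 reference fits are ordinary least squares on
log-signal.

## Problem sizes and numerical choices

Default study conditions: 64×64×16 volume at 2 mm isotropic, 6 coils,
accel 6 per contrast, 4 bins, 70 dB SNR, full dictionary (276 688 atoms).
The smaller 32×32×8 phantom with 4 coils is used for the lossless and
water/fat checks, where the chain is exact by construction and size only
affects runtime.  CG tolerances are 1e-6 (relative) unless a test demands a
dense-oracle comparison, where CG is run to convergence.  Quantile-bin
edges use `searchsorted(..., side="right")`, so constant traces collapse
into a single bin.  All randomness flows from one seed through named
substreams (sampling, coils, motion, noise), making every run reproducible
from its manifest.
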