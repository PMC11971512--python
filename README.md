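# triomap

Simulation and reconstruction toolkit for **free-breathing 3D joint
T1/T1ρ/T2 cardiac mapping with Dixon water–fat imaging** at 1.5 T.

Native T1, T1ρ and T2 relaxation times of the myocardium are complementary,
contrast-agent-free markers of fibrosis, edema and inflammation.  A
magnetization-prepared sequence interleaved over five heartbeats — (1)
adiabatic inversion (TI = 250 ms), (2) no preparation, (3) spin-lock
preparation (TSL = 40 ms, 400 Hz), (4) T2 preparation (40 ms), (5) no
preparation — encodes all three parameters in a single free-breathing scan,
acquired with a two-point bipolar Dixon spoiled-GRE readout
(TE1/TE2/TR = 2.38/4.76/6.71 ms, FA = 8°, 16 segments per heartbeat, 107 ms
acquisition window) on a variable-density Cartesian trajectory with spiral
profile order and golden-angle increments within and across contrasts,
6× undersampled per contrast.

`triomap` implements the whole method at desk scale, end to end:

* **signal_model** — 1D Bloch simulation of the longitudinal magnetization
  (perfect spoiling) through repeated 5-heartbeat cycles; dictionary
  generation on the printed grid
  T1 = [50:50:600, 600:15:1800, 1800:50:2200, 2200:100:3000] ms,
  T1ρ = T2 = [5:5:20, 20:1.5:80, 80:4:100, 100:10:300, 300:100:600] ms
  constrained to T2 ≤ T1ρ ≤ T1, each atom the signed unit-norm 5-point signal
  (mean over the first 30 % of the centric readout).
* **phantom** — piecewise-constant vial phantoms, smooth complex coil maps,
  per-heartbeat respiratory translation traces, and the forward simulation of
  motion-corrupted, undersampled, noisy two-echo multi-coil k-space plus 2D
  image navigators (iNAVs).
* **sampling** — the variable-density spiral-profile Cartesian pattern with
  centric reordering and per-respiratory-bin mask extraction.
* **motion** — iNAV translation estimation (normalized cross-correlation with
  sub-pixel refinement), quantile respiratory binning (B = 4), translational
  k-space correction to bin centres, soft-binned iterative SENSE bin images,
  B-spline free-form registration to end-expiration, and the
  motion-compensated encoding operator `E(c) = Σ_b A_b^(c) F S U_b` with an
  exact (sparse-transpose) adjoint.
* **recon** — HD-PROST: ADMM with iterative-SENSE data consistency and
  patch-tensor low-rank regularization via higher-order SVD truncation
  (λ = 0.04, μ = 0.1, 5 outer iterations, 5 SENSE iterations, 20×20×20
  search window, 5×5×5 patches, 20 similar patches, patch offset 4), jointly
  over all C = 10 contrast/echo volumes.
* **waterfat** — two-point Dixon separation with smooth background-phase
  correction (exact per-voxel 2×2 complex solve at the configured fat shift).
* **mapping** — polarity restoration from the 4th-contrast in-phase echo,
  per-voxel normalization, maximum-inner-product dictionary matching, and
  the 2D spin-echo reference fits (IR-SE two-parameter fit; log-linear
  mono-exponential T1ρ/T2 fits).
* **interface / CLI** — validated YAML configuration, NIfTI/HDF5/CSV/JSON
  I/O, seeded end-to-end pipeline.

## Worked example

Run the full default pipeline — 64×64×16 phantom (2 mm isotropic), nine
vials spanning the myocardial range, 6× per-contrast undersampling, 4
respiratory bins, 8 mm foot–head breathing, 70 dB SNR — and print per-vial
map statistics:

```bash
triomap all --seed 1 --output runs/demo
```

```
outputs written to runs/demo
vial 1: T1   300.0 ms  T1rho   50.9 ms  T2   41.5 ms
vial 2: T1   451.4 ms  T1rho   34.4 ms  T2   25.6 ms
vial 3: T1   609.7 ms  T1rho   64.5 ms  T2   49.9 ms
vial 4: T1   831.2 ms  T1rho   42.9 ms  T2   34.9 ms
vial 5: T1  1008.4 ms  T1rho   56.1 ms  T2   43.3 ms
vial 6: T1  1118.4 ms  T1rho   82.0 ms  T2   64.2 ms
vial 7: T1  1264.9 ms  T1rho  115.6 ms  T2   85.2 ms
vial 8: T1  1419.5 ms  T1rho   68.4 ms  T2   56.6 ms
vial 9: T1  1551.0 ms  T1rho  130.7 ms  T2   77.9 ms
```

Each line is the mean of the matched T1/T1ρ/T2 over the interior voxels of
one vial; the ground truth for vial 1 is 300/50/41 ms, for vial 5
1005/56/44 ms.  Short-T1 vials recover almost exactly; accuracy degrades
for the longest T1/T1ρ vials (vials 7 and 9), mirroring the sequence's
design for myocardial-range values — a single 40 ms preparation and 5
heartbeats between inversions encode long relaxation times only weakly.
`runs/demo/` contains the
matched maps and ground truth as NIfTI, the k-space bundle, reconstruction
and dictionary as HDF5, per-vial statistics as CSV, and a JSON manifest that
(with the seed) fully reproduces the run.

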