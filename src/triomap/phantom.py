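"""Digital phantoms and the forward acquisition model.

Provides piecewise-constant 3D tissue-parameter volumes resembling multi-vial
relaxometry phantoms (agar/NiCl2 vials on a signal-free background), smooth
complex coil sensitivities, per-heartbeat respiratory translation traces with a
dominant foot-head (FH) component, and the forward simulation of the 5-contrast
two-echo Dixon GRE acquisition: motion-corrupted, undersampled, noisy Cartesian
k-space plus the per-heartbeat 2D image navigators (iNAVs).

Geometry: volume axes are (x, y, z) = (right-left RL, foot-head FH,
anterior-posterior AP).  The readout direction kx is fully sampled; (ky, kz)
is the phase-encode plane handled by :mod:`triomap.sampling`.  Respiratory
motion is rigid in-plane translation (RL, FH) per heartbeat; iNAVs are coronal
projections (along AP).

Fat model: a single spectral peak at ``fat_shift_hz`` (default -220 Hz at
1.5 T), so echo 1 (TE1=2.38 ms) is close to out-of-phase and echo 2
(TE2=4.76 ms) close to in-phase.  The fat compartment shares its region's
relaxation parameters; Dixon separation downstream works on water images only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import AcquisitionSpec, TissueParams, simulate_shot_train
from .sampling import SamplingPattern  # noqa: F401  (public type in signatures)

__all__ = [
    "FAT_SHIFT_HZ",
    "TissueParameterMap",
    "MotionTrace",
    "MultiContrastKspace",
    "make_vial_phantom",
    "make_coil_sensitivities",
    "simulate_motion_trace",
    "simulate_acquisition",
    "contrast_weights",
    "dixon_echo_factor",
    "project_inav",
    "fft3c",
    "ifft3c",
    "T1MES_LIKE_VIALS",
]

FAT_SHIFT_HZ = -220.0

# Nine vials spanning the myocardial/blood range of a T1-mapping multi-vial
# phantom (native and post-contrast like values), t2 <= t1rho <= t1; all
# values lie on the default dictionary grid.
T1MES_LIKE_VIALS = [
    TissueParams(t1=300.0, t1rho=50.0, t2=41.0),
    TissueParams(t1=450.0, t1rho=35.0, t2=26.0),
    TissueParams(t1=600.0, t1rho=65.0, t2=50.0),
    TissueParams(t1=810.0, t1rho=44.0, t2=35.0),
    TissueParams(t1=1005.0, t1rho=56.0, t2=44.0),
    TissueParams(t1=1110.0, t1rho=80.0, t2=62.0),
    TissueParams(t1=1275.0, t1rho=100.0, t2=80.0),
    TissueParams(t1=1425.0, t1rho=68.0, t2=56.0),
    TissueParams(t1=1500.0, t1rho=92.0, t2=71.0),
]


@dataclass
class TissueParameterMap:
    """Voxelwise ground-truth (or estimated) tissue parameters."""

    t1: np.ndarray
    t1rho: np.ndarray
    t2: np.ndarray
    m0: np.ndarray
    fat_fraction: np.ndarray
    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


@dataclass
class MotionTrace:
    """Per-heartbeat rigid respiratory translation [mm]."""

    fh: np.ndarray
    rl: np.ndarray
    seed: int

    @property
    def n_heartbeats(self) -> int:
        return len(self.fh)


@dataclass
class MultiContrastKspace:
    """Cartesian multi-contrast two-echo multi-coil k-space.

    ``data[c, e, coil, kx, ky, kz]`` is nonzero only on sampled phase-encode
    cells; ``hb_index[c, ky, kz]`` gives the acquiring (global) heartbeat or
    -1.  ``masks[c, ky, kz]`` is the per-contrast union sampling mask.
    """

    data: np.ndarray
    masks: np.ndarray
    hb_index: np.ndarray
    noise_sigma: float
    acq: AcquisitionSpec
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def n_contrasts(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[3:]


# ---------------------------------------------------------------------------
# FFT conventions: unitary, DC at n//2 in every axis
# ---------------------------------------------------------------------------

def fft3c(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Centred unitary 3D FFT (image -> k-space)."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft3c(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Centred unitary 3D inverse FFT (k-space -> image)."""
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_vial_phantom(
    n_vials: int,
    params: list[TissueParams] | None = None,
    fat_vials: set[int] | frozenset[int] = frozenset(),
    shape: tuple[int, int, int] = (64, 64, 16),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    fat_fractions: dict[int, float] | None = None,
    radius_frac: float = 0.10,
    ring_frac: float = 0.62,
) -> TissueParameterMap:
    """Cylindrical vials arranged on a ring over a signal-free background.

    ``params[i]`` fills vial ``i`` (label ``i+1``); vials in ``fat_vials`` get
    fat fraction 1 (or the value from ``fat_fractions``), others 0.  Vials run
    the full z extent.  Overlapping vials raise an error.
    """
    if params is None:
        params = T1MES_LIKE_VIALS[:n_vials]
    if len(params) != n_vials:
        raise ValueError(f"expected {n_vials} parameter sets, got {len(params)}")
    nx, ny, nz = shape
    t1 = np.full(shape, 1.0)
    t1rho = np.full(shape, 1.0)
    t2 = np.full(shape, 1.0)
    m0 = np.zeros(shape)
    ff = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    if n_vials == 0:
        return TissueParameterMap(t1, t1rho, t2, m0, ff, labels, voxel_size)
    r_vial = radius_frac * min(nx, ny)
    r_ring = ring_frac * min(nx, ny) / 2.0
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for i, p in enumerate(params):
        if n_vials == 1:
            vx, vy = cx, cy
        else:
            ang = 2 * np.pi * i / n_vials
            vx, vy = cx + r_ring * np.cos(ang), cy + r_ring * np.sin(ang)
        disk = (xx - vx) ** 2 + (yy - vy) ** 2 <= r_vial**2
        if not disk.any():
            raise ValueError(f"vial {i} does not fit in shape {shape}")
        vol = np.repeat(disk[:, :, None], nz, axis=2)
        if (labels[vol] != 0).any():
            raise ValueError(f"vial {i} overlaps a previous vial")
        labels[vol] = i + 1
        t1[vol], t1rho[vol], t2[vol] = p.t1, p.t1rho, p.t2
        m0[vol] = p.m0
        if i in fat_vials:
            ff[vol] = 1.0 if fat_fractions is None else fat_fractions.get(i, 1.0)
    return TissueParameterMap(t1, t1rho, t2, m0, ff, labels, voxel_size)


def make_coil_sensitivities(
    n_coils: int, shape: tuple[int, int, int], seed: int = 0
) -> np.ndarray:
    """Smooth complex coil maps, normalized so sum_c |S_c|^2 = 1 everywhere.

    Coils are Gaussian magnitude lobes centred on a ring around the FOV with a
    smooth low-order polynomial phase; identical seeds give identical maps.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = shape
    if n_coils == 1:
        return np.ones((1, nx, ny, nz), dtype=complex)
    rng = np.random.default_rng(seed)
    x = np.linspace(-1, 1, nx)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    z = np.linspace(-1, 1, nz)[None, None, :]
    sens = np.empty((n_coils, nx, ny, nz), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
        cx, cy = 1.2 * np.cos(ang), 1.2 * np.sin(ang)
        cz = rng.uniform(-0.5, 0.5)
        width = 1.1 + rng.uniform(-0.1, 0.1)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)
                       + (z - cz) ** 2 / (2 * (2 * width) ** 2)))
        a, b, cph = rng.normal(0, 0.8, size=3)
        phase = a * x + b * y + cph * x * y + 2 * np.pi * c / n_coils
        sens[c] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    return sens / rss


def simulate_motion_trace(
    n_heartbeats: int,
    fh_amplitude: float = 8.0,
    period: float = 4.3,
    drift: float = 0.0,
    seed: int = 0,
    jitter_sd: float = 0.3,
    rl_ratio: float = 0.3,
) -> MotionTrace:
    """Pseudo-respiratory translation trace.

    FH displacement is ``amplitude * sin^2(pi * h / period) + drift * h`` plus
    seeded Gaussian jitter; RL is ``rl_ratio`` times FH.  Units mm, one sample
    per heartbeat.  The default period (4.3 heartbeats, ~14 breaths/min at
    60 bpm) is deliberately incommensurate with the 5-heartbeat preparation
    cycle so every contrast samples the full respiratory range.
    """
    if fh_amplitude < 0:
        raise ValueError("fh_amplitude must be >= 0")
    h = np.arange(n_heartbeats, dtype=float)
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, jitter_sd, size=n_heartbeats) if jitter_sd > 0 else 0.0
    fh = fh_amplitude * np.sin(np.pi * h / period) ** 2 + drift * h + jitter
    rl = rl_ratio * fh
    return MotionTrace(fh=fh, rl=rl, seed=seed)


# ---------------------------------------------------------------------------
# forward acquisition
# ---------------------------------------------------------------------------

def contrast_weights(pmap: TissueParameterMap, acq: AcquisitionSpec) -> np.ndarray:
    """Per-voxel unnormalized 5-contrast signal weights (signed, m0 excluded).

    Exploits the piecewise-constant phantom: the Bloch shot train is simulated
    once per labeled region and broadcast to its voxels.  Background (label 0)
    gets zero weight.
    """
    w = np.zeros((5,) + pmap.shape)
    from types import SimpleNamespace

    ids = pmap.region_ids()
    if ids.size:
        t1 = np.array([pmap.t1[pmap.labels == i][0] for i in ids])
        t1r = np.array([pmap.t1rho[pmap.labels == i][0] for i in ids])
        t2 = np.array([pmap.t2[pmap.labels == i][0] for i in ids])
        tissue = SimpleNamespace(t1=t1, t1rho=t1r, t2=t2, m0=np.ones_like(t1))
        sig = simulate_shot_train(tissue, acq)  # [n_regions, 5]
        for j, i in enumerate(ids):
            region = pmap.labels == i
            for c in range(5):
                w[c][region] = sig[j, c]
    return w


def _shift_phase(shape, dx_vox: float, dy_vox: float) -> np.ndarray:
    """Linear k-space phase implementing an image-domain (x, y) translation.

    Multiplying centred k-space by this ramp shifts image content by
    (+dx, +dy) voxels (periodic).
    """
    nx, ny, _ = shape
    kx = np.arange(nx) - nx // 2
    ky = np.arange(ny) - ny // 2
    ph = np.exp(-2j * np.pi * (kx[:, None] * dx_vox / nx + ky[None, :] * dy_vox / ny))
    return ph[:, :, None]


def dixon_echo_factor(fat_fraction: np.ndarray, te_ms: float,
                      fat_shift_hz: float = FAT_SHIFT_HZ) -> np.ndarray:
    """Complex water+fat modulation ``(1-ff) + ff * exp(i 2 pi df TE)``."""
    theta = 2 * np.pi * fat_shift_hz * te_ms * 1e-3
    return (1.0 - fat_fraction) + fat_fraction * np.exp(1j * theta)


def project_inav(volume: np.ndarray, downsample: int = 4) -> np.ndarray:
    """Coronal projection (sum over AP) downsampled by block averaging."""
    proj = np.abs(volume).sum(axis=2)
    nx, ny = proj.shape
    d = downsample
    nx2, ny2 = nx // d * d, ny // d * d
    return proj[:nx2, :ny2].reshape(nx2 // d, d, ny2 // d, d).mean(axis=(1, 3))


def simulate_acquisition(
    pmap: TissueParameterMap,
    acq: AcquisitionSpec,
    pattern: SamplingPattern,
    sens: np.ndarray,
    motion: MotionTrace | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    fat_shift_hz: float = FAT_SHIFT_HZ,
    inav_downsample: int = 4,
) -> tuple[MultiContrastKspace, np.ndarray]:
    """Forward-simulate the motion-corrupted undersampled two-echo acquisition.

    Per contrast c and echo e the coil image is
    ``S_coil * w_c * ((1-ff) + ff exp(i theta_e)) * m0`` translated rigidly by
    the acquiring heartbeat's (RL, FH) shift; its k-space is sampled on the
    cells owned by that heartbeat.  Complex Gaussian noise with per-component
    standard deviation ``noise_sigma`` is added to sampled entries.  Returns
    the k-space bundle and the per-heartbeat iNAV images.
    """
    nx, ny, nz = pmap.shape
    if pattern.matrix != (ny, nz):
        raise ValueError(f"pattern matrix {pattern.matrix} does not match phantom ({ny}, {nz})")
    if sens.shape[1:] != pmap.shape:
        raise ValueError("sensitivity shape mismatch")
    n_coils = sens.shape[0]
    C = pattern.n_contrasts
    n_hb = pattern.n_heartbeats
    if motion is None:
        motion = MotionTrace(fh=np.zeros(n_hb), rl=np.zeros(n_hb), seed=0)
    if motion.n_heartbeats < n_hb:
        raise ValueError("motion trace shorter than the acquisition")
    vx, vy, _ = pmap.voxel_size
    w = contrast_weights(pmap, acq)
    tes = (acq.te1, acq.te2)
    rng = np.random.default_rng(seed)
    data = np.zeros((C, 2, n_coils, nx, ny, nz), dtype=complex)
    hb_index = np.where(pattern.owner >= 0, pattern.owner, -1)
    masks = pattern.contrast_masks()

    for c in range(C):
        owned = pattern.owner[c]
        for e, te in enumerate(tes):
            img = w[c] * dixon_echo_factor(pmap.fat_fraction, te, fat_shift_hz) * pmap.m0
            ksp0 = fft3c(sens * img[None])  # [coil, kx, ky, kz], static object
            for s in range(pattern.n_shots):
                hb = pattern.heartbeat_of(c, s)
                cells = owned == hb
                if not cells.any():
                    continue
                ph = _shift_phase(pmap.shape, motion.rl[hb] / vx, motion.fh[hb] / vy)
                yy, zz = np.nonzero(cells)
                data[c, e, :, :, yy, zz] = (ksp0 * ph)[:, :, yy, zz].transpose(2, 0, 1)
    if noise_sigma > 0:
        sampled = masks.astype(bool)  # [C, ny, nz]
        for c in range(C):
            yy, zz = np.nonzero(sampled[c])
            n = len(yy)
            noise = rng.normal(0, noise_sigma, size=(2, 2, n_coils, nx, n)).view()
            cplx = noise[0] + 1j * noise[1]
            data[c, :, :, :, yy, zz] += cplx.transpose(3, 0, 1, 2)

    # iNAVs: coronal projection of the proton-density object at the true shift.
    base = pmap.m0
    inavs = []
    from scipy.ndimage import shift as nd_shift

    for hb in range(n_hb):
        shifted = nd_shift(base, (motion.rl[hb] / vx, motion.fh[hb] / vy, 0.0),
                           order=1, mode="constant")
        inavs.append(project_inav(shifted, inav_downsample))
    inavs = np.stack(inavs)

    ksp = MultiContrastKspace(
        data=data, masks=masks, hb_index=hb_index, noise_sigma=float(noise_sigma),
        acq=acq, voxel_size=pmap.voxel_size,
    )
    return ksp, inavs
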