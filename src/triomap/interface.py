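"""Configuration, I/O round-trips and the end-to-end pipeline driver.

The pipeline wires the stages together in acquisition order:

    phantom -> sampling -> forward acquisition -> iNAV motion estimation ->
    respiratory binning -> translational k-space correction -> per-bin SENSE ->
    non-rigid registration -> HD-PROST -> Dixon water/fat -> polarity
    restoration -> dictionary matching -> maps + statistics.

Everything is reproducible from (config, seed): the single global seed is
fanned out into named substreams (sampling, coils, motion, noise) so stages
can be re-run in isolation with identical results.

File formats: NIfTI-1 for real-valued volumes/maps, HDF5 for k-space and
complex volumes, CSV for per-region statistics, JSON for the run manifest,
YAML for configuration.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import mapping as mapping_mod
from . import motion as motion_mod
from . import phantom as phantom_mod
from . import recon as recon_mod
from . import sampling as sampling_mod
from . import signal_model as sm
from . import waterfat as wf_mod
from .signal_model import AcquisitionSpec, SignalDictionary, TissueParams

__all__ = [
    "PipelineConfig", "PhantomConfig", "AcquisitionConfig", "SamplingConfig",
    "MotionConfig", "ReconConfig", "MappingConfig",
    "load_config", "substream_seed", "run_pipeline", "PipelineResult",
    "write_nifti", "read_nifti", "write_complex_h5", "read_complex_h5",
    "io_roundtrip", "save_dictionary", "load_dictionary",
    "save_kspace_bundle", "load_kspace_bundle",
]

log = logging.getLogger("triomap")


# ---------------------------------------------------------------------------
# configuration schema (unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VialConfig(_Strict):
    t1: float
    t1rho: float
    t2: float
    m0: float = 1.0


class PhantomConfig(_Strict):
    shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size_mm: float = 2.0
    n_vials: int = 9
    vials: Optional[list[VialConfig]] = None
    fat_vials: list[int] = Field(default_factory=list)
    fat_fractions: dict[int, float] = Field(default_factory=dict)


class AcquisitionConfig(_Strict):
    rr_interval: float = 1000.0
    ti: float = 250.0
    tsl: float = 40.0
    sla: float = 400.0
    t2prep_dur: float = 40.0
    tr: float = 6.71
    te1: float = 2.38
    te2: float = 4.76
    flip_angle: float = 8.0
    segments_per_hb: int = 16
    trigger_delay: Optional[float] = None
    n_prep_cycles: int = 3
    centric_fraction: float = 0.30
    idle_fifth: bool = False

    def to_spec(self) -> AcquisitionSpec:
        return AcquisitionSpec(**self.model_dump())


class SamplingConfig(_Strict):
    accel: float = 6.0
    golden_step_deg: float = sampling_mod.GOLDEN_ANGLE_DEG
    vd_exponent: float = 1.0


class MotionConfig(_Strict):
    enabled: bool = True
    fh_amplitude_mm: float = 8.0
    period_hb: float = 4.3
    drift_mm_per_hb: float = 0.0
    jitter_sd_mm: float = 0.3
    n_bins: int = 4
    soft_weight: float = 0.5
    inav_downsample: int = 4
    bin_recon_iters: int = 15
    max_shift_mm: tuple[float, float] = (10.0, 20.0)  # (RL, FH)
    ffd_grid_spacing_mm: float = 32.0
    ffd_levels: int = 2
    ffd_refine_bound_mm: float = 0.5


class NoiseConfig(_Strict):
    snr_db: Optional[float] = 70.0  # None disables noise


class CoilConfig(_Strict):
    n_coils: int = 6


class ReconConfig(_Strict):
    lam: float = 0.04
    mu: float = 0.1
    outer_iters: int = 5
    sense_iters: int = 5
    search_window: int = 20
    patch_size: int = 5
    n_similar: int = 20
    patch_offset: int = 4

    def to_hdprost(self) -> recon_mod.HDProstConfig:
        return recon_mod.HDProstConfig(**self.model_dump())


class MappingConfig(_Strict):
    t1_ranges: Optional[list[list[float]]] = None
    t1rho_ranges: Optional[list[list[float]]] = None
    t2_ranges: Optional[list[list[float]]] = None
    mask_threshold: float = 0.05


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "triomap_out"
    fat_shift_hz: float = phantom_mod.FAT_SHIFT_HZ
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    motion: MotionConfig = Field(default_factory=MotionConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    coils: CoilConfig = Field(default_factory=CoilConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    mapping: MappingConfig = Field(default_factory=MappingConfig)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic named substream of the global seed."""
    return np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])


def _substream_int(seed: int, name: str) -> int:
    return int(substream_seed(seed, name).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def write_nifti(volume: np.ndarray, path: str | Path,
                voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vox


def write_complex_h5(volume: np.ndarray, path: str | Path, name: str = "data") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset(name, data=volume, track_times=False)


def read_complex_h5(path: str | Path, name: str = "data") -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as fh:
        return fh[name][()]


def io_roundtrip(volume: np.ndarray, path: str | Path,
                 voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)) -> np.ndarray:
    """Write then re-read a volume; HDF5 for complex data, NIfTI for real."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        write_complex_h5(volume, path)
        return read_complex_h5(path)
    write_nifti(volume, path, voxel_size)
    data, _ = read_nifti(path)
    return data


def save_dictionary(d: SignalDictionary, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("grid/t1", data=d.t1, track_times=False)
        fh.create_dataset("grid/t1rho", data=d.t1rho, track_times=False)
        fh.create_dataset("grid/t2", data=d.t2, track_times=False)
        fh.create_dataset("atoms", data=d.atoms, track_times=False)
        for k, v in d.acq.to_dict().items():
            fh.attrs[k] = v if v is not None else np.nan


def load_dictionary(path: str | Path) -> SignalDictionary:
    import h5py

    with h5py.File(path, "r") as fh:
        attrs = dict(fh.attrs)
        attrs["segments_per_hb"] = int(attrs["segments_per_hb"])
        attrs["n_prep_cycles"] = int(attrs["n_prep_cycles"])
        attrs["idle_fifth"] = bool(attrs["idle_fifth"])
        acq = AcquisitionSpec(**attrs)
        return SignalDictionary(
            t1=fh["grid/t1"][()], t1rho=fh["grid/t1rho"][()],
            t2=fh["grid/t2"][()], atoms=fh["atoms"][()], acq=acq,
        )


def save_kspace_bundle(ksp: phantom_mod.MultiContrastKspace, path: str | Path,
                       sens: np.ndarray | None = None,
                       inavs: np.ndarray | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=ksp.data, track_times=False)
        fh.create_dataset("masks", data=ksp.masks, track_times=False)
        fh.create_dataset("hb_index", data=ksp.hb_index, track_times=False)
        if sens is not None:
            fh.create_dataset("sens", data=sens, track_times=False)
        if inavs is not None:
            fh.create_dataset("inavs", data=inavs, track_times=False)
        fh.attrs["noise_sigma"] = ksp.noise_sigma
        fh.attrs["voxel_size"] = ksp.voxel_size
        for k, v in ksp.acq.to_dict().items():
            fh.attrs[f"acq_{k}"] = v if v is not None else np.nan


def load_kspace_bundle(path: str | Path):
    import h5py

    with h5py.File(path, "r") as fh:
        acq_kwargs = {k[4:]: fh.attrs[k] for k in fh.attrs if k.startswith("acq_")}
        acq_kwargs["segments_per_hb"] = int(acq_kwargs["segments_per_hb"])
        acq_kwargs["n_prep_cycles"] = int(acq_kwargs["n_prep_cycles"])
        acq_kwargs["idle_fifth"] = bool(acq_kwargs["idle_fifth"])
        ksp = phantom_mod.MultiContrastKspace(
            data=fh["data"][()], masks=fh["masks"][()], hb_index=fh["hb_index"][()],
            noise_sigma=float(fh.attrs["noise_sigma"]),
            acq=AcquisitionSpec(**acq_kwargs),
            voxel_size=tuple(fh.attrs["voxel_size"]),
        )
        sens = fh["sens"][()] if "sens" in fh else None
        inavs = fh["inavs"][()] if "inavs" in fh else None
    return ksp, sens, inavs


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    config: PipelineConfig
    truth: phantom_mod.TissueParameterMap
    pattern: sampling_mod.SamplingPattern
    kspace: phantom_mod.MultiContrastKspace
    inavs: np.ndarray
    sens: np.ndarray
    motion_true: phantom_mod.MotionTrace
    shifts_est: np.ndarray  # [n_hb, 2] (rl, fh) mm
    bins: np.ndarray
    reference_bin: int
    fields: list
    X: np.ndarray  # [10, nx, ny, nz]
    residual_history: list[float]
    water: np.ndarray  # [5, nx, ny, nz]
    fat: np.ndarray
    fat_fraction_est: np.ndarray
    signed: np.ndarray  # [5, nx, ny, nz]
    dictionary: SignalDictionary
    maps: mapping_mod.QuantitativeMaps
    region_stats: list[dict]
    output_dir: Path | None


def _default_vials(cfg: PhantomConfig) -> list[TissueParams]:
    if cfg.vials is not None:
        return [TissueParams(v.t1, v.t1rho, v.t2, v.m0) for v in cfg.vials]
    return phantom_mod.T1MES_LIKE_VIALS[: cfg.n_vials]


def build_phantom(cfg: PhantomConfig) -> phantom_mod.TissueParameterMap:
    vials = _default_vials(cfg)
    vs = (cfg.voxel_size_mm,) * 3
    return phantom_mod.make_vial_phantom(
        n_vials=len(vials), params=vials, fat_vials=set(cfg.fat_vials),
        shape=tuple(cfg.shape), voxel_size=vs,
        fat_fractions=dict(cfg.fat_fractions) or None,
    )


def noise_sigma_for_snr(pmap, acq, snr_db: float | None,
                        fat_shift_hz: float) -> float:
    """k-space noise sd giving the requested image-domain object SNR [dB].

    SNR is defined on the no-preparation contrast, in-phase echo: mean object
    magnitude divided by the per-component noise sd (unitary FFT preserves
    noise levels; coil combination with sum |S|^2 = 1 does too).
    """
    if snr_db is None:
        return 0.0
    w = phantom_mod.contrast_weights(pmap, acq)
    img = np.abs(w[1] * phantom_mod.dixon_echo_factor(pmap.fat_fraction, acq.te2,
                                                      fat_shift_hz) * pmap.m0)
    mean_sig = img[pmap.m0 > 0].mean()
    return float(mean_sig / 10 ** (snr_db / 20))


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full simulation + reconstruction + mapping pipeline."""
    t_start = time.time()
    cfg = config
    seed = cfg.seed
    acq = cfg.acquisition.to_spec()
    out_dir = Path(cfg.output_dir) if write_outputs else None
    file_handler = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        file_handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
        file_handler.setFormatter(logging.Formatter("%(message)s"))
        log.addHandler(file_handler)
        log.setLevel(logging.INFO)

    def stage(name):
        log.info("[%7.1fs] stage: %s", time.time() - t_start, name)

    stage("phantom")
    pmap = build_phantom(cfg.phantom)
    nx, ny, nz = pmap.shape
    vs = pmap.voxel_size

    stage("sampling")
    pattern = sampling_mod.generate_caspr_pattern(
        matrix=(ny, nz), accel=cfg.sampling.accel, n_contrasts=5,
        segments_per_hb=acq.segments_per_hb,
        golden_step_deg=cfg.sampling.golden_step_deg,
        vd_exponent=cfg.sampling.vd_exponent,
        seed=_substream_int(seed, "sampling"),
    )
    n_hb = pattern.n_heartbeats

    stage("coils/motion")
    sens = phantom_mod.make_coil_sensitivities(
        cfg.coils.n_coils, pmap.shape, seed=_substream_int(seed, "coils"))
    if cfg.motion.enabled:
        trace = phantom_mod.simulate_motion_trace(
            n_hb, fh_amplitude=cfg.motion.fh_amplitude_mm,
            period=cfg.motion.period_hb, drift=cfg.motion.drift_mm_per_hb,
            jitter_sd=cfg.motion.jitter_sd_mm,
            seed=_substream_int(seed, "motion"),
        )
    else:
        trace = phantom_mod.MotionTrace(np.zeros(n_hb), np.zeros(n_hb), 0)

    stage("acquisition")
    sigma = noise_sigma_for_snr(pmap, acq, cfg.noise.snr_db, cfg.fat_shift_hz)
    ksp, inavs = phantom_mod.simulate_acquisition(
        pmap, acq, pattern, sens, motion=trace, noise_sigma=sigma,
        seed=_substream_int(seed, "noise"), fat_shift_hz=cfg.fat_shift_hz,
        inav_downsample=cfg.motion.inav_downsample,
    )

    stage("motion estimation")
    n_bins = cfg.motion.n_bins if cfg.motion.enabled else 1
    if cfg.motion.enabled:
        px = (vs[0] * cfg.motion.inav_downsample, vs[1] * cfg.motion.inav_downsample)
        shifts = np.array([
            motion_mod.estimate_translation_ncc(
                inavs[h], inavs[0], max_shift_mm=cfg.motion.max_shift_mm,
                pixel_size_mm=px)
            for h in range(n_hb)
        ])
        bins, centers_fh, ref_bin = motion_mod.assign_bins(shifts[:, 1], n_bins)
        centers_rl = np.array([
            np.median(shifts[bins == b, 0]) if (bins == b).any() else 0.0
            for b in range(n_bins)
        ])
        centers_fh = np.where(np.isnan(centers_fh), 0.0, centers_fh)
        ksp_c = motion_mod.correct_translation_kspace(
            ksp, shifts[:, 0], shifts[:, 1], bins, centers_rl, centers_fh)
    else:
        shifts = np.zeros((n_hb, 2))
        bins = np.zeros(n_hb, dtype=int)
        ref_bin = 0
        ksp_c = ksp

    bin_masks = sampling_mod.bin_sampling_masks(pattern, bins, n_bins)  # [C,B,ny,nz]

    stage("bin images + registration")
    fields: list = [None] * n_bins
    if n_bins > 1:
        # 4th contrast, in-phase echo drives the bin images
        bin_imgs = motion_mod.reconstruct_bin_images(
            ksp_c.data[3, 1], bin_masks[3], sens,
            n_iters=cfg.motion.bin_recon_iters,
            soft_weight=cfg.motion.soft_weight,
        )
        for b in range(n_bins):
            if b == ref_bin:
                continue
            # anchor the FFD at the navigator-implied inter-bin translation;
            # the B-spline models only a bounded residual deformation
            init = (centers_rl[ref_bin] - centers_rl[b],
                    centers_fh[ref_bin] - centers_fh[b], 0.0)
            fld = motion_mod.register_ffd(
                np.abs(bin_imgs[ref_bin]), np.abs(bin_imgs[b]), voxel_size=vs,
                grid_spacing_mm=cfg.motion.ffd_grid_spacing_mm,
                n_levels=cfg.motion.ffd_levels,
                init_translation_mm=init,
                refine_bound_mm=cfg.motion.ffd_refine_bound_mm,
            )
            fld.reference_bin = ref_bin
            fields[b] = fld

    stage("HD-PROST reconstruction")
    # channels: (contrast, echo) -> c * 2 + e, echoes share the contrast mask
    chan_masks = np.repeat(bin_masks, 2, axis=0)
    K = ksp_c.data.reshape((10,) + ksp_c.data.shape[2:])
    E = motion_mod.compose_encoding_operator(chan_masks, sens, fields, vs)
    hd_cfg = cfg.recon.to_hdprost()
    X, history = recon_mod.hd_prost_reconstruct(K, E, hd_cfg)

    stage("water/fat separation")
    theta_ip = 2 * np.pi * cfg.fat_shift_hz * acq.te2 * 1e-3
    theta_op = 2 * np.pi * cfg.fat_shift_hz * acq.te1 * 1e-3
    ip_c4, op_c4 = X[3 * 2 + 1], X[3 * 2 + 0]
    phase_map = wf_mod.estimate_background_phase(ip_c4, op_c4, acq.te1, acq.te2)
    water = np.empty((5,) + pmap.shape, dtype=complex)
    fat = np.empty_like(water)
    for c in range(5):
        water[c], fat[c] = wf_mod.dixon_separate(
            X[c * 2 + 1], X[c * 2 + 0], phase_map, theta_op, theta_ip)
    obj_mask_rough = np.abs(water[1]) + np.abs(fat[1]) > 0
    ff_est = wf_mod.fat_fraction(water[1], fat[1], obj_mask_rough)

    stage("mapping")
    signed, _qc = mapping_mod.restore_polarity(water, ip_c4)
    mask = mapping_mod.signal_mask(signed, cfg.mapping.mask_threshold)
    mp = cfg.mapping
    dictionary = sm.build_dictionary(
        acq,
        t1_ranges=mp.t1_ranges or sm.DEFAULT_T1_RANGES,
        t1rho_ranges=mp.t1rho_ranges or sm.DEFAULT_T1RHO_RANGES,
        t2_ranges=mp.t2_ranges or sm.DEFAULT_T2_RANGES,
    )
    maps = mapping_mod.match_dictionary(signed, dictionary, mask)
    stats = mapping_mod.region_statistics(maps, pmap.labels)

    result = PipelineResult(
        config=cfg, truth=pmap, pattern=pattern, kspace=ksp, inavs=inavs,
        sens=sens, motion_true=trace, shifts_est=shifts, bins=bins,
        reference_bin=ref_bin, fields=fields, X=X, residual_history=history,
        water=water, fat=fat, fat_fraction_est=ff_est, signed=signed,
        dictionary=dictionary, maps=maps, region_stats=stats,
        output_dir=out_dir,
    )
    if out_dir is not None:
        stage("writing outputs")
        _write_outputs(result)
    stage("done")
    if file_handler is not None:
        log.removeHandler(file_handler)
        file_handler.close()
    return result


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_outputs(res: PipelineResult) -> None:
    out = res.output_dir
    vs = res.truth.voxel_size
    for name in ("t1", "t1rho", "t2"):
        write_nifti(getattr(res.maps, name), out / f"map_{name}.nii.gz", vs)
        write_nifti(getattr(res.truth, name), out / f"truth_{name}.nii.gz", vs)
    for name in ("m0", "fat_fraction", "labels"):
        write_nifti(getattr(res.truth, name), out / f"truth_{name}.nii.gz", vs)
    write_nifti(res.maps.match_score, out / "match_score.nii.gz", vs)
    write_nifti(res.maps.mask.astype(np.float32), out / "mask.nii.gz", vs)
    write_nifti(res.fat_fraction_est, out / "fat_fraction.nii.gz", vs)
    # echo-magnitude volumes (x, y, z, contrast), one file per echo;
    # complex data lives in recon.h5
    mag = np.abs(res.X).reshape((5, 2) + res.truth.shape)
    for e in range(2):
        write_nifti(np.moveaxis(mag[:, e], 0, -1), out / f"contrasts_echo{e + 1}.nii.gz", vs)
    for b, fld in enumerate(res.fields):
        if fld is not None:
            write_nifti(np.moveaxis(fld.displacement, 0, -1),
                        out / f"deformation_bin{b}.nii.gz", vs)
    save_kspace_bundle(res.kspace, out / "kspace.h5", sens=res.sens, inavs=res.inavs)
    import h5py

    with h5py.File(out / "recon.h5", "w") as fh:
        fh.create_dataset("X", data=res.X, track_times=False)
        fh.create_dataset("residual_history", data=np.asarray(res.residual_history),
                          track_times=False)
        fh.create_dataset("water", data=res.water, track_times=False)
        fh.create_dataset("fat", data=res.fat, track_times=False)
    save_dictionary(res.dictionary, out / "dictionary.h5")
    with open(out / "bins.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["heartbeat", "fh_mm", "rl_mm", "bin"])
        for h in range(len(res.bins)):
            w.writerow([h, f"{res.shifts_est[h, 1]:.4f}",
                        f"{res.shifts_est[h, 0]:.4f}", int(res.bins[h])])
    if res.region_stats:
        with open(out / "region_stats.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(res.region_stats[0].keys()))
            w.writeheader()
            w.writerows(res.region_stats)
    manifest = {
        "config": res.config.model_dump(),
        "config_hash": _config_hash(res.config),
        "seed": res.config.seed,
        "versions": {"numpy": np.__version__},
        "n_heartbeats": int(res.pattern.n_heartbeats),
        "reference_bin": int(res.reference_bin),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
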