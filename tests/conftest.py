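"""Shared fixtures: default sequence timing, small phantoms, and the two
expensive session-scoped pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from triomap.interface import PipelineConfig
from triomap.phantom import make_coil_sensitivities, make_vial_phantom
from triomap.signal_model import AcquisitionSpec, build_dictionary


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def small_phantom():
    """9-vial phantom at desk scale 32x32x8 (2 mm voxels)."""
    return make_vial_phantom(9, shape=(32, 32, 8))


@pytest.fixture(scope="session")
def small_sens(small_phantom):
    return make_coil_sensitivities(4, small_phantom.shape, seed=11)


@pytest.fixture(scope="session")
def full_dictionary(acq):
    """Dictionary on the full default (T1, T1rho, T2) grid (~277k atoms)."""
    return build_dictionary(acq)


@pytest.fixture(scope="session")
def lossless_result():
    """Noise-free, motion-free, fully sampled pipeline run (32x32x8).

    In this limit the chain phantom -> k-space -> SENSE -> Dixon -> polarity
    -> matching is exact, so matched maps must equal the on-grid ground truth.
    The ADMM runs a single outer iteration without thresholding (lam=0): at
    acceleration 1 the data-consistency subproblem is fully determined.
    """
    from triomap.interface import run_pipeline

    cfg = PipelineConfig(
        seed=0,
        phantom={"shape": (32, 32, 8), "n_vials": 9},
        sampling={"accel": 1.0},
        motion={"enabled": False},
        noise={"snr_db": None},
        coils={"n_coils": 4},
        recon={"lam": 0.0, "outer_iters": 1, "sense_iters": 10,
               "search_window": 10},
    )
    return run_pipeline(cfg, write_outputs=False)


@pytest.fixture(scope="session")
def stressed_result():
    """Full default pipeline: 64x64x16, 6x per contrast, 4 respiratory bins,
    8 mm FH breathing, 70 dB SNR, complete motion-compensated HD-PROST chain."""
    from triomap.interface import run_pipeline

    return run_pipeline(PipelineConfig(seed=1), write_outputs=False)


def region_errors(truth, maps, param: str) -> np.ndarray:
    """Relative absolute errors over interior (eroded) vial voxels."""
    from scipy.ndimage import binary_erosion

    errs = []
    for lab in truth.region_ids():
        region = binary_erosion(truth.labels == lab) & maps.mask
        t = getattr(truth, param)[region]
        e = getattr(maps, param)[region]
        errs.append(np.abs(e - t) / t)
    return np.concatenate(errs)
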