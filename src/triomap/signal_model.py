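"""Bloch signal model for the interleaved 5-heartbeat multi-parametric sequence.

The sequence acquires five differently prepared volumes over five consecutive
heartbeats: (1) adiabatic inversion recovery, (2) no preparation, (3) spin-lock
(T1rho) preparation, (4) T2 preparation, and (5) no preparation.  Each heartbeat
reads out a segment of a spoiled gradient-echo (GRE) train; with centric k-space
reordering the k-space centre is acquired at the start of the readout, so the
effective contrast of each volume is the mean signal over the first fraction of
the echo train.

Only the longitudinal magnetization is simulated (perfect spoiling); the
preparation modules act instantaneously on Mz:

* inversion:   Mz -> -Mz,
* T1rho-prep:  Mz -> Mz * exp(-TSL / T1rho),
* T2-prep:     Mz -> Mz * exp(-Tprep / T2),

and T1 recovery during the (40 ms) preparation pulses is neglected.  Between RF
events Mz relaxes mono-exponentially towards M0 with time constant T1.  The
spin-lock amplitude is carried as metadata only (no dispersion model).

All simulation routines are written to broadcast over numpy arrays of tissue
parameters so that dictionaries with hundreds of thousands of entries are
generated in a handful of vectorized passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from types import SimpleNamespace
from typing import Sequence

import numpy as np

__all__ = [
    "Preparation",
    "TissueParams",
    "AcquisitionSpec",
    "SignalDictionary",
    "apply_preparation",
    "simulate_readout",
    "simulate_shot_train",
    "parse_range_spec",
    "build_dictionary",
    "DEFAULT_T1_RANGES",
    "DEFAULT_T1RHO_RANGES",
    "DEFAULT_T2_RANGES",
]

N_CONTRASTS = 5

# Printed dictionary grids, [start, step, stop] inclusive of stop.
DEFAULT_T1_RANGES = [[50, 50, 600], [600, 15, 1800], [1800, 50, 2200], [2200, 100, 3000]]
DEFAULT_T1RHO_RANGES = [[5, 5, 20], [20, 1.5, 80], [80, 4, 100], [100, 10, 300], [300, 100, 600]]
DEFAULT_T2_RANGES = DEFAULT_T1RHO_RANGES


class Preparation(Enum):
    """Magnetization preparation played before a readout."""

    IR = "ir"
    NONE = "none"
    T1RHO = "t1rho"
    T2PREP = "t2prep"


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue species.

    All times in milliseconds; ``m0`` is the equilibrium magnetization in
    arbitrary units.  Dictionary grids additionally require t2 <= t1rho <= t1.
    """

    t1: float
    t1rho: float
    t2: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t1", "t1rho", "t2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not np.isfinite(self.m0) or self.m0 < 0:
            raise ValueError(f"m0 must be finite and non-negative, got {self.m0}")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Timing and flip-angle parameters of the 5-heartbeat acquisition.

    Times in ms, flip angle in degrees, spin-lock amplitude in Hz.
    ``trigger_delay`` is the time from the R-wave to the first readout pulse;
    when ``None`` it defaults to ``rr_interval - 300`` ms, capped so the
    readout window (segments_per_hb * tr) stays inside the RR interval and
    floored at the inversion time so the IR pulse falls in the same beat.
    ``centric_fraction`` is the fraction of the echo train averaged into each
    dictionary point (centric reordering puts the k-space centre first).
    """

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
    trigger_delay: float | None = None
    n_prep_cycles: int = 3
    centric_fraction: float = 0.30
    idle_fifth: bool = False

    def __post_init__(self) -> None:
        if self.segments_per_hb < 1:
            raise ValueError("segments_per_hb must be >= 1")
        if self.ti < 0:
            raise ValueError("ti must be >= 0")
        if not (0.0 < self.centric_fraction <= 1.0):
            raise ValueError("centric_fraction must lie in (0, 1]")
        if self.readout_duration > self.rr_interval - self.resolved_trigger_delay + 1e-9:
            raise ValueError(
                "readout window exceeds RR interval: "
                f"{self.segments_per_hb} x {self.tr} ms does not fit after the trigger delay"
            )

    @property
    def readout_duration(self) -> float:
        """Acquisition window per heartbeat [ms]."""
        return self.segments_per_hb * self.tr

    @property
    def resolved_trigger_delay(self) -> float:
        if self.trigger_delay is not None:
            return self.trigger_delay
        td = self.rr_interval - 300.0
        td = min(td, self.rr_interval - self.readout_duration)
        return max(td, 0.0)

    @property
    def n_centric(self) -> int:
        """Number of early-readout TRs averaged into a dictionary point."""
        return max(1, int(round(self.centric_fraction * self.segments_per_hb)))

    def to_dict(self) -> dict:
        return {
            "rr_interval": self.rr_interval,
            "ti": self.ti,
            "tsl": self.tsl,
            "sla": self.sla,
            "t2prep_dur": self.t2prep_dur,
            "tr": self.tr,
            "te1": self.te1,
            "te2": self.te2,
            "flip_angle": self.flip_angle,
            "segments_per_hb": self.segments_per_hb,
            "trigger_delay": self.resolved_trigger_delay,
            "n_prep_cycles": self.n_prep_cycles,
            "centric_fraction": self.centric_fraction,
            "idle_fifth": self.idle_fifth,
        }


@dataclass
class SignalDictionary:
    """Unit-norm signed 5-point signal atoms on a (T1, T1rho, T2) grid."""

    t1: np.ndarray  # [n] ms
    t1rho: np.ndarray  # [n] ms
    t2: np.ndarray  # [n] ms
    atoms: np.ndarray  # [n, 5], each row unit L2 norm, signed
    acq: AcquisitionSpec

    def __len__(self) -> int:
        return self.atoms.shape[0]


# ---------------------------------------------------------------------------
# elementary events
# ---------------------------------------------------------------------------

def _relax(mz, m0, t1, dt):
    """Free T1 recovery of Mz towards m0 over dt milliseconds."""
    return m0 + (mz - m0) * np.exp(-dt / t1)


def apply_preparation(mz, prep: Preparation, tissue: TissueParams, acq: AcquisitionSpec):
    """Apply one instantaneous preparation module to longitudinal magnetization."""
    if prep is Preparation.IR:
        return -mz
    if prep is Preparation.NONE:
        return mz
    if prep is Preparation.T1RHO:
        return mz * np.exp(-acq.tsl / tissue.t1rho)
    if prep is Preparation.T2PREP:
        return mz * np.exp(-acq.t2prep_dur / tissue.t2)
    raise ValueError(f"unknown preparation {prep!r}")


def simulate_readout(mz_in, tissue: TissueParams, acq: AcquisitionSpec):
    """Simulate one segmented GRE echo train.

    Per TR the RF pulse samples ``signal = Mz * sin(FA)`` and leaves
    ``Mz * cos(FA)`` behind, which then recovers towards m0 over TR.

    Returns ``(signal_per_tr, mz_out)`` where ``signal_per_tr`` has shape
    ``(segments_per_hb, *broadcast)`` and ``mz_out`` is the magnetization at
    the end of the last TR interval.
    """
    if acq.segments_per_hb < 1:
        raise ValueError("segments_per_hb must be >= 1")
    fa = np.deg2rad(acq.flip_angle)
    sin_fa, cos_fa = np.sin(fa), np.cos(fa)
    mz = np.asarray(mz_in, dtype=float)
    signals = np.empty((acq.segments_per_hb,) + mz.shape, dtype=float)
    for k in range(acq.segments_per_hb):
        signals[k] = mz * sin_fa
        mz = _relax(mz * cos_fa, tissue.m0, tissue.t1, acq.tr)
    return signals, mz


_HB_PREPS = (
    Preparation.IR,
    Preparation.NONE,
    Preparation.T1RHO,
    Preparation.T2PREP,
    Preparation.NONE,
)


def simulate_shot_train(tissue: TissueParams, acq: AcquisitionSpec) -> np.ndarray:
    """Simulate the repeating 5-heartbeat schedule and return the 5 contrast points.

    ``n_prep_cycles`` sets of 5 heartbeats are simulated (the first sets drive
    Mz to its periodic steady state).  For the last set, each contrast point is
    the mean of the first ``n_centric`` per-TR signals of its heartbeat.  With
    ``acq.idle_fifth`` the 5th heartbeat plays no readout (pure recovery) and
    the 5th point is copied from the no-preparation heartbeat 2.

    Values are signed: the IR contrast may be negative.  Broadcasts over array
    ``tissue`` fields.
    """
    td = acq.resolved_trigger_delay
    t_after = acq.rr_interval - td - acq.readout_duration
    nc = acq.n_centric
    mz = np.asarray(tissue.m0, dtype=float) * np.ones(np.shape(tissue.t1))
    out = [None] * N_CONTRASTS
    for cycle in range(acq.n_prep_cycles):
        last = cycle == acq.n_prep_cycles - 1
        for hb, prep in enumerate(_HB_PREPS):
            if prep is Preparation.IR:
                # IR pulse is placed TI before the first readout pulse.
                t_ir = max(td - acq.ti, 0.0)
                mz = _relax(mz, tissue.m0, tissue.t1, t_ir)
                mz = apply_preparation(mz, prep, tissue, acq)
                mz = _relax(mz, tissue.m0, tissue.t1, td - t_ir)
            else:
                mz = _relax(mz, tissue.m0, tissue.t1, td)
                mz = apply_preparation(mz, prep, tissue, acq)
            if hb == 4 and acq.idle_fifth:
                mz = _relax(mz, tissue.m0, tissue.t1, acq.rr_interval - td)
                if last:
                    out[4] = out[1]
                continue
            sig, mz = simulate_readout(mz, tissue, acq)
            if last:
                out[hb] = sig[:nc].mean(axis=0)
            mz = _relax(mz, tissue.m0, tissue.t1, t_after)
    return np.stack(out, axis=-1)


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def parse_range_spec(ranges: Sequence[Sequence[float]]) -> np.ndarray:
    """Expand ``[start, step, stop]`` triplets (stop inclusive) into a sorted,
    de-duplicated value array."""
    vals: list[float] = []
    for start, step, stop in ranges:
        if step <= 0 or stop < start:
            raise ValueError(f"invalid range triplet [{start}, {step}, {stop}]")
        n = int(round((stop - start) / step))
        vals.extend(start + step * np.arange(n + 1))
    arr = np.unique(np.round(np.asarray(vals, dtype=float), 9))
    if not np.all(np.diff(arr) > 0):
        raise ValueError("range spec must produce strictly increasing values")
    return arr


def build_dictionary(
    acq: AcquisitionSpec,
    t1_ranges: Sequence[Sequence[float]] = DEFAULT_T1_RANGES,
    t1rho_ranges: Sequence[Sequence[float]] = DEFAULT_T1RHO_RANGES,
    t2_ranges: Sequence[Sequence[float]] = DEFAULT_T2_RANGES,
) -> SignalDictionary:
    """Simulate the signal dictionary on the Cartesian (T1, T1rho, T2) grid.

    The grid is the Cartesian product of the three value lists filtered by the
    physical constraint t2 <= t1rho <= t1; each atom is the 5-point signed
    signal of :func:`simulate_shot_train`, normalized to unit L2 norm.
    """
    t1v = parse_range_spec(t1_ranges)
    t1rv = parse_range_spec(t1rho_ranges)
    t2v = parse_range_spec(t2_ranges)
    t1g, t1rg, t2g = np.meshgrid(t1v, t1rv, t2v, indexing="ij")
    keep = (t2g <= t1rg) & (t1rg <= t1g)
    t1f, t1rf, t2f = t1g[keep], t1rg[keep], t2g[keep]
    if t1f.size == 0:
        raise ValueError("dictionary grid is empty after the t2<=t1rho<=t1 constraint")
    tissue = SimpleNamespace(t1=t1f, t1rho=t1rf, t2=t2f, m0=np.ones_like(t1f))
    atoms = simulate_shot_train(tissue, acq)
    norms = np.linalg.norm(atoms, axis=-1, keepdims=True)
    atoms = atoms / norms
    return SignalDictionary(t1=t1f, t1rho=t1rf, t2=t2f, atoms=atoms, acq=acq)
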