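"""HD-PROST: motion-compensated patch-tensor low-rank reconstruction.

The multi-contrast images X (all contrast/echo channels jointly) are
reconstructed by ADMM on the Lagrangian

    L(X, T, Y) = ||E X - K||_F^2 + lambda sum_v ||T_v||_*
                 + mu/2 sum_v ||T_v - P_v(X) - Y_v / mu||_F^2,

where P_v stacks, for each reference voxel v on a stride grid, the n_similar
most similar image patches across all channels into a 3rd-order tensor
(patch-voxels x similar-patches x channels).  Each outer iteration solves
(i) the data-consistency subproblem by conjugate gradient on the normal
equations ("iterative SENSE"), (ii) the tensor denoising subproblem by
truncated higher-order SVD, and (iii) updates the multipliers
Y <- Y + mu (P(X) - T).

Patch similarity is measured by the L2 distance between patches of the
channel-averaged magnitude image; similar-patch positions are selected once
from the initial reconstruction and kept fixed across outer iterations so the
multipliers stay aligned with their tensors.  Patch windows are clipped to
valid in-volume patch positions at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import EncodingOperator

__all__ = [
    "HDProstConfig",
    "PatchSelection",
    "patch_grid",
    "patch_select",
    "select_all_patches",
    "extract_patches",
    "aggregate_patches",
    "hosvd_denoise",
    "data_consistency_step",
    "hd_prost_reconstruct",
]


@dataclass
class HDProstConfig:
    """Regularization and patch parameters of the ADMM reconstruction."""

    lam: float = 0.04
    mu: float = 0.1
    outer_iters: int = 5
    sense_iters: int = 5
    search_window: int = 20
    patch_size: int = 5
    n_similar: int = 20
    patch_offset: int = 4
    cg_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("mu", "outer_iters", "sense_iters", "search_window",
                     "patch_size", "n_similar", "patch_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.patch_size > self.search_window:
            raise ValueError("patch_size must not exceed search_window")


@dataclass
class PatchSelection:
    """Fixed similar-patch geometry: corners of selected patches per reference."""

    refs: np.ndarray  # [n_refs, 3] reference patch corners
    similar: np.ndarray  # [n_refs, n_similar] flat corner indices
    corner_shape: tuple[int, int, int]  # valid-corner grid dims per axis
    patch_size: int
    counts: np.ndarray  # [nx, ny, nz] aggregation coverage counts


def _axis_positions(dim: int, patch: int, offset: int) -> np.ndarray:
    """Stride-grid patch corners along one axis, end-inclusive (full tiling)."""
    if dim < patch:
        raise ValueError(f"volume dimension {dim} smaller than patch {patch}")
    pos = list(range(0, dim - patch + 1, offset))
    if pos[-1] != dim - patch:
        pos.append(dim - patch)
    return np.asarray(pos)


def patch_grid(shape: tuple[int, int, int], cfg: HDProstConfig) -> np.ndarray:
    """Reference patch corners on the stride grid, [n_refs, 3]."""
    ax = [_axis_positions(d, cfg.patch_size, cfg.patch_offset) for d in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def _sliding_norms(sim: np.ndarray, p: int):
    """Contiguous sliding patches of the similarity volume and their sq-norms."""
    from numpy.lib.stride_tricks import sliding_window_view

    sw = sliding_window_view(sim, (p, p, p))  # [cx, cy, cz, p, p, p]
    sw = np.ascontiguousarray(sw, dtype=np.float64)
    cshape = sw.shape[:3]
    flat = sw.reshape(cshape + (p**3,))
    n2 = np.einsum("xyzp,xyzp->xyz", flat, flat)
    return flat, n2, cshape


def patch_select(
    X: np.ndarray,
    v: tuple[int, int, int],
    cfg: HDProstConfig,
    sim: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Select the n_similar most similar patch corners for reference corner v.

    Similarity is the L2 distance between patches of ``sim`` (channel-averaged
    magnitude of X by default); candidates are all valid patch corners within
    the search window centred on v.  The reference patch itself has distance
    zero and is always selected; ties are broken by scan (raster) order.
    Returns ``(T_v, corners)`` with ``T_v`` of shape
    [patch_voxels, n_similar, n_channels].
    """
    if sim is None:
        sim = np.mean(np.abs(X), axis=0)
    p = cfg.patch_size
    flat, n2, cshape = _sliding_norms(sim, p)
    corners = _select_for_ref(np.asarray(v), flat, n2, cshape, cfg)
    T = _gather_tensor(X, corners, cshape, p, cfg.n_similar)
    return T, corners


def _select_for_ref(v, flat, n2, cshape, cfg: HDProstConfig) -> np.ndarray:
    half = cfg.search_window // 2
    sl = []
    for a in range(3):
        lo = max(int(v[a]) - half, 0)
        hi = min(int(v[a]) + half, cshape[a] - 1)
        sl.append((lo, hi + 1))
    block = flat[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
    bn2 = n2[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
    ref = flat[tuple(int(c) for c in v)]
    d = bn2 - 2.0 * (block @ ref) + float(ref @ ref)
    dflat = d.ravel()
    k = min(cfg.n_similar, dflat.size)
    # stable selection: smallest distance first, raster order breaks ties
    idx = np.argsort(np.round(dflat, 12), kind="stable")[:k]
    if k < cfg.n_similar:  # tiny volumes: repeat best matches
        idx = np.concatenate([idx, idx[: cfg.n_similar - k]])
        idx = idx[: cfg.n_similar]
    bx, by, bz = np.unravel_index(idx, d.shape)
    gx, gy, gz = bx + sl[0][0], by + sl[1][0], bz + sl[2][0]
    return (gx * cshape[1] + gy) * cshape[2] + gz


def _gather_tensor(X, corner_flat, cshape, p, n_similar) -> np.ndarray:
    C = X.shape[0]
    cx, cy, cz = np.unravel_index(corner_flat, cshape)
    T = np.empty((p**3, n_similar, C), dtype=np.complex128)
    for j in range(n_similar):
        blk = X[:, cx[j]:cx[j] + p, cy[j]:cy[j] + p, cz[j]:cz[j] + p]
        T[:, j, :] = blk.reshape(C, -1).T
    return T


def select_all_patches(X: np.ndarray, cfg: HDProstConfig) -> PatchSelection:
    """Run similar-patch selection for every stride-grid reference voxel."""
    sim = np.mean(np.abs(X), axis=0)
    p = cfg.patch_size
    refs = patch_grid(sim.shape, cfg)
    flat, n2, cshape = _sliding_norms(sim, p)
    similar = np.empty((len(refs), cfg.n_similar), dtype=np.int64)
    for i, v in enumerate(refs):
        similar[i] = _select_for_ref(v, flat, n2, cshape, cfg)
    counts = np.zeros(sim.shape)
    ones = np.ones((p, p, p))
    cx, cy, cz = np.unravel_index(similar.ravel(), cshape)
    for x0, y0, z0 in zip(cx, cy, cz):
        counts[x0:x0 + p, y0:y0 + p, z0:z0 + p] += ones
    return PatchSelection(refs=refs, similar=similar, corner_shape=cshape,
                          patch_size=p, counts=counts)


def extract_patches(X: np.ndarray, selection: PatchSelection) -> np.ndarray:
    """P(X): gather all patch tensors, [n_refs, patch_voxels, n_similar, C]."""
    p = selection.patch_size
    n_refs, n_sim = selection.similar.shape
    C = X.shape[0]
    out = np.empty((n_refs, p**3, n_sim, C), dtype=np.complex128)
    cx, cy, cz = np.unravel_index(selection.similar, selection.corner_shape)
    for i in range(n_refs):
        for j in range(n_sim):
            blk = X[:, cx[i, j]:cx[i, j] + p, cy[i, j]:cy[i, j] + p,
                    cz[i, j]:cz[i, j] + p]
            out[i, :, j, :] = blk.reshape(C, -1).T
    return out


def aggregate_patches(T: np.ndarray, selection: PatchSelection,
                      shape: tuple[int, int, int], average: bool = True) -> np.ndarray:
    """P^H(T): scatter-add patch tensors back; optionally divide by coverage."""
    p = selection.patch_size
    n_refs, _, n_sim, C = T.shape
    out = np.zeros((C,) + shape, dtype=np.complex128)
    cx, cy, cz = np.unravel_index(selection.similar, selection.corner_shape)
    for i in range(n_refs):
        for j in range(n_sim):
            blk = T[i, :, j, :].T.reshape(C, p, p, p)
            out[:, cx[i, j]:cx[i, j] + p, cy[i, j]:cy[i, j] + p,
                cz[i, j]:cz[i, j] + p] += blk
    if average:
        cnt = np.maximum(selection.counts, 1e-30)
        out = out / cnt[None]
    return out


# ---------------------------------------------------------------------------
# HOSVD denoising
# ---------------------------------------------------------------------------

def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def hosvd_denoise(T: np.ndarray, lam: float, rule: str = "rank") -> np.ndarray:
    """Denoise one 3rd-order tensor by HOSVD truncation.

    Mode-wise singular bases are computed from the (small) Gram matrices of
    the unfoldings.  With the default ``rule="rank"`` the multilinear rank is
    truncated: each mode keeps the singular directions whose singular value is
    at least ``lam * sigma_max`` of that mode (classical truncated HOSVD).
    ``rule="core"`` instead zeroes individual core coefficients with magnitude
    below ``lam * max|core|``.  ``lam = 0`` is the identity.  Operates
    directly on complex entries.
    """
    if T.ndim != 3:
        raise ValueError("expected a 3rd-order tensor")
    if lam == 0:
        return T.copy()
    us = []
    svals = []
    for mode in range(3):
        a = _unfold(T, mode)
        w, u = np.linalg.eigh(a @ a.conj().T)
        w, u = w[::-1], u[:, ::-1]  # descending
        svals.append(np.sqrt(np.maximum(w, 0.0)))
        us.append(u)
    if rule == "rank":
        for mode in range(3):
            s = svals[mode]
            keep = int(np.count_nonzero(s >= lam * s[0])) if s[0] > 0 else 1
            us[mode] = us[mode][:, :max(keep, 1)]
    elif rule != "core":
        raise ValueError(f"unknown truncation rule {rule!r}")
    core = np.einsum("ia,jb,kc,ijk->abc", us[0].conj(), us[1].conj(), us[2].conj(), T,
                     optimize=True)
    if rule == "core":
        thresh = lam * np.abs(core).max()
        core = np.where(np.abs(core) < thresh, 0.0, core)
    return np.einsum("ia,jb,kc,abc->ijk", us[0], us[1], us[2], core, optimize=True)


def _denoise_all(PX: np.ndarray, lam: float) -> np.ndarray:
    out = np.empty_like(PX)
    for i in range(PX.shape[0]):
        out[i] = hosvd_denoise(PX[i], lam)
    return out


# ---------------------------------------------------------------------------
# ADMM
# ---------------------------------------------------------------------------

def data_consistency_step(
    E: EncodingOperator,
    K: np.ndarray,
    cfg: HDProstConfig,
    selection: PatchSelection | None = None,
    target: np.ndarray | None = None,
    X_init: np.ndarray | None = None,
    mu: float | None = None,
) -> np.ndarray:
    """Regularized SENSE subproblem.

    Approximately solves the coverage-weighted subproblem
    ``argmin_X ||E X - K||^2 + mu/2 sum_v w_v ||target_v - P_v X||^2``
    with ``w_v = 1/count`` (overlap averaging), whose normal equations are
    ``(E^H E + (mu/2) I) X = E^H K + (mu/2) avg(P^H target)`` because the
    coverage-weighted ``P^H W P`` is exactly the identity.  Solved by
    conjugate gradient, warm-started at ``X_init``; ``mu = 0`` (or no
    selection) gives plain iterative SENSE.  Raises if the residual grows by
    more than 10x (divergence).
    """
    mu = cfg.mu if mu is None else mu
    shape = E.shape
    rhs = E.adjoint(K)
    use_reg = mu > 0 and selection is not None and target is not None
    if use_reg:
        rhs = rhs + (mu / 2) * aggregate_patches(target, selection, shape, average=True)

    def normal_op(x):
        y = E.normal(x)
        if use_reg:
            y = y + (mu / 2) * x
        return y

    x = np.zeros_like(rhs) if X_init is None else X_init.astype(np.complex128)
    r = rhs - normal_op(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    rs0 = rs
    rhs_norm = np.linalg.norm(rhs)
    for _ in range(cfg.sense_iters):
        if np.sqrt(rs) <= cfg.cg_tol * max(rhs_norm, 1e-30):
            break
        ap = normal_op(p)
        alpha = rs / np.vdot(p, ap).real
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.vdot(r, r).real
        if rs_new > 100 * rs0:
            raise RuntimeError("CG diverged in the data-consistency step")
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def hd_prost_reconstruct(
    K: np.ndarray,
    E: EncodingOperator,
    cfg: HDProstConfig,
    verbose: bool = False,
) -> tuple[np.ndarray, list[float]]:
    """Full ADMM reconstruction; returns (X, data-consistency residual history).

    X has one volume per contrast/echo channel.  The pipeline is deterministic
    given (K, E, cfg): there is no randomness inside the reconstruction.
    """
    shape = E.shape
    X = E.adjoint(K)  # zero-filled, motion-compensated starting point
    selection = select_all_patches(X, cfg)
    T = extract_patches(X, selection)
    Y = np.zeros_like(T)
    history: list[float] = []
    for it in range(cfg.outer_iters):
        X = data_consistency_step(E, K, cfg, selection=selection,
                                  target=T - Y / cfg.mu, X_init=X)
        PX = extract_patches(X, selection)
        T = _denoise_all(PX + Y / cfg.mu, cfg.lam)
        Y = Y + cfg.mu * (PX - T)
        res = float(np.linalg.norm(E.forward(X) - K) / max(np.linalg.norm(K), 1e-30))
        history.append(res)
        if verbose:
            print(f"  ADMM iter {it + 1}/{cfg.outer_iters}: |EX-K|/|K| = {res:.3e}")
    return X, history
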