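"""Deterministic rigid registration on attenuation-map volumes.

The dual-isotope acquisition may be slightly displaced relative to the
Ho-only acquisition (the patient stays on the table, so motion is rigid and
small). Alignment is estimated on the attenuation maps — the in-silico
stand-in for the low-dose CT — by maximizing normalized mutual information
over a deterministic coarse grid of integer-voxel translations and a small
set of in-plane rotations, followed by local Nelder–Mead refinement of all
six parameters. Determinism is the point: the same inputs always return the
same transform, which a stochastic-gradient optimizer would not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geometry import RigidTransform, resample_into
from .volume import VoxelVolume

__all__ = ["RegistrationConfig", "RegistrationResult", "register_rigid"]


@dataclass(frozen=True)
class RegistrationConfig:
    metric: str = "nmi"  # "nmi" or "ncc"
    bins: int = 32
    translation_range_vox: int = 3
    rotation_scan_deg: tuple[float, ...] = (-6.0, -3.0, 0.0, 3.0, 6.0)
    refine: bool = True
    coarse_stride: int = 2  # voxel subsampling during the coarse scan
    # presmoothing of both inputs before metric evaluation; suppresses the
    # interpolation artifact that otherwise pins intensity metrics to
    # grid-aligned poses (one voxel width by default)
    presmooth_sigma_mm: float = 4.8


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    n_evaluations: int


def _support(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    thr_a = 1e-6 * max(float(a.max()), 1e-30)
    thr_b = 1e-6 * max(float(b.max()), 1e-30)
    return (a > thr_a) & (b > thr_b)


def _nmi(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    m = _support(a, b)
    if m.sum() < 8:
        return -np.inf
    h, _, _ = np.histogram2d(a[m], b[m], bins=bins)
    p = h / h.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    hxy = -(p[nz] * np.log(p[nz])).sum()
    hx = -(px[px > 0] * np.log(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log(py[py > 0])).sum()
    if hxy == 0:
        return 2.0
    return (hx + hy) / hxy


def _ncc(a: np.ndarray, b: np.ndarray, bins: int = 0) -> float:
    m = _support(a, b)
    if m.sum() < 8:
        return -np.inf
    av, bv = a[m] - a[m].mean(), b[m] - b[m].mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return -np.inf
    return float((av * bv).sum() / denom)


def register_rigid(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate the rigid motion of ``moving`` relative to ``fixed``.

    Returns a transform ``T`` such that ``resample_into(moving, T)`` aligns
    the moving volume onto the fixed frame; if the moving volume was created
    by moving the fixed one *by* ``M``, the estimate recovers ``T ~ M``.
    """
    config = config or RegistrationConfig()
    if not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("fixed and moving must share grid spacing")
    f = np.asarray(fixed.data, dtype=np.float64)
    g = np.asarray(moving.data, dtype=np.float64)
    if f.std() == 0 or g.std() == 0:
        raise ValueError("no gradient information: constant image")
    if config.presmooth_sigma_mm > 0:
        from scipy import ndimage

        sig = tuple(config.presmooth_sigma_mm / s for s in fixed.spacing)
        f = ndimage.gaussian_filter(f, sig)
        g = ndimage.gaussian_filter(g, sig)
        fixed = VoxelVolume(f, fixed.spacing, fixed.origin)
        moving = VoxelVolume(g, moving.spacing, moving.origin)
    metric = {"nmi": _nmi, "ncc": _ncc}[config.metric]
    n_eval = 0
    sp = np.asarray(fixed.spacing)
    stride = config.coarse_stride
    sub = (slice(None, None, stride),) * 3

    def score_volume(resampled: np.ndarray, coarse: bool) -> float:
        nonlocal n_eval
        n_eval += 1
        if coarse:
            return metric(f[sub], resampled[sub], config.bins)
        return metric(f, resampled, config.bins)

    # --- coarse scan: integer-voxel shifts (np.roll) x in-plane rotations
    r = config.translation_range_vox
    best = (-np.inf, RigidTransform())
    for rz in config.rotation_scan_deg:
        if rz == 0:
            rotated = g
        else:
            rotated = np.asarray(
                resample_into(moving, RigidTransform(rotation_deg=(0, 0, rz))).data
            )
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dz in range(-r, r + 1):
                    # rolling by -d samples moving at index+d: lookup map v+d
                    cand = np.roll(rotated, shift=(-dx, -dy, -dz), axis=(0, 1, 2))
                    s = score_volume(cand, coarse=True)
                    if s > best[0]:
                        best = (
                            s,
                            RigidTransform(
                                translation=tuple(np.array([dx, dy, dz]) * sp),
                                rotation_deg=(0.0, 0.0, rz),
                            ),
                        )
    t0 = best[1]

    def full_score(params: np.ndarray) -> float:
        T = RigidTransform(translation=tuple(params[:3]), rotation_deg=tuple(params[3:]))
        res = resample_into(moving, T, fixed_grid=fixed)
        return score_volume(np.asarray(res.data), coarse=False)

    x0 = np.array([*t0.translation, *t0.rotation_deg], dtype=float)
    best_full = full_score(x0)
    if not config.refine:
        return RegistrationResult(t0, best_full, n_eval)

    # identity short-circuit: if the coarse optimum is the identity and no
    # refinement step improves on it, return the exact identity so aligned
    # pairs round-trip bitwise
    res = optimize.minimize(
        lambda p: -full_score(p),
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 0.05,
            "fatol": 1e-7,
            "maxiter": 400,
            "initial_simplex": x0 + np.vstack([np.zeros(6), np.diag([2.4, 2.4, 2.4, 1.5, 1.5, 1.5])]),
        },
    )
    if -res.fun > best_full:
        params = res.x
        T = RigidTransform(translation=tuple(params[:3]), rotation_deg=tuple(params[3:]))
        return RegistrationResult(T, float(-res.fun), n_eval)
    return RegistrationResult(t0, best_full, n_eval)
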