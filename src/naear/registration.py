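"""Landmark-based thin-plate-spline fusion of sodium to structural imaging.

The workflow mirrors manual control-point registration: an observer places
9-16 paired landmarks (posterior-fossa bone-CSF and brain-CSF interfaces,
never the inner ear itself, which is the analysis target), the structural
volume is the fixed space and the sodium volume the moving space, and an
interpolating 3D thin-plate spline (radial kernel ``|r|``) maps every fixed
landmark exactly onto its moving partner.  Resampling is pull-back: for
each output voxel the transform supplies the moving-space location to
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage

__all__ = [
    "LandmarkSet",
    "SplineTransform",
    "LandmarkError",
    "fit_tps",
    "resample",
    "transfer_masks",
]


class LandmarkError(ValueError):
    """Degenerate landmark configuration (duplicates or coplanarity)."""


@dataclass
class LandmarkSet:
    """Paired control points in world millimetres.

    ``fixed`` are structural-space points, ``moving`` their sodium-space
    partners; 9-16 pairs is the intended operating range (a warning is
    issued outside it, not an error -- small synthetic cases are useful).
    """

    fixed: np.ndarray      # (n, 3)
    moving: np.ndarray     # (n, 3)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[1] != 3:
            raise ValueError("fixed and moving must both be (n, 3)")
        if not self.labels:
            self.labels = tuple(f"L-{i + 1}" for i in range(len(self.fixed)))
        if not 9 <= len(self.fixed) <= 16:
            warnings.warn(
                f"{len(self.fixed)} landmark pairs (9-16 is the intended range)",
                stacklevel=2,
            )
        d = np.linalg.norm(
            self.fixed[:, None, :] - self.fixed[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        dup = np.argwhere(d < 1e-9)
        if dup.size:
            i, j = dup[0]
            raise LandmarkError(
                f"duplicate fixed landmarks: {self.labels[i]} and {self.labels[j]}"
            )

    def __len__(self) -> int:
        return len(self.fixed)


@dataclass
class SplineTransform:
    """Interpolating 3D thin-plate spline, fixed space -> moving space.

    ``affine``/``translation`` hold the polynomial part; ``weights`` the
    per-landmark radial coefficients (kernel ``phi(r) = r``); ``centers``
    the fixed landmarks the kernel is anchored on.
    """

    affine: np.ndarray        # (3, 3)
    translation: np.ndarray   # (3,)
    weights: np.ndarray       # (n, 3)
    centers: np.ndarray       # (n, 3)
    kernel: str = "r"

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.affine.T + self.translation
        if len(self.centers):
            r = np.linalg.norm(
                pts[:, None, :] - self.centers[None, :, :], axis=-1
            )
            out = out + r @ self.weights
        return out

    def inverse(self, points: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
        """Numerically invert the transform (fixed-point on the affine part).

        Exact in one step for a pure affine transform; for mild nonrigid
        warps the iteration converges quadratically-enough in practice.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ainv = np.linalg.inv(self.affine)
        x = (pts - self.translation) @ ainv.T
        for _ in range(max_iter):
            resid = self(x) - pts
            if np.abs(resid).max() < tol:
                break
            x = x - resid @ ainv.T
        return x


def fit_tps(landmarks: LandmarkSet) -> SplineTransform:
    """Fit the interpolating spline through every landmark pair.

    Solves the standard bordered system (kernel block + affine polynomial,
    with the orthogonality side conditions) so that a purely affine
    correspondence yields zero radial weights and arbitrary pairs are
    matched exactly.  Requires at least 4 non-coplanar pairs.
    """
    f, m = landmarks.fixed, landmarks.moving
    n = len(landmarks)
    if n < 4:
        raise LandmarkError("need at least 4 landmark pairs")
    p = np.column_stack([np.ones(n), f])
    if np.linalg.matrix_rank(p, tol=1e-8) < 4:
        raise LandmarkError(
            "fixed landmarks are coplanar or collinear; the 3D spline is "
            f"singular (points: {', '.join(landmarks.labels)})"
        )
    k = np.linalg.norm(f[:, None, :] - f[None, :, :], axis=-1)
    a = np.zeros((n + 4, n + 4))
    a[:n, :n] = k
    a[:n, n:] = p
    a[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = m
    try:
        sol = linalg.solve(a, rhs)
    except linalg.LinAlgError as exc:  # pragma: no cover - rank check above
        raise LandmarkError(f"singular landmark system: {exc}") from exc
    weights = sol[:n]
    translation = sol[n]
    affine = sol[n + 1:].T
    return SplineTransform(
        affine=affine, translation=translation, weights=weights, centers=f.copy()
    )


def _voxel_to_world(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _world_to_voxel(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def resample(
    volume: np.ndarray,
    transform: SplineTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    moving_affine: np.ndarray,
    interpolation: str = "linear",
) -> np.ndarray:
    """Pull-back resampling of a moving-space volume onto a target grid.

    Each target voxel centre is mapped through ``transform`` into moving
    world space and the volume is interpolated there (``linear`` for
    intensities, ``nearest`` for labels); locations outside the moving
    field of view become 0.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if abs(np.linalg.det(np.asarray(target_affine)[:3, :3])) < 1e-12:
        raise ValueError("target affine is singular")
    idx = np.indices(target_shape).reshape(3, -1).T.astype(float)
    world = _voxel_to_world(np.asarray(target_affine), idx)
    moving_world = transform(world)
    moving_idx = _world_to_voxel(np.asarray(moving_affine), moving_world)
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(volume, dtype=float),
        moving_idx.T,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return out.reshape(target_shape)


def transfer_masks(
    masks: dict[str, np.ndarray],
    transform: SplineTransform,
    structural_affine: np.ndarray,
    sodium_shape: tuple[int, int, int],
    sodium_affine: np.ndarray,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, float]]]:
    """Carry binary structural-space masks onto the sodium grid.

    ``transform`` maps structural (fixed) world coordinates to sodium
    (moving) world coordinates, so each sodium voxel is filled from the
    structural mask at the *inverse*-mapped location, nearest-neighbour.
    Returns the transferred masks plus a per-mask report of voxel counts
    and mm^3 volumes before and after; an empty output raises a warning
    (the structure fell outside the field of view).
    """
    report: dict[str, dict[str, float]] = {}
    out: dict[str, np.ndarray] = {}
    vox_in = abs(np.linalg.det(np.asarray(structural_affine)[:3, :3]))
    vox_out = abs(np.linalg.det(np.asarray(sodium_affine)[:3, :3]))

    idx = np.indices(sodium_shape).reshape(3, -1).T.astype(float)
    sodium_world = _voxel_to_world(np.asarray(sodium_affine), idx)
    structural_world = transform.inverse(sodium_world)
    structural_idx = _world_to_voxel(np.asarray(structural_affine), structural_world)

    for name, mask in masks.items():
        mask = np.asarray(mask)
        if not np.array_equal(np.unique(mask), np.unique(mask.astype(bool))):
            raise ValueError(f"mask {name!r} is not binary")
        vals = ndimage.map_coordinates(
            mask.astype(np.uint8), structural_idx.T, order=0,
            mode="constant", cval=0,
        )
        transferred = vals.reshape(sodium_shape).astype(bool)
        if not transferred.any():
            warnings.warn(
                f"mask {name!r} is empty after transfer (outside FOV?)",
                stacklevel=2,
            )
        report[name] = {
            "voxels_before": int(mask.sum()),
            "volume_before_mm3": float(mask.sum() * vox_in),
            "voxels_after": int(transferred.sum()),
            "volume_after_mm3": float(transferred.sum() * vox_out),
        }
        out[name] = transferred
    return out, report
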