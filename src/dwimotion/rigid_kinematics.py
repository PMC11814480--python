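"""Rigid-body kinematics and the voxel-wise RMS displacement measure.

The movement measure everything downstream uses is defined directly on
voxels: apply two rigid poses to every intracerebral voxel, take the
displacement between the two images of each voxel, and average the
squared displacements over the mask —

    RMS(a, b)^2 = mean_x | T_b(x) - T_a(x) |^2 .

Poses rotate about the origin of the mask coordinate frame, with
rotation composed as R = Rx(rx) · Ry(ry) · Rz(rz) (a package-wide
convention; both the simulator and this oracle use it, so the pipeline
is self-consistent). Mask coordinates are therefore expressed relative
to the rotation center; :func:`make_spherical_mask` builds masks
centered on it.

The mean over voxels collapses to a closed form: writing M = R_b - R_a,
d = t_b - t_a, S = mean(x xᵀ) and x̄ = mean(x) over mask voxels,

    RMS^2 = tr(Mᵀ M S) + 2 dᵀ M x̄ + |d|^2 ,

which is exact (no small-angle approximation) and O(1) per pose pair
once S is cached. In particular a pure translation gives RMS = |t|
independent of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np

from .eddy_io import MotionTrace, RMSSeries
from .errors import ValidationError

__all__ = [
    "BrainMask",
    "RigidPose",
    "rotation_matrix",
    "pose_to_matrix",
    "rms_displacement",
    "trace_to_rms_series",
    "make_spherical_mask",
    "load_mask_tsv",
]


@dataclass(frozen=True)
class RigidPose:
    """A rigid pose: translation ``t`` (mm) and rotation ``r`` (radians
    about x, y, z, composed Rx·Ry·Rz)."""

    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t).all() and np.isfinite(self.r).all()):
            raise ValidationError("pose parameters must be finite")


class BrainMask:
    """Coordinates (mm) of intracerebral voxels, expressed relative to
    the rotation center (the coordinate origin)."""

    def __init__(self, voxel_coords: np.ndarray) -> None:
        coords = np.asarray(voxel_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ValidationError("mask must be a non-empty (n, 3) coordinate array")
        if not np.isfinite(coords).all():
            raise ValidationError("mask coordinates must be finite")
        self.voxel_coords = coords

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    @cached_property
    def centroid(self) -> np.ndarray:
        return self.voxel_coords.mean(axis=0)

    @cached_property
    def second_moment(self) -> np.ndarray:
        """S = mean over voxels of x xᵀ (uncentered)."""
        x = self.voxel_coords
        return (x.T @ x) / x.shape[0]


def rotation_matrix(r: np.ndarray | tuple[float, float, float]) -> np.ndarray:
    """3x3 rotation R = Rx(rx) · Ry(ry) · Rz(rz), angles in radians."""
    rx, ry, rz = (float(v) for v in r)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def pose_to_matrix(pose: RigidPose, center: np.ndarray | None = None) -> np.ndarray:
    """4x4 homogeneous transform for ``pose``.

    The map is x ↦ R (x - c) + c + t with c the rotation center
    (default: the origin).
    """
    R = rotation_matrix(pose.r)
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = c - R @ c + np.asarray(pose.t, dtype=float)
    return T


def rms_displacement(pose_a: RigidPose, pose_b: RigidPose, mask: BrainMask) -> float:
    """RMS over mask voxels of the displacement between the two poses'
    images of each voxel (mm). Symmetric in its pose arguments, >= 0,
    and exactly |t_b - t_a| when both rotations agree."""
    if not isinstance(mask, BrainMask):
        mask = BrainMask(np.asarray(mask))
    M = rotation_matrix(pose_b.r) - rotation_matrix(pose_a.r)
    d = np.asarray(pose_b.t, dtype=float) - np.asarray(pose_a.t, dtype=float)
    # mean |M x + d|^2 expanded over the mask's first and second moments
    msq = float(
        np.sum((M.T @ M) * mask.second_moment) + 2.0 * d @ (M @ mask.centroid) + d @ d
    )
    return float(np.sqrt(max(msq, 0.0)))


def trace_to_rms_series(trace: MotionTrace, mask: BrainMask) -> RMSSeries:
    """Ground-truth RMS series for a motion trace.

    ``abs_rms[k]`` is the RMS displacement between volume 0 and volume k,
    ``rel_rms[k]`` between volumes k-1 and k; both are 0 at k = 0.
    """
    n = trace.n_volumes
    poses = [RigidPose(t=tuple(trace.trans[k]), r=tuple(trace.rot[k])) for k in range(n)]
    abs_rms = np.zeros(n)
    rel_rms = np.zeros(n)
    for k in range(1, n):
        abs_rms[k] = rms_displacement(poses[0], poses[k], mask)
        rel_rms[k] = rms_displacement(poses[k - 1], poses[k], mask)
    return RMSSeries(abs_rms=abs_rms, rel_rms=rel_rms)


def make_spherical_mask(radius: float = 80.0, spacing: float = 4.0) -> BrainMask:
    """Regular grid of points with Euclidean norm <= radius, centered at
    the origin, in deterministic lexicographic order.

    Defaults approximate an adult head (radius 80 mm) at a spacing coarse
    enough to stay fast (~8,000 points at 4 mm).
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if not 0 < spacing <= radius:
        raise ValidationError("spacing must be in (0, radius]")
    n = int(np.floor(radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = np.einsum("ij,ij->i", pts, pts) <= radius**2 + 1e-9
    return BrainMask(pts[keep])


def load_mask_tsv(path: str | Path) -> BrainMask:
    """Load a mask from a 3-column whitespace/tab-delimited coordinate file."""
    coords = np.loadtxt(path, ndmin=2)
    if coords.shape[1] != 3:
        raise ValidationError(f"{path}: mask file must have exactly 3 columns")
    return BrainMask(coords)
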