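"""Trajectory transformations and behavioral measures.

Implements the visuomotor rotation (VMR) applied to cursor velocity, the
shared target/perturbation reference frame that lets trajectories to all eight
targets (and sessions with opposite rotation directions) be averaged, the
midpoint angular error used to quantify adaptation, and the deflection measure
used to read out visual-like vs motor-like encoding from reconstructed
trajectories.

Sign conventions
----------------
Rotations are counterclockwise-positive about +Z. In the aligned frame the
``along_perturbation`` axis points in the direction of the applied visual
rotation, so positive deflections / angular errors mean "toward the visual
feedback" and negative ones mean "toward the compensatory motor side".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignedTrajectory",
    "AngularError",
    "apply_vmr",
    "align_to_target_frame",
    "midpoint_angle",
    "deflection",
    "average_aligned",
]


@dataclass
class AngularError:
    """Signed midpoint angular error of one trial (degrees)."""

    alpha_deg: float
    trial_index: int = -1
    phase: str = ""

    def __post_init__(self) -> None:
        if not -180.0 <= self.alpha_deg <= 180.0:
            raise ValueError("alpha_deg outside [-180, 180]")


@dataclass
class AlignedTrajectory:
    """A trajectory in the shared target-axis / perturbation-axis frame.

    ``along_target`` is the coordinate (mm) on the center-to-target axis,
    ``along_perturbation`` the coordinate on the orthogonal in-plane axis with
    positive sign toward the applied visual rotation. The first sample is the
    origin. ``samples``, when present, holds the per-point stack of the
    trajectories that were averaged (for bootstrapping).
    """

    along_target: np.ndarray
    along_perturbation: np.ndarray
    rotation_sign: int = 1
    samples: np.ndarray | None = None   # (n_traj, n_points, 2) for averages

    def __post_init__(self) -> None:
        self.along_target = np.asarray(self.along_target, dtype=float)
        self.along_perturbation = np.asarray(self.along_perturbation, dtype=float)
        if self.along_target.shape != self.along_perturbation.shape:
            raise ValueError("axis arrays must have equal length")
        if self.rotation_sign not in (-1, 1):
            raise ValueError("rotation_sign must be +1 (CCW) or -1 (CW)")

    def __len__(self) -> int:
        return self.along_target.size

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.along_target, self.along_perturbation])


def _rot2(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, -s], [s, c]])


def apply_vmr(points: np.ndarray, rotation_deg: float, direction: str = "CCW") -> np.ndarray:
    """Rotate the X-Y components of 3-D points/velocities about the Z axis.

    ``direction`` 'CCW' applies +rotation_deg, 'CW' applies -rotation_deg;
    Z components are untouched. Accepts a single point or an (..., 3) array.
    """
    if direction not in ("CW", "CCW"):
        raise ValueError("direction must be 'CW' or 'CCW'")
    p = np.asarray(points, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("expected 3-D points")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite coordinates")
    sign = 1.0 if direction == "CCW" else -1.0
    R = _rot2(np.deg2rad(sign * rotation_deg))
    out = p.copy()
    out[..., :2] = p[..., :2] @ R.T
    return out


def align_to_target_frame(traj_3d: np.ndarray, target: np.ndarray,
                          rotation_sign: int = 1) -> AlignedTrajectory:
    """Express a 3-D trajectory in the shared target/perturbation frame.

    The trajectory is first projected onto the X-Y perturbation plane, then
    re-expressed with one axis along the in-plane center-to-target direction
    and the orthogonal axis signed by ``rotation_sign`` so that sessions with
    opposite rotation directions are averageable. The first sample is shifted
    to the origin.
    """
    traj = np.asarray(traj_3d, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("trajectory must be (n, 3)")
    t_xy = np.asarray(target, dtype=float)[:2]
    norm = np.linalg.norm(t_xy)
    if norm < 1e-12:
        raise ValueError("target has no in-plane component; frame undefined")
    u = t_xy / norm
    # +90 deg rotation of u gives the CCW side; rotation_sign folds CW sessions
    perp = rotation_sign * np.array([-u[1], u[0]])
    p = traj[:, :2] - traj[0, :2]
    return AlignedTrajectory(p @ u, p @ perp, rotation_sign=rotation_sign)


def _point_at_path_fraction(xy: np.ndarray, fraction: float) -> np.ndarray:
    """Linear interpolation to the point at `fraction` of cumulative path length."""
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length trajectory")
    s = fraction * total
    idx = int(np.searchsorted(cum, s, side="right") - 1)
    idx = min(idx, len(seg) - 1)
    if seg[idx] == 0:
        return xy[idx]
    w = (s - cum[idx]) / seg[idx]
    return xy[idx] + w * (xy[idx + 1] - xy[idx])


def midpoint_angle(traj: AlignedTrajectory, *, method: str = "path",
                   trial_index: int = -1, phase: str = "") -> AngularError:
    """Signed angle of the halfway point relative to the center-to-target line.

    ``method='path'`` (default) takes the point at 50% of cumulative path
    length; ``method='time'`` the point at 50% of elapsed samples. Positive
    angles point toward the applied visual rotation.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples")
    xy = traj.xy
    if method == "path":
        pt = _point_at_path_fraction(xy, 0.5)
    elif method == "time":
        t = 0.5 * (len(traj) - 1)
        lo = int(np.floor(t))
        w = t - lo
        pt = xy[lo] if w == 0 else (1 - w) * xy[lo] + w * xy[min(lo + 1, len(traj) - 1)]
    else:
        raise ValueError("method must be 'path' or 'time'")
    if np.allclose(pt, 0):
        raise ValueError("midpoint at origin; angle undefined")
    alpha = np.degrees(np.arctan2(pt[1], pt[0]))
    return AngularError(float(alpha), trial_index=trial_index, phase=phase)


def deflection(traj: AlignedTrajectory, fraction: float, *, basis: str = "time") -> float:
    """Perturbation-axis coordinate at a fraction of the movement.

    ``basis='time'`` (default) indexes the sample closest to ``fraction`` of
    normalized movement time (fraction=1.0 is the end of movement);
    ``basis='path'`` uses cumulative path length instead.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if basis == "time":
        idx = int(round(fraction * (len(traj) - 1)))
        return float(traj.along_perturbation[idx])
    if basis == "path":
        pt = _point_at_path_fraction(traj.xy, fraction)
        return float(pt[1])
    raise ValueError("basis must be 'time' or 'path'")


def average_aligned(trajs: list[AlignedTrajectory], n_points: int = 100) -> AlignedTrajectory:
    """Pointwise average after resampling each trajectory to ``n_points``.

    Resampling is linear interpolation over normalized time. The result keeps
    the per-trajectory resampled stack in ``samples`` for bootstrapping.
    """
    if not trajs:
        raise ValueError("empty trajectory list")
    if any(len(t) < 2 for t in trajs):
        raise ValueError("each trajectory needs at least 2 samples")
    grid = np.linspace(0.0, 1.0, n_points)
    stack = np.empty((len(trajs), n_points, 2))
    for i, t in enumerate(trajs):
        src = np.linspace(0.0, 1.0, len(t))
        stack[i, :, 0] = np.interp(grid, src, t.along_target)
        stack[i, :, 1] = np.interp(grid, src, t.along_perturbation)
    mean = stack.mean(axis=0)
    return AlignedTrajectory(mean[:, 0], mean[:, 1],
                             rotation_sign=trajs[0].rotation_sign, samples=stack)
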