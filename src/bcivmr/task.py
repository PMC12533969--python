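"""Task geometry and session schedule for the 3D memory-guided center-out task.

The workspace is a cube centered on a fixation point; the eight reach targets
sit at its vertices. Time is discretized into non-overlapping 50 ms bins, the
cadence of the closed decoding loop. Coordinates are right-handed: X rightward,
Y upward, Z toward the subject; the visuomotor rotation acts in the X-Y
(fronto-parallel) plane only, counterclockwise positive about +Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["TaskConfig", "PerturbationSchedule", "make_targets"]


@dataclass
class TaskConfig:
    """Geometry and timing of the memory-guided center-out task.

    All durations are in milliseconds and must be positive multiples of
    ``bin_ms`` where they are binned. ``movement_ms`` is the nominal duration
    of the bell-shaped (minimum-jerk) reach command; it must not exceed
    ``movement_timeout_ms``.
    """

    cube_side: float = 70.0            # mm, target cube edge length
    n_targets: int = 8                 # cube vertices
    fixation_ms: int = 400
    cue_ms: int = 300
    planning_ms: int = 400
    variable_delay_max_ms: int = 600
    movement_timeout_ms: int = 1500
    movement_ms: int = 700             # nominal minimum-jerk reach duration
    bin_ms: int = 50
    hand_security_radius_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.cube_side <= 0:
            raise ValueError("cube_side must be positive")
        if self.n_targets != 8:
            raise ValueError("the center-out task uses the 8 cube vertices")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        for name in ("fixation_ms", "planning_ms", "variable_delay_max_ms",
                     "movement_timeout_ms", "movement_ms"):
            value = getattr(self, name)
            if value % self.bin_ms:
                raise ValueError(f"{name}={value} is not a multiple of bin_ms")
        if self.movement_ms > self.movement_timeout_ms:
            raise ValueError("movement_ms exceeds movement_timeout_ms")

    # -- bin bookkeeping ---------------------------------------------------
    @property
    def dt_s(self) -> float:
        return self.bin_ms / 1000.0

    @property
    def fixation_bins(self) -> int:
        return self.fixation_ms // self.bin_ms

    @property
    def cue_bins(self) -> int:
        # cue may not be a bin multiple (300/50 is); round up to cover it
        return -(-self.cue_ms // self.bin_ms)

    @property
    def planning_bins(self) -> int:
        return self.planning_ms // self.bin_ms

    @property
    def max_delay_bins(self) -> int:
        return self.variable_delay_max_ms // self.bin_ms

    @property
    def movement_bins(self) -> int:
        return self.movement_ms // self.bin_ms

    @property
    def trial_bins(self) -> int:
        """Fixed per-trial bin count (delay shorter than max is padded by hold)."""
        return (self.fixation_bins + self.cue_bins + self.planning_bins
                + self.max_delay_bins + self.movement_bins)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PerturbationSchedule:
    """Baseline -> rotation -> washout phase layout of one session."""

    rotation_deg: float = 30.0
    direction: str = "CCW"             # CCW positive about +Z, CW negative
    n_baseline: int = 160
    n_rotation: int = 300
    n_washout: int = 160

    def __post_init__(self) -> None:
        if self.direction not in ("CW", "CCW"):
            raise ValueError("direction must be 'CW' or 'CCW'")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg is a magnitude; use direction for sign")
        if min(self.n_baseline, self.n_rotation) < 0 or self.n_washout < 0:
            raise ValueError("trial counts must be non-negative")

    @property
    def rotation_sign(self) -> int:
        return 1 if self.direction == "CCW" else -1

    @property
    def signed_rotation_deg(self) -> float:
        """Rotation with CCW-positive sign convention."""
        return self.rotation_sign * self.rotation_deg

    @property
    def n_trials(self) -> int:
        return self.n_baseline + self.n_rotation + self.n_washout

    def phase_of(self, trial: int) -> str:
        if trial < 0 or trial >= self.n_trials:
            raise IndexError(f"trial {trial} outside schedule of {self.n_trials}")
        if trial < self.n_baseline:
            return "baseline"
        if trial < self.n_baseline + self.n_rotation:
            return "rotation"
        return "washout"

    def phases(self) -> np.ndarray:
        return np.array(
            ["baseline"] * self.n_baseline
            + ["rotation"] * self.n_rotation
            + ["washout"] * self.n_washout
        )

    def to_dict(self) -> dict:
        return asdict(self)


def make_targets(config: TaskConfig | None = None, cube_side: float | None = None) -> np.ndarray:
    """Eight reach targets at the vertices of the workspace cube.

    Targets are ordered by the sign pattern of (x, y, z) read as a 3-bit index
    (bit 2 -> x, bit 1 -> y, bit 0 -> z; 0 = negative). The set is centered on
    the origin (the fixation point).

    Returns an (8, 3) array in mm.
    """
    if cube_side is None:
        cube_side = (config or TaskConfig()).cube_side
    if cube_side <= 0:
        raise ValueError("cube_side must be positive")
    half = cube_side / 2.0
    targets = np.empty((8, 3))
    for i in range(8):
        signs = np.array([(i >> 2) & 1, (i >> 1) & 1, i & 1], dtype=float)
        targets[i] = half * (2.0 * signs - 1.0)
    return targets
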