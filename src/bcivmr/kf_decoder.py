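"""Biomimetic velocity Kalman filter decoder.

The decoder maps binned spike counts to 3-D cursor velocity. The observation
model is the per-unit linear tuning ``count = b0 + b1*vx + b2*vy + b3*vz``
estimated by least squares on calibration data; the state model is a linear
velocity transition fitted the same way. The state is the augmented vector
(vx, vy, vz, 1): the constant channel carries each unit's baseline rate into
the observation equation and is never updated by the filter.

Units: velocities in mm/s; counts in spikes per bin (the observation matrix
absorbs the units); time step ``bin_ms``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DecoderModel",
    "AssistSchedule",
    "calibrate",
    "retrain_to_target",
    "decode_step",
    "decode_trial",
    "decode_closed_loop",
]

_STATE_DIM = 4  # (vx, vy, vz, 1)


@dataclass
class DecoderModel:
    """Calibrated velocity Kalman filter.

    H : (n_units, 4) observation matrix; last column is the baseline rate b0.
    Q : (n_units, n_units) observation-noise covariance.
    A : (4, 4) state transition; the constant channel is pinned (A[3] = e4).
    W : (4, 4) process-noise covariance; zero in the constant channel.
    """

    unit_ids: list
    H: np.ndarray
    Q: np.ndarray
    A: np.ndarray
    W: np.ndarray
    bin_ms: float = 50.0

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.unit_ids)
        if self.H.shape != (n, _STATE_DIM):
            raise ValueError("H must be (n_units, 4) matching the roster")
        for name, M in (("Q", self.Q), ("W", self.W)):
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-6 * max(1.0, np.abs(M).max()):
                raise ValueError(f"{name} must be positive semi-definite")
        self._cache: dict = {}

    # -- convenience views -------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def Hv(self) -> np.ndarray:
        """Velocity block of the observation matrix (n_units, 3)."""
        return self.H[:, :3]

    @property
    def b0(self) -> np.ndarray:
        """Baseline rates (n_units,)."""
        return self.H[:, 3]

    @property
    def Av(self) -> np.ndarray:
        return self.A[:3, :3]

    @property
    def Wv(self) -> np.ndarray:
        return self.W[:3, :3]

    def _info_terms(self):
        """Cached Q^-1 H_v and Q^-1-weighted terms for the information update."""
        if "QiH" not in self._cache:
            Q = self.Q.copy()
            floor = 1e-9 * max(1.0, float(np.trace(Q)) / max(self.n_units, 1))
            try:
                np.linalg.cholesky(Q + 0.0)
            except np.linalg.LinAlgError:
                Q[np.diag_indices_from(Q)] += floor
            # a second guard: exactly-zero Q (noiseless calibration)
            if np.abs(Q).max() == 0.0:
                Q[np.diag_indices_from(Q)] += floor
            try:
                QiH = np.linalg.solve(Q, self.Hv)
            except np.linalg.LinAlgError:
                Q[np.diag_indices_from(Q)] += floor
                QiH = np.linalg.solve(Q, self.Hv)
            self._cache["QiH"] = QiH
            self._cache["M"] = self.Hv.T @ QiH  # H' Q^-1 H, (3, 3)
        return self._cache["QiH"], self._cache["M"]

    def initial_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Zero velocity with broad diagonal covariance (10x process noise)."""
        x = np.array([0.0, 0.0, 0.0, 1.0])
        P = np.zeros((_STATE_DIM, _STATE_DIM))
        scale = 10.0 * np.trace(self.Wv) / 3.0
        P[:3, :3] = 10.0 * self.Wv + max(scale, 1.0) * 1e-3 * np.eye(3) + 1e-6 * np.eye(3)
        return x, P

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": 1,
            "unit_ids": list(map(str, self.unit_ids)),
            "bin_ms": self.bin_ms,
        }
        for name in ("H", "Q", "A", "W"):
            M = getattr(self, name)
            payload[name] = {"shape": list(M.shape), "data": M.ravel().tolist()}
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DecoderModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        mats = {k: np.array(payload[k]["data"]).reshape(payload[k]["shape"])
                for k in ("H", "Q", "A", "W")}
        return cls(unit_ids=payload["unit_ids"], bin_ms=payload["bin_ms"], **mats)


@dataclass
class AssistSchedule:
    """Blocked computer-assistance weights for decoder retraining.

    ``levels`` are the computer-control fractions per block (monotonically
    decreasing, ending at 0), ``block_sizes`` the trials per block.
    """

    levels: list[float] = field(default_factory=lambda: [0.7, 0.5, 0.3, 0.1, 0.0])
    block_sizes: list[int] = field(default_factory=lambda: [20, 20, 20, 20, 20])

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.block_sizes):
            raise ValueError("levels and block_sizes must have equal length")
        if any(b <= 0 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if any(l2 > l1 for l1, l2 in zip(self.levels, self.levels[1:])):
            raise ValueError("assist weights must decrease monotonically")
        if self.levels and self.levels[-1] != 0.0:
            raise ValueError("final assist weight must be 0")

    @property
    def n_trials(self) -> int:
        return int(sum(self.block_sizes))

    def weight_for_trial(self, trial: int) -> float:
        """Computer weight for a trial index; 0 beyond the schedule."""
        if trial < 0:
            raise IndexError("negative trial index")
        edge = 0
        for level, size in zip(self.levels, self.block_sizes):
            edge += size
            if trial < edge:
                return level
        return 0.0


def _fit_linear(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares Y ~ X with ridge fallback for near-singular designs.

    Returns (coefficients (p, k), residual covariance (k, k))."""
    n, p = X.shape
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        lam = 1e-8 * max(np.trace(XtX) / p, 1.0)
        log.warning("near-singular regressors (cond=%.3g); ridge loading %.3g applied",
                    cond, lam)
        warnings.warn("near-singular regressors: ridge fallback applied",
                      RuntimeWarning, stacklevel=3)
        XtX = XtX + lam * np.eye(p)
    coef = np.linalg.solve(XtX, X.T @ Y)
    resid = Y - X @ coef
    dof = max(n - p, 1)
    return coef, resid.T @ resid / dof


def calibrate(counts: np.ndarray, velocities: np.ndarray, bin_ms: float = 50.0,
              unit_ids=None) -> DecoderModel:
    """Calibrate the decoder by regressing counts on velocity, bin by bin.

    ``counts`` is (n_bins, n_units), ``velocities`` (n_bins, 3) in mm/s,
    aligned per bin. Fills H/Q by per-unit least squares of counts on
    (vx, vy, vz, 1), and A/W by least squares of v_t on v_{t-1}.
    """
    Y = np.asarray(counts, dtype=float)
    V = np.asarray(velocities, dtype=float)
    if Y.ndim != 2 or V.ndim != 2 or V.shape[1] != 3:
        raise ValueError("counts must be (n_bins, n_units) and velocities (n_bins, 3)")
    if Y.shape[0] != V.shape[0]:
        raise ValueError("counts and velocities must be bin-aligned")
    n_bins, n_units = Y.shape
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if n_bins <= _STATE_DIM:
        raise ValueError("need more bins than the state dimension")
    if unit_ids is None:
        unit_ids = [f"u{i:03d}" for i in range(n_units)]
    if len(unit_ids) != n_units:
        raise ValueError("unit roster does not match count columns")

    X = np.column_stack([V, np.ones(n_bins)])
    coef, Q = _fit_linear(X, Y)
    H = coef.T

    Av, Wv = _fit_linear(V[:-1], V[1:])
    A = np.eye(_STATE_DIM)
    A[:3, :3] = Av.T
    W = np.zeros((_STATE_DIM, _STATE_DIM))
    W[:3, :3] = 0.5 * (Wv + Wv.T)
    return DecoderModel(unit_ids=list(unit_ids), H=H, Q=Q, A=A, W=W, bin_ms=bin_ms)


def retrain_to_target(decoder: DecoderModel, counts: np.ndarray,
                      targets: np.ndarray, positions: np.ndarray,
                      nominal_speed: float = 200.0) -> DecoderModel:
    """Recalibrate with idealized velocities pointing at the cued target.

    Training outputs are unit vectors from the current cursor position toward
    the target, scaled by ``nominal_speed`` (mm/s). Bins where the cursor sits
    exactly on the target are excluded (zero training vector rule).
    """
    counts = np.asarray(counts, dtype=float)
    targets = np.asarray(targets, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if counts.shape[1] != decoder.n_units:
        raise ValueError("count columns do not match the decoder roster")
    vec = targets - positions
    norms = np.linalg.norm(vec, axis=1)
    keep = norms > 1e-9
    if not np.any(keep):
        raise ValueError("all training bins degenerate (cursor on target)")
    if not np.all(keep):
        log.info("retrain_to_target: excluded %d degenerate bins", int((~keep).sum()))
    v_train = nominal_speed * vec[keep] / norms[keep, None]
    return calibrate(counts[keep], v_train, bin_ms=decoder.bin_ms,
                     unit_ids=decoder.unit_ids)


def decode_step(decoder: DecoderModel, prior_state: np.ndarray,
                prior_cov: np.ndarray, counts_bin: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """One Kalman predict+update cycle on the augmented (v, 1) state.

    ``prior_state``/``prior_cov`` are the previous posterior. The constant
    channel is pinned to 1 with zero variance. The update is computed in
    information form on the velocity block, which is algebraically the
    standard update whenever the innovation covariance is invertible.
    """
    x = np.asarray(prior_state, dtype=float)
    P = np.asarray(prior_cov, dtype=float)
    y = np.asarray(counts_bin, dtype=float)
    if x.shape != (_STATE_DIM,) or P.shape != (_STATE_DIM, _STATE_DIM):
        raise ValueError("state must be (4,) and covariance (4, 4)")
    if y.shape != (decoder.n_units,):
        raise ValueError("counts_bin does not match the decoder roster")

    # predict (velocity block only; constant channel pinned)
    v_pred = decoder.Av @ x[:3]
    P_pred = decoder.Av @ P[:3, :3] @ decoder.Av.T + decoder.Wv
    P_pred = 0.5 * (P_pred + P_pred.T)

    QiH, M = decoder._info_terms()
    try:
        Pp_inv = np.linalg.inv(P_pred + 1e-12 * np.eye(3))
        info = Pp_inv + M
        P_post = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("degenerate innovation covariance") from exc
    innov_info = QiH.T @ (y - decoder.b0)
    v_post = P_post @ (Pp_inv @ v_pred + innov_info)

    state = np.array([v_post[0], v_post[1], v_post[2], 1.0])
    cov = np.zeros((_STATE_DIM, _STATE_DIM))
    cov[:3, :3] = 0.5 * (P_post + P_post.T)
    return state, cov


def decode_trial(decoder: DecoderModel, counts_by_bin: np.ndarray) -> np.ndarray:
    """Decode a sequence of bins; returns velocities (n_bins, 3) in mm/s."""
    counts_by_bin = np.asarray(counts_by_bin, dtype=float)
    x, P = decoder.initial_state()
    out = np.empty((counts_by_bin.shape[0], 3))
    for i, y in enumerate(counts_by_bin):
        x, P = decode_step(decoder, x, P, y)
        out[i] = x[:3]
    return out


def decode_closed_loop(decoder: DecoderModel, counts_by_bin: np.ndarray,
                       assist_weight: float | np.ndarray = 0.0,
                       computer_velocity: np.ndarray | None = None,
                       start: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Decode one trial's bins into a cursor path with optional assistance.

    Per bin the output velocity is ``w*computer + (1-w)*decoded``; position
    integrates velocity over ``bin_ms`` starting at ``start`` (default the
    center). Returns (positions (n_bins+1, 3), velocities (n_bins, 3)).
    """
    counts_by_bin = np.asarray(counts_by_bin, dtype=float)
    n_bins = counts_by_bin.shape[0]
    w = np.broadcast_to(np.asarray(assist_weight, dtype=float), (n_bins,))
    if np.any(w > 0) and computer_velocity is None:
        raise ValueError("assisted decoding requires computer_velocity")
    if computer_velocity is None:
        computer_velocity = np.zeros((n_bins, 3))
    computer_velocity = np.asarray(computer_velocity, dtype=float)
    if computer_velocity.shape != (n_bins, 3):
        raise ValueError("computer_velocity must be (n_bins, 3)")

    decoded = decode_trial(decoder, counts_by_bin)
    vel = w[:, None] * computer_velocity + (1.0 - w[:, None]) * decoded
    dt = decoder.bin_ms / 1000.0
    pos = np.zeros((n_bins + 1, 3)) if start is None else np.tile(np.asarray(start, float), (n_bins + 1, 1))
    pos[1:] = pos[0] + np.cumsum(vel * dt, axis=0)
    return pos, vel
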