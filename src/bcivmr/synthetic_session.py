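"""Closed-loop generator of BCI visuomotor-rotation sessions.

A session is a sequence of memory-guided center-out trials driven by a
population of linearly (cosine-) tuned units. On each trial an intended
velocity command follows a minimum-jerk speed profile toward the target
direction rotated by the current aim offset; units fire around
``b0 + b_vec . v(t)`` with shared low-rank latent noise and private noise; a
velocity Kalman filter decodes the controlling units' counts into cursor
velocity, which is rotated by the visuomotor perturbation during rotation
trials. After each trial the shared aim offset is updated from the signed
midpoint error by a leaky error-correcting rule, so the ground-truth
adaptation state is known for every trial.

Populations adapt with configurable gain: each unit expresses the shared aim
scaled by its ``adaptation_gain`` (nonadaptive groups: 0), and units may be
tuned in the motor frame (the intended command) or the visual frame (the
perturbed cursor), which instantiates the competing encoding hypotheses the
offline reconstruction readout arbitrates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import TaskConfig, PerturbationSchedule, make_targets
from .geometry import align_to_target_frame, midpoint_angle, apply_vmr
from .kf_decoder import DecoderModel, calibrate, decode_trial

__all__ = [
    "NeuronSpec",
    "LearningModel",
    "SessionData",
    "make_population",
    "population_label",
    "minimum_jerk_speed",
    "simulate_trial",
    "generate_session",
    "save_session",
    "load_session",
]

SCHEMA_VERSION = 1
PLANNING_NOMINAL_SPEED = 200.0  # mm/s, fictive speed carried by planning tuning


@dataclass
class NeuronSpec:
    """Tuning model of one unit.

    ``b0`` is the baseline rate and ``b_vec`` the 3-vector tuning gain, both
    in spikes per bin (per mm/s for ``b_vec``). ``speed_gain`` is the
    condition-independent speed sensitivity (spikes per bin per mm/s of
    cursor speed) — in motor cortical populations this movement-locked
    component is typically the largest principal component, and it gives the
    population a genuinely 4-dimensional stable manifold (three directional
    dimensions plus one speed dimension). ``planning_gain`` scales the
    directional term during the memory period. ``latent_loading`` holds the
    unit's weights onto the shared latent factors. ``adaptation_gain`` scales
    how much of the shared aim offset the unit expresses; ``reference_frame``
    is 'motor' (intended command) or 'visual' (perturbed cursor).
    """

    unit_id: str
    area: str                      # M1 | PMd | PRR
    controlling: bool
    b0: float
    b_vec: np.ndarray
    planning_gain: float = 0.5
    noise_sd: float = 0.5
    latent_loading: np.ndarray = field(default_factory=lambda: np.zeros(4))
    adaptation_gain: float = 1.0
    reference_frame: str = "motor"
    speed_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.area not in ("M1", "PMd", "PRR"):
            raise ValueError("area must be M1, PMd or PRR")
        if self.b0 < 0:
            raise ValueError("b0 must be non-negative")
        if not 0.0 <= self.planning_gain <= 1.0:
            raise ValueError("planning_gain must lie in [0, 1]")
        if self.reference_frame not in ("motor", "visual"):
            raise ValueError("reference_frame must be 'motor' or 'visual'")
        self.b_vec = np.asarray(self.b_vec, dtype=float)
        self.latent_loading = np.asarray(self.latent_loading, dtype=float)


def population_label(spec: NeuronSpec) -> str:
    """Group label used to look up per-population adaptation gains."""
    return f"{spec.area}:{'controlling' if spec.controlling else 'noncontrolling'}"


@dataclass
class LearningModel:
    """Trial-by-trial re-association learning on a single scalar aim angle.

    After each trial, ``aim <- retention*aim - learning_rate*alpha`` where
    ``alpha`` is the signed midpoint error (CCW-positive, degrees). With
    ``learning_rate=0`` the aim stays at ``aim_deg_0``. Per-population
    expression of the shared aim is scaled by ``adaptation_gain_by_population``
    (keys like 'PRR:noncontrolling', fallback 'controlling'/'noncontrolling',
    default 1).
    """

    learning_rate: float = 0.002
    retention: float = 0.9996
    aim_deg_0: float = 0.0
    adaptation_gain_by_population: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.retention <= 1:
            raise ValueError("retention must lie in (0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")

    def gain_for(self, spec: NeuronSpec) -> float:
        gains = self.adaptation_gain_by_population
        label = population_label(spec)
        if label in gains:
            return float(gains[label])
        generic = "controlling" if spec.controlling else "noncontrolling"
        if generic in gains:
            return float(gains[generic])
        return 1.0


@dataclass
class SessionData:
    """One simulated session: counts, events, kinematics, roster, truth."""

    counts: np.ndarray              # (n_trials, n_bins, n_units)
    trial_table: pd.DataFrame       # trial, target, phase, event bins, alpha
    cursor: np.ndarray              # (n_trials, n_bins + 1, 3) mm
    hand: np.ndarray                # (n_trials, n_bins + 1, 3) mm
    units: list[NeuronSpec]
    truth: np.ndarray               # per-trial ground-truth aim offset (deg)
    config: TaskConfig
    schedule: PerturbationSchedule
    decoder: DecoderModel | None = None
    schema_version: int = SCHEMA_VERSION

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[2]

    @property
    def targets(self) -> np.ndarray:
        return make_targets(self.config)

    def unit_indices(self, areas=None, controlling=None) -> np.ndarray:
        idx = []
        for i, u in enumerate(self.units):
            if areas is not None and u.area not in areas:
                continue
            if controlling is not None and u.controlling != controlling:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def trials_in_phase(self, phase: str) -> np.ndarray:
        return np.flatnonzero(self.trial_table["phase"].to_numpy() == phase)

    def late_rotation_trials(self, fraction: float = 0.5) -> np.ndarray:
        """Last ``fraction`` of rotation-phase trials."""
        rot = self.trials_in_phase("rotation")
        k = int(np.ceil(fraction * rot.size))
        return rot[rot.size - k:]

    def movement_bins(self, trial: int) -> np.ndarray:
        row = self.trial_table.iloc[trial]
        return np.arange(int(row["go_bin"]), int(row["move_end_bin"]))

    def planning_bins(self, trial: int, window_bins: int | None = None) -> np.ndarray:
        """Memory-period bins (cue offset to go); optionally the last window."""
        row = self.trial_table.iloc[trial]
        bins = np.arange(int(row["cue_off_bin"]), int(row["go_bin"]))
        if window_bins is not None:
            bins = bins[-window_bins:]
        return bins


def make_population(n: int, area: str, controlling: bool, rng: np.random.Generator,
                    b0_range=(0.5, 3.0), modulation_range=(0.003, 0.009),
                    planning_gain_range=(0.3, 0.7), noise_sd: float = 0.5,
                    latent_rank: int = 4, latent_sd: float = 0.3,
                    speed_gain_range=(0.002, 0.006),
                    reference_frame: str = "motor", id_prefix: str | None = None
                    ) -> list[NeuronSpec]:
    """Draw a population with approximately uniform preferred directions."""
    if id_prefix is None:
        id_prefix = f"{area}{'c' if controlling else 'n'}"
    specs = []
    for i in range(n):
        pd_dir = rng.normal(size=3)
        pd_dir /= np.linalg.norm(pd_dir)
        b_norm = rng.uniform(*modulation_range)
        specs.append(NeuronSpec(
            speed_gain=rng.uniform(*speed_gain_range),
            unit_id=f"{id_prefix}{i:03d}",
            area=area,
            controlling=controlling,
            b0=rng.uniform(*b0_range),
            b_vec=b_norm * pd_dir,
            planning_gain=rng.uniform(*planning_gain_range),
            noise_sd=noise_sd,
            latent_loading=rng.normal(scale=latent_sd, size=latent_rank),
            reference_frame=reference_frame,
        ))
    return specs


def minimum_jerk_speed(n_bins: int, dt_s: float, distance: float,
                       duration_s: float) -> np.ndarray:
    """Per-bin speeds (mm/s) of a minimum-jerk reach, sampled at bin centers.

    The profile integrates (by the midpoint rule) to ``distance`` over
    ``duration_s``; bins beyond the duration are zero.
    """
    t = (np.arange(n_bins) + 0.5) * dt_s
    tau = np.clip(t / duration_s, 0.0, 1.0)
    speed = distance / duration_s * 30.0 * tau**2 * (1.0 - tau) ** 2
    # midpoint-rule correction so the path lands on the target
    total = speed.sum() * dt_s
    if total > 0:
        speed *= distance / total
    return speed


def _rotate_xy(vec: np.ndarray, deg: float) -> np.ndarray:
    """Rotate the in-plane component of a 3-vector CCW by ``deg``."""
    out = np.array(vec, dtype=float)
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    x, y = out[0], out[1]
    out[0], out[1] = c * x - s * y, s * x + c * y
    return out


def _expected_rates(specs, target, aim_offset_deg, config, speed_profile,
                    plan_slice, move_slice, n_bins):
    """Expected counts (n_bins, n_units) for motor-frame units.

    Planning-period tuning points at the (aim-scaled) target direction with a
    fixed nominal speed; movement-period tuning follows the aimed minimum-jerk
    command. Returns also the per-unit aimed movement direction matrix for the
    closed loop.
    """
    n_units = len(specs)
    rates = np.empty((n_bins, n_units))
    unit_dirs = np.empty((n_units, 3))
    target = np.asarray(target, dtype=float)
    distance = np.linalg.norm(target)
    u_target = target / distance
    for j, spec in enumerate(specs):
        rates[:, j] = spec.b0
        aim_j = spec.adaptation_gain * aim_offset_deg
        dir_j = _rotate_xy(u_target, aim_j)
        unit_dirs[j] = dir_j
        drive = float(spec.b_vec @ dir_j)
        rates[plan_slice, j] += spec.planning_gain * PLANNING_NOMINAL_SPEED * drive
        rates[move_slice, j] += speed_profile * (drive + spec.speed_gain)
    return rates, unit_dirs


def simulate_trial(aim_offset_deg: float, target: np.ndarray,
                   specs: list[NeuronSpec], decoder: DecoderModel,
                   schedule: PerturbationSchedule, rng: np.random.Generator,
                   config: TaskConfig | None = None, phase: str = "baseline",
                   delay_bins: int | None = None, round_counts: bool = True,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Simulate one closed-loop trial.

    Returns (counts (n_bins, n_units), cursor (n_bins+1, 3), hand (n_bins+1, 3),
    events). The cursor sits at the fixation point until the go cue, then
    integrates the decoded (and, in rotation trials, visually rotated)
    velocity; after movement end it holds its final position. The hand stays
    within the security radius throughout (BCI context).
    """
    config = config or TaskConfig()
    controlling_ids = [s.unit_id for s in specs if s.controlling]
    if list(decoder.unit_ids) != controlling_ids:
        raise ValueError("decoder roster does not match the controlling units")

    if delay_bins is None:
        delay_bins = int(rng.integers(0, config.max_delay_bins + 1))
    fix, cue = config.fixation_bins, config.cue_bins
    plan, move = config.planning_bins, config.movement_bins
    n_bins = config.trial_bins
    cue_on = fix
    cue_off = fix + cue
    go = cue_off + plan + delay_bins
    move_end = go + move
    plan_slice = slice(cue_off, go)
    move_slice = slice(go, move_end)

    target = np.asarray(target, dtype=float)
    distance = float(np.linalg.norm(target))
    speed = minimum_jerk_speed(move, config.dt_s, distance, config.movement_ms / 1000.0)

    motor_specs = [s for s in specs if s.reference_frame == "motor"]
    visual_specs = [s for s in specs if s.reference_frame == "visual"]
    motor_idx = [i for i, s in enumerate(specs) if s.reference_frame == "motor"]
    visual_idx = [i for i, s in enumerate(specs) if s.reference_frame == "visual"]

    rates = np.empty((n_bins, len(specs)))
    m_rates, unit_dirs = _expected_rates(
        motor_specs, target, aim_offset_deg, config, speed, plan_slice, move_slice, n_bins)
    rates[:, motor_idx] = m_rates

    # shared latent factors + private noise
    ranks = {s.latent_loading.size for s in specs}
    rank = max(ranks) if ranks else 0
    z = rng.standard_normal((n_bins, rank)) if rank else np.zeros((n_bins, 0))
    noise = np.empty_like(rates)
    for j, spec in enumerate(specs):
        noise[:, j] = rng.normal(scale=spec.noise_sd, size=n_bins) if spec.noise_sd > 0 else 0.0
        if spec.latent_loading.size:
            noise[:, j] += z[:, :spec.latent_loading.size] @ spec.latent_loading

    counts = rates + noise

    # decode the controlling units' movement-period counts into cursor velocity
    ctrl_idx = [i for i, s in enumerate(specs) if s.controlling]
    ctrl_counts = counts[move_slice][:, ctrl_idx]
    if round_counts:
        ctrl_counts = np.clip(np.rint(ctrl_counts), 0, None)
    v_dec = decode_trial(decoder, ctrl_counts)
    rot = schedule.signed_rotation_deg if phase == "rotation" else 0.0
    v_cursor = apply_vmr(v_dec, abs(rot), "CCW" if rot >= 0 else "CW") if rot else v_dec

    cursor = np.zeros((n_bins + 1, 3))
    cursor[go + 1: move_end + 1] = np.cumsum(v_cursor * config.dt_s, axis=0)
    cursor[move_end + 1:] = cursor[move_end]

    # visual-frame units fire around the realized (perturbed) cursor velocity
    if visual_specs:
        for j, i in zip(range(len(visual_specs)), visual_idx):
            spec = visual_specs[j]
            rates[:, i] = spec.b0
            u_target = target / distance
            rates[plan_slice, i] += (spec.planning_gain * PLANNING_NOMINAL_SPEED
                                     * float(spec.b_vec @ u_target))
            rates[move_slice, i] += (v_cursor @ spec.b_vec
                                     + spec.speed_gain * np.linalg.norm(v_cursor, axis=1))
        counts = rates + noise

    if round_counts:
        counts = np.clip(np.rint(counts), 0, None)
    else:
        counts = np.clip(counts, 0, None)

    hand = np.zeros((n_bins + 1, 3))
    jitter_sd = min(2.0, config.hand_security_radius_mm / 6.0)
    if jitter_sd > 0:
        hand += rng.normal(scale=jitter_sd, size=hand.shape)
        r = np.linalg.norm(hand, axis=1)
        over = r > config.hand_security_radius_mm
        if np.any(over):
            hand[over] *= (config.hand_security_radius_mm / r[over])[:, None]

    events = {"cue_on_bin": cue_on, "cue_off_bin": cue_off, "go_bin": go,
              "move_end_bin": move_end, "delay_bins": delay_bins}
    return counts, cursor, hand, events


def _calibration_block(specs, config, rng, n_trials=40, round_counts=True):
    """Simulated manual-control block: true hand velocities + evoked counts."""
    targets = make_targets(config)
    move = config.movement_bins
    all_v, all_y = [], []
    for t in range(n_trials):
        target = targets[t % 8]
        distance = float(np.linalg.norm(target))
        speed = minimum_jerk_speed(move, config.dt_s, distance,
                                   config.movement_ms / 1000.0)
        v = np.outer(speed, target / distance)
        y = np.empty((move, len(specs)))
        for j, spec in enumerate(specs):
            y[:, j] = spec.b0 + v @ spec.b_vec + spec.speed_gain * speed
            if spec.noise_sd > 0:
                y[:, j] += rng.normal(scale=spec.noise_sd, size=move)
            if spec.latent_loading.size:
                z = rng.standard_normal((move, spec.latent_loading.size))
                y[:, j] += z @ spec.latent_loading
        if round_counts:
            y = np.clip(np.rint(y), 0, None)
        all_v.append(v)
        all_y.append(y)
    return np.vstack(all_y), np.vstack(all_v)


def generate_session(config: TaskConfig, schedule: PerturbationSchedule,
                     specs: list[NeuronSpec], learning: LearningModel,
                     round_counts: bool = True, n_calibration_trials: int = 40,
                     ) -> SessionData:
    """Generate a full baseline -> rotation -> washout session.

    A decoder is first calibrated on a simulated manual-control block using
    the controlling units, then trials are generated in schedule order with
    the aim offset updated after each trial by the leaky error-correcting
    rule. Fully reproducible from ``learning.seed``.
    """
    if schedule.n_baseline <= 0 or schedule.n_rotation < 0:
        raise ValueError("schedule needs baseline trials")
    rng = np.random.default_rng(learning.seed)

    specs = [replace(s, adaptation_gain=learning.gain_for(s)) for s in specs]
    ctrl = [s for s in specs if s.controlling]
    if len(ctrl) < 2:
        raise ValueError("need at least 2 controlling units")

    y_cal, v_cal = _calibration_block(ctrl, config, rng,
                                      n_trials=n_calibration_trials,
                                      round_counts=round_counts)
    decoder = calibrate(y_cal, v_cal, bin_ms=config.bin_ms,
                        unit_ids=[s.unit_id for s in ctrl])

    targets = make_targets(config)
    n_trials = schedule.n_trials
    n_bins = config.trial_bins
    counts = np.empty((n_trials, n_bins, len(specs)))
    cursor = np.empty((n_trials, n_bins + 1, 3))
    hand = np.empty((n_trials, n_bins + 1, 3))
    truth = np.empty(n_trials)
    rows = []

    aim = learning.aim_deg_0
    # target order: shuffled blocks of all eight, as in a pseudorandomized task
    order = np.concatenate([rng.permutation(8) for _ in range(-(-n_trials // 8))])[:n_trials]
    for t in range(n_trials):
        phase = schedule.phase_of(t)
        tgt_idx = int(order[t])
        target = targets[tgt_idx]
        truth[t] = aim
        c, cur, h, ev = simulate_trial(aim, target, specs, decoder, schedule,
                                       rng, config=config, phase=phase,
                                       round_counts=round_counts)
        counts[t], cursor[t], hand[t] = c, cur, h
        move_path = cur[ev["go_bin"]: ev["move_end_bin"] + 1]
        aligned = align_to_target_frame(move_path, target, rotation_sign=1)
        try:
            alpha_ccw = midpoint_angle(aligned).alpha_deg
        except ValueError:
            alpha_ccw = 0.0
        if learning.learning_rate > 0:
            aim = learning.retention * aim - learning.learning_rate * alpha_ccw
        rows.append({
            "trial": t, "target": tgt_idx, "phase": phase,
            "rotation_sign": schedule.rotation_sign,
            "cue_on_bin": ev["cue_on_bin"], "cue_off_bin": ev["cue_off_bin"],
            "go_bin": ev["go_bin"], "move_end_bin": ev["move_end_bin"],
            "alpha_ccw_deg": alpha_ccw,
            "alpha_deg": schedule.rotation_sign * alpha_ccw,
            "success": True,
        })

    table = pd.DataFrame(rows)
    return SessionData(counts=counts, trial_table=table, cursor=cursor,
                       hand=hand, units=specs, truth=truth, config=config,
                       schedule=schedule, decoder=decoder)


# ---------------------------------------------------------------------------
# serialization: one directory per session
# ---------------------------------------------------------------------------

_UNIT_COLUMNS = ["unit_id", "area", "controlling", "b0", "planning_gain",
                 "noise_sd", "adaptation_gain", "reference_frame", "speed_gain"]


def save_session(session: SessionData, path) -> None:
    """Write a session directory: HDF5 arrays + CSV tables + JSON config."""
    import h5py
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "arrays.h5", "w", track_order=True) as fh:
        for name in ("counts", "cursor", "hand", "truth"):
            fh.create_dataset(name, data=getattr(session, name),
                              track_times=False)
    session.trial_table.to_csv(path / "trial_table.csv", index=False)

    unit_rows = []
    for u in session.units:
        row = {k: getattr(u, k) for k in _UNIT_COLUMNS}
        row.update({f"b{ax}": v for ax, v in zip("xyz", u.b_vec)})
        row.update({f"L{i}": v for i, v in enumerate(u.latent_loading)})
        unit_rows.append(row)
    pd.DataFrame(unit_rows).to_csv(path / "units.csv", index=False)

    meta = {
        "schema_version": session.schema_version,
        "task": session.config.to_dict(),
        "schedule": session.schedule.to_dict(),
        "latent_rank": int(session.units[0].latent_loading.size) if session.units else 0,
    }
    with open(path / "config.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if session.decoder is not None:
        session.decoder.to_json(path / "decoder.json")


def load_session(path) -> SessionData:
    """Read back a session directory written by :func:`save_session`."""
    import h5py
    from pathlib import Path

    path = Path(path)
    with open(path / "config.json") as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {meta.get('schema_version')}")
    with h5py.File(path / "arrays.h5", "r") as fh:
        arrays = {k: fh[k][()] for k in ("counts", "cursor", "hand", "truth")}
    table = pd.read_csv(path / "trial_table.csv")
    units_df = pd.read_csv(path / "units.csv")
    rank = int(meta.get("latent_rank", 0))
    units = []
    for _, row in units_df.iterrows():
        units.append(NeuronSpec(
            unit_id=str(row["unit_id"]), area=row["area"],
            controlling=bool(row["controlling"]), b0=float(row["b0"]),
            b_vec=np.array([row["bx"], row["by"], row["bz"]], dtype=float),
            planning_gain=float(row["planning_gain"]),
            noise_sd=float(row["noise_sd"]),
            latent_loading=np.array([row[f"L{i}"] for i in range(rank)], dtype=float),
            adaptation_gain=float(row["adaptation_gain"]),
            reference_frame=str(row["reference_frame"]),
            speed_gain=float(row.get("speed_gain", 0.0)),
        ))
    decoder = None
    if (path / "decoder.json").exists():
        decoder = DecoderModel.from_json(path / "decoder.json")
    return SessionData(
        counts=arrays["counts"], trial_table=table, cursor=arrays["cursor"],
        hand=arrays["hand"], units=units, truth=arrays["truth"],
        config=TaskConfig(**meta["task"]),
        schedule=PerturbationSchedule(**meta["schedule"]),
        decoder=decoder, schema_version=meta["schema_version"])
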