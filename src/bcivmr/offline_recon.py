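"""Offline population re-decoding: the core inferential readout.

A velocity Kalman filter is trained on the *baseline* activity of a chosen
population (movement period against realized cursor velocities, or memory
period against unit vectors to the cued target) and then applied to rotation
trials. During rotation, motor command and visual feedback are spatially
incongruent, so the sign of the reconstructed trajectories' deflection along
the perturbation axis arbitrates what the population encodes: ~0 deflection
means a stationary nonadaptive signal, positive the perturbed visual cursor,
negative the adapted motor command (re-association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AlignedTrajectory, align_to_target_frame, average_aligned, deflection
from .kf_decoder import DecoderModel, calibrate, decode_trial
from .synthetic_session import SessionData

log = logging.getLogger(__name__)

__all__ = [
    "PopulationSelector",
    "ReconResult",
    "RelativeGain",
    "recon_movement",
    "recon_memory",
    "classify_target",
    "classification_accuracy",
    "aiming_vector",
    "relative_gain",
    "planning_movement_table",
]


@dataclass
class PopulationSelector:
    """Select units by area and controlling status.

    ``areas`` is a subset of {M1, PMd, PRR} or None for all;
    ``controlling`` is 'controlling', 'noncontrolling' or 'all'.
    """

    areas: tuple | None = None
    controlling: str = "all"

    def __post_init__(self) -> None:
        if self.controlling not in ("controlling", "noncontrolling", "all"):
            raise ValueError("controlling must be controlling|noncontrolling|all")
        if self.areas is not None:
            self.areas = tuple(self.areas)
            bad = set(self.areas) - {"M1", "PMd", "PRR"}
            if bad:
                raise ValueError(f"unknown areas {bad}")

    def indices(self, session: SessionData) -> np.ndarray:
        ctrl = {"controlling": True, "noncontrolling": False, "all": None}[self.controlling]
        idx = session.unit_indices(areas=self.areas, controlling=ctrl)
        if idx.size == 0:
            raise ValueError(f"selector {self.label} matches no units")
        return idx

    @property
    def label(self) -> str:
        area = "-".join(self.areas) if self.areas else "all"
        return f"{area}:{self.controlling}"


@dataclass
class ReconResult:
    """Reconstructed trajectories of one population over a set of trials."""

    trial_indices: np.ndarray
    trajectories: list           # per-trial (n_bins+1, 3) reconstructed paths
    aligned: list                # per-trial AlignedTrajectory
    deflection_end: np.ndarray   # perturbation-axis coordinate at end
    phase: np.ndarray            # phase label per trial
    population: str = ""
    epoch: str = "movement"      # movement | planning

    def __post_init__(self) -> None:
        n = len(self.trial_indices)
        if not (len(self.trajectories) == len(self.aligned)
                == len(self.deflection_end) == len(self.phase) == n):
            raise ValueError("one reconstruction per analyzed trial required")

    def mean_aligned(self, n_points: int = 100) -> AlignedTrajectory:
        return average_aligned(self.aligned, n_points=n_points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": self.trial_indices,
            "phase": self.phase,
            "population": self.population,
            "epoch": self.epoch,
            "deflection_end": self.deflection_end,
        })


@dataclass
class RelativeGain:
    """A population's final adaptation angle relative to the controlling one."""

    population: str
    final_angle_deg: float
    controlling_angle_deg: float
    gain_percent: float
    undefined: bool = False


def _cursor_velocities(session: SessionData, trial: int) -> np.ndarray:
    """Realized cursor velocity (mm/s) over the movement bins of a trial."""
    bins = session.movement_bins(trial)
    pos = session.cursor[trial]
    dt = session.config.dt_s
    return (pos[bins + 1] - pos[bins]) / dt


def _successful(session: SessionData, trials: np.ndarray) -> np.ndarray:
    ok = session.trial_table["success"].to_numpy()[trials]
    return trials[ok.astype(bool)]


def recon_movement(session: SessionData, selector: PopulationSelector,
                   phase_test: str = "rotation", phase_train: str = "baseline",
                   trials_test: np.ndarray | None = None) -> ReconResult:
    """Reconstruct movement-period trajectories from a population offline.

    The KF is calibrated on the selected units' baseline movement-period
    counts against the realized cursor velocities, then applied to the test
    trials' movement-period counts; decoded velocities are integrated into
    positions, aligned to the target frame, and the end-of-movement
    deflection is extracted. When testing on the training phase itself a
    leave-one-out procedure is used so every baseline trial is analyzable.
    """
    idx = selector.indices(session)
    if idx.size < 2:
        raise ValueError("need at least 2 units for decoding")
    train_trials = _successful(session, session.trials_in_phase(phase_train))
    if train_trials.size == 0:
        raise ValueError(f"no {phase_train} trials to train on")
    if trials_test is None:
        trials_test = session.trials_in_phase(phase_test)
    trials_test = _successful(session, np.asarray(trials_test, dtype=int))
    if trials_test.size == 0:
        raise ValueError(f"no {phase_test} trials to test on")

    def training_data(exclude: int | None = None):
        ys, vs = [], []
        for t in train_trials:
            if exclude is not None and t == exclude:
                continue
            bins = session.movement_bins(t)
            ys.append(session.counts[t][bins][:, idx])
            vs.append(_cursor_velocities(session, t))
        return np.vstack(ys), np.vstack(vs)

    loo = phase_test == phase_train
    decoder = None
    if not loo:
        y, v = training_data()
        decoder = calibrate(y, v, bin_ms=session.config.bin_ms,
                            unit_ids=[session.units[i].unit_id for i in idx])

    targets = session.targets
    sign = session.schedule.rotation_sign
    dt = session.config.dt_s
    trajectories, aligned, defl = [], [], []
    for t in trials_test:
        dec = decoder
        if loo:
            y, v = training_data(exclude=int(t))
            dec = calibrate(y, v, bin_ms=session.config.bin_ms,
                            unit_ids=[session.units[i].unit_id for i in idx])
        bins = session.movement_bins(t)
        v_hat = decode_trial(dec, session.counts[t][bins][:, idx])
        path = np.vstack([np.zeros(3), np.cumsum(v_hat * dt, axis=0)])
        tgt = targets[int(session.trial_table.iloc[t]["target"])]
        al = align_to_target_frame(path, tgt, rotation_sign=sign)
        trajectories.append(path)
        aligned.append(al)
        defl.append(deflection(al, 1.0))

    return ReconResult(
        trial_indices=trials_test, trajectories=trajectories, aligned=aligned,
        deflection_end=np.array(defl),
        phase=session.trial_table["phase"].to_numpy()[trials_test],
        population=selector.label, epoch="movement")


def recon_memory(session: SessionData, selector: PopulationSelector,
                 phase_test: str = "rotation", phase_train: str = "baseline",
                 trials_test: np.ndarray | None = None) -> ReconResult:
    """Reconstruct hypothetical planning-period trajectories.

    Calibration regresses baseline memory-period counts on unit vectors
    pointing at the cued target (sampled every bin); the decoder is then
    applied per bin to the test trials' memory period and the hypothetical
    trajectory is the cumulative sum of the decoded vectors. Trajectories are
    in arbitrary units (unit-norm regression targets).
    """
    idx = selector.indices(session)
    if idx.size < 2:
        raise ValueError("need at least 2 units for decoding")
    train_trials = _successful(session, session.trials_in_phase(phase_train))
    if train_trials.size == 0:
        raise ValueError(f"no {phase_train} trials to train on")
    if trials_test is None:
        trials_test = session.trials_in_phase(phase_test)
    trials_test = _successful(session, np.asarray(trials_test, dtype=int))
    if trials_test.size == 0:
        raise ValueError(f"no {phase_test} trials to test on")

    targets = session.targets
    table = session.trial_table

    def training_data(exclude: int | None = None):
        ys, vs = [], []
        for t in train_trials:
            if exclude is not None and t == exclude:
                continue
            bins = session.planning_bins(t)
            tgt = targets[int(table.iloc[t]["target"])]
            u = tgt / np.linalg.norm(tgt)
            ys.append(session.counts[t][bins][:, idx])
            vs.append(np.tile(u, (bins.size, 1)))
        return np.vstack(ys), np.vstack(vs)

    loo = phase_test == phase_train
    decoder = None
    if not loo:
        y, v = training_data()
        decoder = calibrate(y, v, bin_ms=session.config.bin_ms,
                            unit_ids=[session.units[i].unit_id for i in idx])

    sign = session.schedule.rotation_sign
    trajectories, aligned, defl = [], [], []
    for t in trials_test:
        dec = decoder
        if loo:
            y, v = training_data(exclude=int(t))
            dec = calibrate(y, v, bin_ms=session.config.bin_ms,
                            unit_ids=[session.units[i].unit_id for i in idx])
        bins = session.planning_bins(t)
        v_hat = decode_trial(dec, session.counts[t][bins][:, idx])
        path = np.vstack([np.zeros(3), np.cumsum(v_hat, axis=0)])  # arbitrary units
        tgt = targets[int(table.iloc[t]["target"])]
        al = align_to_target_frame(path, tgt, rotation_sign=sign)
        trajectories.append(path)
        aligned.append(al)
        defl.append(deflection(al, 1.0))

    return ReconResult(
        trial_indices=trials_test, trajectories=trajectories, aligned=aligned,
        deflection_end=np.array(defl),
        phase=table["phase"].to_numpy()[trials_test],
        population=selector.label, epoch="planning")


def classify_target(final_position: np.ndarray, targets: np.ndarray
                    ) -> tuple[int, bool]:
    """Nearest target to a reconstructed endpoint (8-way classifier).

    Ties are broken by the lowest target index and flagged. Returns
    (target index, tie flag).
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape[0] != 8:
        raise ValueError("expected 8 targets")
    d = np.linalg.norm(targets - np.asarray(final_position, dtype=float), axis=1)
    best = int(np.argmin(d))
    tie = bool(np.sum(np.isclose(d, d[best], rtol=0, atol=1e-9)) > 1)
    if tie:
        log.info("classifier tie at distance %.3f; lowest index %d chosen", d[best], best)
    return best, tie


def classification_accuracy(recon: ReconResult, session: SessionData) -> float:
    """Fraction of trials whose reconstruction endpoint classifies correctly."""
    targets = session.targets
    truth = session.trial_table["target"].to_numpy()[recon.trial_indices]
    hits = 0
    for traj, true_idx in zip(recon.trajectories, truth):
        pred, _ = classify_target(traj[-1], targets)
        hits += pred == int(true_idx)
    return hits / len(recon.trajectories)


def aiming_vector(recon: ReconResult, session: SessionData,
                  window_ms: float = 400.0) -> np.ndarray:
    """Per-trial sum of unit-normalized decoded directions before 'go'.

    Uses the final ``window_ms`` of the planning reconstruction (8 bins at
    50 ms); zero-norm decoded bins are skipped and logged. Returns
    (n_trials, 3).
    """
    if recon.epoch != "planning":
        raise ValueError("aiming vectors are defined on planning reconstructions")
    n_bins = int(round(window_ms / session.config.bin_ms))
    out = np.zeros((len(recon.trajectories), 3))
    for i, path in enumerate(recon.trajectories):
        steps = np.diff(path, axis=0)[-n_bins:]
        if steps.shape[0] < n_bins:
            raise ValueError("fewer decoded bins than the aiming window")
        norms = np.linalg.norm(steps, axis=1)
        keep = norms > 1e-12
        if not np.all(keep):
            log.info("aiming_vector: skipped %d zero-norm bins", int((~keep).sum()))
        out[i] = (steps[keep] / norms[keep, None]).sum(axis=0)
    return out


def _final_angle(recon: ReconResult, n_points: int = 100) -> float:
    """Signed angle (deg) of the mean aligned trajectory endpoint."""
    mean = recon.mean_aligned(n_points=n_points)
    x, y = mean.along_target[-1], mean.along_perturbation[-1]
    if np.hypot(x, y) < 1e-12:
        raise ValueError("degenerate mean trajectory")
    return float(np.degrees(np.arctan2(y, x)))


def relative_gain(result_pop: ReconResult, result_ctrl: ReconResult) -> RelativeGain:
    """Adaptation angle of a population as a percentage of the controlling one.

    The final angle is the signed angle between the mean reconstructed
    trajectory endpoint and the direct-to-target axis in the aligned frame.
    A near-zero controlling angle makes the gain undefined (flagged).
    """
    ang_pop = _final_angle(result_pop)
    ang_ctrl = _final_angle(result_ctrl)
    undefined = abs(ang_ctrl) < 1e-6
    if undefined:
        log.warning("controlling final angle ~0; relative gain undefined")
        gain = float("nan")
    else:
        gain = 100.0 * ang_pop / ang_ctrl
    return RelativeGain(population=result_pop.population,
                        final_angle_deg=ang_pop,
                        controlling_angle_deg=ang_ctrl,
                        gain_percent=gain, undefined=undefined)


def planning_movement_table(session: SessionData,
                            selectors: list[PopulationSelector],
                            session_id: str = "s0", animal_id: str = "A",
                            movement_ms_post_go: float = 200.0,
                            planning_window_ms: float = 400.0) -> pd.DataFrame:
    """Per-trial planning vs movement deflection pairs for the learning model.

    Planning deflection is taken at the end of the 400 ms pre-go window of
    the memory reconstruction (arbitrary units); movement deflection at
    200 ms after go (mm), early enough to limit feedback-driven corrections.
    Rotation-phase trials only.
    """
    move_bins_post = int(round(movement_ms_post_go / session.config.bin_ms))
    frames = []
    rot_trials = session.trials_in_phase("rotation")
    for sel in selectors:
        mov = recon_movement(session, sel, trials_test=rot_trials)
        mem = recon_memory(session, sel, trials_test=rot_trials)
        frac = move_bins_post / session.config.movement_bins
        mov_defl = np.array([deflection(a, frac) for a in mov.aligned])
        plan_defl = np.empty(len(mem.aligned))
        n_window = int(round(planning_window_ms / session.config.bin_ms))
        for i, path in enumerate(mem.trajectories):
            seg = path[-(n_window + 1):]
            tgt = session.targets[int(session.trial_table.iloc[mem.trial_indices[i]]["target"])]
            al = align_to_target_frame(seg, tgt, rotation_sign=session.schedule.rotation_sign)
            plan_defl[i] = al.along_perturbation[-1]
        frames.append(pd.DataFrame({
            "animal": animal_id, "session": session_id,
            "population": sel.label,
            "trial": mov.trial_indices,
            "trial_number": np.arange(len(mov.trial_indices)),
            "planning_deflection": plan_defl,
            "movement_deflection": mov_defl,
        }))
    return pd.concat(frames, ignore_index=True)
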