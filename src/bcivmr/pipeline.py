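"""Run orchestration: generate -> decode -> analyze -> report.

A run is fully described by a :class:`RunConfig` (seed-complete); executing it
writes session directories, decoder models, analysis tables and a manifest
with a config hash, so any stage can be reproduced or resumed from its
serialized inputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .task import TaskConfig, PerturbationSchedule
from .synthetic_session import (LearningModel, SessionData, generate_session,
                                make_population, save_session, load_session)
from .offline_recon import (PopulationSelector, recon_movement, recon_memory,
                            relative_gain, planning_movement_table)
from .manifold import manifold_preservation
from . import stats as _stats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PopulationConfig", "run_experiment", "make_fixtures",
           "default_populations", "build_roster"]


@dataclass
class PopulationConfig:
    """One generator population: area, controlling flag, size, gains."""

    area: str
    controlling: bool
    n: int
    adaptation_gain: float = 1.0
    reference_frame: str = "motor"


def default_populations() -> list[PopulationConfig]:
    """Experiment-scale roster: frontal controlling units plus frontal and
    parietal noncontrolling groups with partial adaptation gains."""
    return [
        PopulationConfig("M1", True, 20, 1.0),
        PopulationConfig("PMd", True, 20, 1.0),
        PopulationConfig("M1", False, 15, 0.8),
        PopulationConfig("PMd", False, 15, 0.8),
        PopulationConfig("PRR", False, 30, 0.4),
    ]


@dataclass
class RunConfig:
    """Seed-complete description of a simulated experiment."""

    task: TaskConfig = field(default_factory=TaskConfig)
    schedule: PerturbationSchedule = field(default_factory=PerturbationSchedule)
    populations: list[PopulationConfig] = field(default_factory=default_populations)
    learning: LearningModel = field(default_factory=LearningModel)
    n_sessions: int = 1
    alternate_rotation_direction: bool = True
    seed: int = 0
    out_dir: str = "bcivmr_run"
    analyses: tuple = ("adaptation", "recon", "manifold", "planning_movement")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # run identity is independent of its location
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            task=TaskConfig(**d.get("task", {})),
            schedule=PerturbationSchedule(**d.get("schedule", {})),
            populations=[PopulationConfig(**p) for p in d.get("populations", [])]
            or default_populations(),
            learning=LearningModel(**d.get("learning", {})),
            n_sessions=d.get("n_sessions", 1),
            alternate_rotation_direction=d.get("alternate_rotation_direction", True),
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir", "bcivmr_run"),
            analyses=tuple(d.get("analyses", ("adaptation", "recon",
                                              "manifold", "planning_movement"))),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def build_roster(populations: list[PopulationConfig], rng: np.random.Generator,
                 **kwargs):
    """Draw the unit roster for one session from population configs."""
    specs = []
    gains = {}
    for pop in populations:
        specs += make_population(pop.n, pop.area, pop.controlling, rng,
                                 reference_frame=pop.reference_frame, **kwargs)
        key = f"{pop.area}:{'controlling' if pop.controlling else 'noncontrolling'}"
        gains[key] = pop.adaptation_gain
    return specs, gains


def _generate_one(config: RunConfig, session_index: int) -> SessionData:
    ss = np.random.SeedSequence([config.seed, session_index])
    session_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(session_seed)
    specs, gains = build_roster(config.populations, rng)
    learning = LearningModel(
        learning_rate=config.learning.learning_rate,
        retention=config.learning.retention,
        aim_deg_0=config.learning.aim_deg_0,
        adaptation_gain_by_population={**gains,
                                       **config.learning.adaptation_gain_by_population},
        seed=session_seed)
    schedule = config.schedule
    if config.alternate_rotation_direction and session_index % 2:
        schedule = PerturbationSchedule(
            rotation_deg=schedule.rotation_deg,
            direction="CW" if schedule.direction == "CCW" else "CCW",
            n_baseline=schedule.n_baseline, n_rotation=schedule.n_rotation,
            n_washout=schedule.n_washout)
    return generate_session(config.task, schedule, specs, learning)


class _RunLogger:
    """Line-delimited JSON stage log."""

    def __init__(self, path: Path):
        self.path = path

    def emit(self, stage: str, status: str, **extra) -> None:
        rec = {"t": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage,
               "status": status, **extra}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_experiment(config: RunConfig, resume: bool = True) -> Path:
    """Execute the full generate/analyze pipeline into a run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog = _RunLogger(out / "run_log.jsonl")

    manifest = {"version": __version__, "config": config.to_dict(),
                "config_hash": config.config_hash()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    # -- generate ----------------------------------------------------------
    sessions: list[SessionData] = []
    for i in range(config.n_sessions):
        sdir = out / f"session_{i:03d}"
        if resume and (sdir / "config.json").exists():
            runlog.emit("generate", "skipped", session=i)
            sessions.append(load_session(sdir))
            continue
        session = _generate_one(config, i)
        save_session(session, sdir)
        if session.decoder is not None:
            session.decoder.to_json(sdir / "decoder.json")
        sessions.append(session)
        runlog.emit("generate", "ok", session=i)

    selectors = _selectors_for(config)
    if config.schedule.n_rotation == 0:
        runlog.emit("analyze", "skipped",
                    reason="n_rotation=0: rotation-dependent analyses skipped")
        log.warning("n_rotation=0: rotation-dependent analyses skipped")
        return out

    # -- adaptation curve --------------------------------------------------
    if "adaptation" in config.analyses:
        try:
            frames = []
            for i, s in enumerate(sessions):
                rot = s.trials_in_phase("rotation")
                frames.append(pd.DataFrame({
                    "session": i, "trial": np.arange(rot.size),
                    "alpha_deg": s.trial_table["alpha_deg"].to_numpy()[rot]}))
            tidy = pd.concat(frames, ignore_index=True)
            tidy.to_csv(out / "adaptation_alpha.csv", index=False)
            if len(sessions) >= 1:
                fit = _stats.fit_exponential(tidy, n_boot=200)
                with open(out / "adaptation_fit.json", "w") as fh:
                    json.dump(asdict(fit), fh, indent=1)
            runlog.emit("adaptation", "ok")
        except Exception as exc:  # noqa: BLE001
            runlog.emit("adaptation", "failed", error=str(exc))
            raise

    # -- offline reconstruction -------------------------------------------
    if "recon" in config.analyses:
        try:
            rows = []
            ctrl_sel = PopulationSelector(controlling="controlling")
            for i, s in enumerate(sessions):
                late = s.late_rotation_trials()
                res_ctrl = recon_movement(s, ctrl_sel, trials_test=late)
                for sel in selectors:
                    res = (res_ctrl if sel.label == ctrl_sel.label
                           else recon_movement(s, sel, trials_test=late))
                    gain = relative_gain(res, res_ctrl)
                    rows.append({
                        "session": i, "population": sel.label,
                        "mean_deflection_end": float(res.deflection_end.mean()),
                        "final_angle_deg": gain.final_angle_deg,
                        "relative_gain_percent": gain.gain_percent,
                    })
            pd.DataFrame(rows).to_csv(out / "recon_deflections.csv", index=False)
            runlog.emit("recon", "ok")
        except Exception as exc:  # noqa: BLE001
            runlog.emit("recon", "failed", error=str(exc))
            raise

    # -- manifold alignment -------------------------------------------------
    if "manifold" in config.analyses:
        try:
            rows = []
            for i, s in enumerate(sessions):
                for sel in selectors:
                    rep = manifold_preservation(
                        s, sel, rng=np.random.default_rng([config.seed, i, 7]))
                    rows.append({"session": i, "population": sel.label,
                                 **{k: rep[k] for k in ("ai_late_rotation",
                                                        "ai_baseline_cv",
                                                        "abs_difference")}})
            pd.DataFrame(rows).to_csv(out / "alignment_indices.csv", index=False)
            runlog.emit("manifold", "ok")
        except Exception as exc:  # noqa: BLE001
            runlog.emit("manifold", "failed", error=str(exc))
            raise

    # -- planning/movement model -------------------------------------------
    if "planning_movement" in config.analyses and len(sessions) >= 2:
        try:
            tables = [planning_movement_table(s, selectors,
                                              session_id=f"s{i}", animal_id="A")
                      for i, s in enumerate(sessions)]
            table = pd.concat(tables, ignore_index=True)
            table.to_csv(out / "planning_movement_table.csv", index=False)
            report = _stats.planning_movement_model(table, n_boot=100)
            with open(out / "planning_movement_model.json", "w") as fh:
                json.dump(report, fh, indent=1)
            runlog.emit("planning_movement", "ok")
        except Exception as exc:  # noqa: BLE001
            runlog.emit("planning_movement", "failed", error=str(exc))
            raise

    return out


def _selectors_for(config: RunConfig) -> list[PopulationSelector]:
    sels = [PopulationSelector(controlling="controlling")]
    seen = set()
    for pop in config.populations:
        if not pop.controlling:
            key = (pop.area, "noncontrolling")
            if key not in seen:
                seen.add(key)
                sels.append(PopulationSelector(areas=(pop.area,),
                                               controlling="noncontrolling"))
    return sels


def make_fixtures(scale: str = "tiny", out_dir=None, seed: int = 0):
    """Generate a test fixture session.

    ``tiny`` (8 units, 24 trials) is for unit tests and completes in
    seconds; ``paper_like`` matches the experiment's schedule (160 baseline,
    300 rotation, 160 washout trials, ~100 units across the three areas).
    Returns the SessionData (and writes it when ``out_dir`` is given).
    """
    if scale == "tiny":
        schedule = PerturbationSchedule(n_baseline=8, n_rotation=8, n_washout=8)
        pops = [PopulationConfig("M1", True, 6, 1.0),
                PopulationConfig("PRR", False, 2, 0.5)]
    elif scale == "paper_like":
        schedule = PerturbationSchedule()
        pops = default_populations()
    else:
        raise ValueError("scale must be 'tiny' or 'paper_like'")
    rng = np.random.default_rng(seed)
    specs, gains = build_roster(pops, rng)
    learning = LearningModel(adaptation_gain_by_population=gains, seed=seed)
    session = generate_session(TaskConfig(), schedule, specs, learning)
    if out_dir is not None:
        save_session(session, out_dir)
    return session
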