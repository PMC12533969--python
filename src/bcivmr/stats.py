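"""Adaptation statistics.

Exponential learning-curve fits with session-clustered bootstrap inference,
one-sample deflection tests, preferred-direction shift estimation, decoder
contribution scores, firing-rate comparisons, and the hierarchical
planning-to-movement regression with a trial-number interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .offline_recon import PopulationSelector
from .synthetic_session import SessionData, minimum_jerk_speed
from .kf_decoder import DecoderModel

log = logging.getLogger(__name__)

__all__ = [
    "AdaptationFit",
    "TuningShift",
    "ContributionScore",
    "fit_exponential",
    "test_deflections",
    "pd_shift",
    "contribution",
    "planning_movement_model",
    "pairwise_population_slopes",
    "compare_rates",
]


# ---------------------------------------------------------------------------
# exponential adaptation fit
# ---------------------------------------------------------------------------

@dataclass
class AdaptationFit:
    """Pooled exponential fit alpha(t) = a * exp(b * t) of one phase."""

    intercept_deg: float
    decay_per_trial: float
    p_intercept: float
    p_decay: float
    n: int                     # sessions entering the fit
    phase: str = "rotation"

    def predict(self, trial: np.ndarray) -> np.ndarray:
        return self.intercept_deg * np.exp(self.decay_per_trial * np.asarray(trial, float))


def _as_tidy_alpha(alpha_by_session) -> pd.DataFrame:
    if isinstance(alpha_by_session, pd.DataFrame):
        need = {"session", "trial", "alpha_deg"}
        if not need <= set(alpha_by_session.columns):
            raise ValueError(f"alpha table needs columns {sorted(need)}")
        return alpha_by_session
    frames = []
    for s, arr in enumerate(alpha_by_session):
        arr = np.asarray(arr, dtype=float)
        frames.append(pd.DataFrame({
            "session": s, "trial": np.arange(arr.size), "alpha_deg": arr}))
    return pd.concat(frames, ignore_index=True)


def _fit_exp_once(t: np.ndarray, y: np.ndarray, p0=None) -> tuple[float, float]:
    def model(t_, a, b):
        return a * np.exp(np.clip(b * t_, -50, 50))

    starts = [p0] if p0 is not None else []
    a0 = y[: max(5, y.size // 20)].mean()
    if not np.isfinite(a0) or a0 == 0:
        a0 = y.mean() if y.mean() != 0 else 1.0
    starts += [(a0, b0) for b0 in (-0.003, -0.01, -0.001, 0.0, 0.003)]
    last_err = None
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(model, t, y, p0=start, maxfev=5000)
            return float(popt[0]), float(popt[1])
        except (RuntimeError, ValueError) as exc:  # non-convergence
            last_err = exc
    raise RuntimeError(f"exponential fit failed from all starts: {last_err}")


def fit_exponential(alpha_by_session, phase: str = "rotation",
                    n_boot: int = 2000,
                    rng: np.random.Generator | None = None) -> AdaptationFit:
    """Pooled nonlinear least squares of alpha(t) = a*exp(b*t) across sessions.

    ``alpha_by_session`` is either a tidy frame with columns
    (session, trial, alpha_deg) or a list of per-session alpha arrays, trial
    indices counted from the start of the phase. Significance of intercept
    and decay comes from a session-clustered bootstrap (resampling sessions
    with replacement and refitting).
    """
    rng = rng or np.random.default_rng(0)
    df = _as_tidy_alpha(alpha_by_session)
    if df.groupby("session")["trial"].count().min() < 10:
        raise ValueError("need at least 10 trials per session")
    t = df["trial"].to_numpy(float)
    y = df["alpha_deg"].to_numpy(float)
    a_hat, b_hat = _fit_exp_once(t, y)

    sessions = df["session"].unique()
    boots = np.empty((n_boot, 2))
    groups = {s: df[df["session"] == s] for s in sessions}
    for i in range(n_boot):
        pick = rng.choice(sessions, size=sessions.size, replace=True)
        sub = pd.concat([groups[s] for s in pick], ignore_index=True)
        try:
            boots[i] = _fit_exp_once(sub["trial"].to_numpy(float),
                                     sub["alpha_deg"].to_numpy(float),
                                     p0=(a_hat, b_hat))
        except RuntimeError:
            boots[i] = np.nan
    boots = boots[~np.isnan(boots).any(axis=1)]

    def boot_p(column: np.ndarray) -> float:
        if column.size == 0:
            return float("nan")
        lo = np.mean(column <= 0)
        hi = np.mean(column >= 0)
        return float(min(1.0, 2.0 * min(lo, hi) + 1.0 / (column.size + 1)))

    return AdaptationFit(intercept_deg=a_hat, decay_per_trial=b_hat,
                         p_intercept=boot_p(boots[:, 0]),
                         p_decay=boot_p(boots[:, 1]),
                         n=int(sessions.size), phase=phase)


# ---------------------------------------------------------------------------
# deflection test
# ---------------------------------------------------------------------------

def test_deflections(deflections_by_session) -> dict:
    """One-sample t test of per-session mean deflections against zero."""
    x = np.asarray(deflections_by_session, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need per-session means from at least 3 sessions")
    if np.allclose(x, x[0]):
        return {"t": float("nan"), "df": x.size - 1,
                "p": 1.0 if x[0] == 0 else 0.0,
                "mean": float(x.mean()), "sd": 0.0,
                "degenerate_variance": True}
    res = sps.ttest_1samp(x, 0.0)
    return {"t": float(res.statistic), "df": int(x.size - 1),
            "p": float(res.pvalue), "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)), "degenerate_variance": False}


# ---------------------------------------------------------------------------
# preferred-direction shifts
# ---------------------------------------------------------------------------

@dataclass
class TuningShift:
    unit_id: str
    pd_baseline_deg: float
    pd_rotation_deg: float
    shift_deg: float
    epoch: str = "movement"

    def __post_init__(self) -> None:
        if abs(self.shift_deg) > 180:
            raise ValueError("shift must be wrapped to [-180, 180]")


def _wrap_deg(angle: float) -> float:
    return float((angle + 180.0) % 360.0 - 180.0)


def _tuning_vector(session: SessionData, unit: int, trials: np.ndarray,
                   epoch: str) -> np.ndarray:
    """Least-squares tuning vector of one unit over a set of trials.

    Movement epoch: counts on the idealized straight-to-target command
    velocity; planning epoch: counts on the target unit direction."""
    ys, xs = [], []
    targets = session.targets
    cfg = session.config
    for t in trials:
        tgt = targets[int(session.trial_table.iloc[t]["target"])]
        if epoch == "movement":
            bins = session.movement_bins(t)
            speed = minimum_jerk_speed(bins.size, cfg.dt_s,
                                       float(np.linalg.norm(tgt)),
                                       cfg.movement_ms / 1000.0)
            xs.append(np.outer(speed, tgt / np.linalg.norm(tgt)))
        elif epoch == "planning":
            bins = session.planning_bins(t)
            xs.append(np.tile(tgt / np.linalg.norm(tgt), (bins.size, 1)))
        else:
            raise ValueError("epoch must be 'movement' or 'planning'")
        ys.append(session.counts[t][bins][:, unit])
    X = np.column_stack([np.vstack(xs), np.ones(sum(len(y) for y in ys))])
    Y = np.concatenate(ys)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef[:3]


def pd_shift(session: SessionData, unit: int, epoch: str = "movement",
             min_inplane_norm: float = 1e-3,
             rotation_trials: np.ndarray | None = None) -> TuningShift:
    """In-plane tuning rotation between rotation and baseline trials.

    Fits the unit's tuning vector per phase against the straight-to-target
    reference (late-rotation trials by default). When a unit re-aims — its
    drive follows the target direction rotated by an angle theta — the
    fitted tuning vector rotates by -theta, so the shift reported here is
    the rotation of the unit's target-to-command mapping (the negated
    fitted-angle difference), sign-folded by the session's rotation
    direction: positive = toward the applied visual rotation, negative =
    compensatory re-aiming. Units whose in-plane tuning norm falls below
    ``min_inplane_norm`` (spikes/bin per mm/s) in either phase are rejected
    as untuned.
    """
    base = session.trials_in_phase("baseline")
    rot = (rotation_trials if rotation_trials is not None
           else session.late_rotation_trials())
    if base.size < 8 or np.asarray(rot).size < 8:
        raise ValueError("need at least 8 trials per phase for the fit")
    v_base = _tuning_vector(session, unit, base, epoch)
    v_rot = _tuning_vector(session, unit, np.asarray(rot, dtype=int), epoch)
    for name, v in (("baseline", v_base), ("rotation", v_rot)):
        if np.linalg.norm(v[:2]) < min_inplane_norm:
            log.info("unit %d untuned in %s phase; excluded", unit, name)
            raise ValueError(f"unit untuned in {name} phase")
    pd_b = np.degrees(np.arctan2(v_base[1], v_base[0]))
    pd_r = np.degrees(np.arctan2(v_rot[1], v_rot[0]))
    shift = session.schedule.rotation_sign * _wrap_deg(-(pd_r - pd_b))
    return TuningShift(unit_id=session.units[unit].unit_id,
                       pd_baseline_deg=float(pd_b), pd_rotation_deg=float(pd_r),
                       shift_deg=shift, epoch=epoch)


# ---------------------------------------------------------------------------
# decoder contribution
# ---------------------------------------------------------------------------

@dataclass
class ContributionScore:
    unit_id: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("contribution score cannot be negative")


def contribution(decoder: DecoderModel, unit) -> ContributionScore:
    """Norm of a unit's velocity tuning vector plus its baseline rate."""
    if isinstance(unit, (int, np.integer)):
        idx = int(unit)
        if not 0 <= idx < decoder.n_units:
            raise KeyError(f"unit index {idx} outside roster")
    else:
        try:
            idx = list(decoder.unit_ids).index(unit)
        except ValueError as exc:
            raise KeyError(f"unit {unit!r} not in roster") from exc
    b = decoder.H[idx]
    return ContributionScore(unit_id=str(decoder.unit_ids[idx]),
                             score=float(np.linalg.norm(b[:3]) + b[3]))


# ---------------------------------------------------------------------------
# hierarchical planning -> movement model
# ---------------------------------------------------------------------------

_PM_FORMULA = "movement_deflection ~ planning_deflection + planning_deflection:trial_number"


def _check_pm_table(table: pd.DataFrame) -> pd.DataFrame:
    need = {"animal", "session", "trial_number",
            "planning_deflection", "movement_deflection"}
    if not need <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(need)}")
    df = table.copy()
    df["sess_key"] = df["animal"].astype(str) + "/" + df["session"].astype(str)
    if df["sess_key"].nunique() < 2:
        raise ValueError("need at least 2 sessions")
    return df


def _ols_session_fe(df: pd.DataFrame, formula: str = _PM_FORMULA):
    import statsmodels.formula.api as smf
    model = smf.ols(formula + " + C(sess_key)", data=df)
    return model.fit(cov_type="cluster", cov_kwds={"groups": df["sess_key"]})


def planning_movement_model(table: pd.DataFrame, n_boot: int = 500,
                            rng: np.random.Generator | None = None) -> dict:
    """Mixed model of movement deflection on planning deflection.

    Fixed effects: the planning deflection and its interaction with trial
    number; random intercepts for animal with sessions nested in animal.
    Bootstrap confidence intervals resample sessions (clustered). If the
    mixed fit is singular or fails to converge, a session-fixed-effects OLS
    with cluster-robust errors is used and flagged in the report.
    """
    import statsmodels.formula.api as smf

    rng = rng or np.random.default_rng(0)
    df = _check_pm_table(table)

    fit = None
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(_PM_FORMULA, df, groups="animal",
                             re_formula="1",
                             vc_formula={"session": "0 + C(sess_key)"})
            fit = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not fit.converged or not np.all(np.isfinite(fit.params)):
            raise RuntimeError("mixed model did not converge")
    except Exception as exc:  # noqa: BLE001 - any fit failure triggers fallback
        log.warning("mixed model singular/failed (%s); session-FE OLS fallback", exc)
        fit = _ols_session_fe(df)
        fallback = True

    slope_name = "planning_deflection"
    inter_name = "planning_deflection:trial_number"
    params = fit.params
    pvals = fit.pvalues

    # cluster bootstrap over sessions (session-FE OLS for speed/stability)
    keys = df["sess_key"].unique()
    grouped = {k: df[df["sess_key"] == k] for k in keys}
    boots = np.empty((n_boot, 2))
    for i in range(n_boot):
        pick = rng.choice(keys, size=keys.size, replace=True)
        parts = []
        for j, k in enumerate(pick):
            part = grouped[k].copy()
            part["sess_key"] = f"b{j}"       # keep resampled clusters distinct
            parts.append(part)
        sub = pd.concat(parts, ignore_index=True)
        try:
            bfit = _ols_session_fe(sub)
            boots[i] = [bfit.params[slope_name], bfit.params[inter_name]]
        except Exception:  # noqa: BLE001
            boots[i] = np.nan
    boots = boots[~np.isnan(boots).any(axis=1)]
    # t-based interval on the bootstrap SE, centered on the bootstrapped
    # estimator (session-FE OLS): percentile intervals undercover badly with
    # a small number of clusters
    if boots.size:
        center_fit = fit if fallback else _ols_session_fe(df)
        point = np.array([center_fit.params[slope_name],
                          center_fit.params[inter_name]])
        tcrit = sps.t.ppf(0.975, df=max(keys.size - 1, 1))
        half = tcrit * boots.std(axis=0, ddof=1) * np.sqrt(
            keys.size / max(keys.size - 1, 1))
        ci = np.vstack([point - half, point + half])
    else:
        ci = np.full((2, 2), np.nan)

    return {
        "slope": float(params[slope_name]),
        "interaction": float(params[inter_name]),
        "p_slope": float(pvals[slope_name]),
        "p_interaction": float(pvals[inter_name]),
        "ci_slope": (float(ci[0, 0]), float(ci[1, 0])),
        "ci_interaction": (float(ci[0, 1]), float(ci[1, 1])),
        "n_sessions": int(keys.size),
        "n_trials": int(len(df)),
        "fallback_fixed_effects": fallback,
    }


def pairwise_population_slopes(table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise planning-slope comparisons between populations.

    For each population pair a model with a planning x population interaction
    is fitted (session fixed effects, cluster-robust errors) and the
    interaction p-value is Bonferroni-corrected over all pairs.
    """
    import statsmodels.formula.api as smf
    from itertools import combinations

    df = _check_pm_table(table)
    if "population" not in df.columns:
        raise ValueError("table needs a 'population' column")
    pops = sorted(df["population"].unique())
    pairs = list(combinations(pops, 2))
    if not pairs:
        raise ValueError("need at least 2 populations")
    rows = []
    for a, b in pairs:
        sub = df[df["population"].isin([a, b])].copy()
        sub["population"] = pd.Categorical(sub["population"], categories=[a, b])
        model = smf.ols(
            "movement_deflection ~ planning_deflection"
            " + planning_deflection:C(population) + C(sess_key)", data=sub)
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": sub["sess_key"]})
        name = f"planning_deflection:C(population)[T.{b}]"
        rows.append({
            "pop_a": a, "pop_b": b,
            "slope_difference": float(fit.params[name]),
            "p_raw": float(fit.pvalues[name]),
            "p_bonferroni": float(min(1.0, fit.pvalues[name] * len(pairs))),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# firing-rate comparison
# ---------------------------------------------------------------------------

def compare_rates(sessions: list[SessionData], selector: PopulationSelector,
                  phase_a: str = "baseline", phase_b: str = "rotation") -> dict:
    """Rank-sum test of per-session mean firing rates between two phases."""
    if not isinstance(sessions, (list, tuple)) or len(sessions) < 2:
        raise ValueError("need at least 2 sessions (replicates) to compare rates")

    def session_mean(session: SessionData, phase: str) -> float:
        idx = selector.indices(session)
        trials = (session.late_rotation_trials() if phase == "late_rotation"
                  else session.trials_in_phase(phase))
        if trials.size == 0:
            raise ValueError(f"phase {phase} empty")
        vals = [session.counts[t][session.movement_bins(t)][:, idx].mean()
                for t in trials]
        return float(np.mean(vals)) / (session.config.bin_ms / 1000.0)  # spikes/s

    a = np.array([session_mean(s, phase_a) for s in sessions])
    b = np.array([session_mean(s, phase_b) for s in sessions])
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n": len(sessions)}
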