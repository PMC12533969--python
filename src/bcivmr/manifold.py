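"""Neural-manifold structure: PCA variance, alignment index, cross-projection.

The alignment index between two epochs is the fraction of one epoch's top-k
variance captured by the other epoch's top-k principal components:

    AI = tr(P' C_proj P) / sum of top-k eigenvalues of C_proj

where P holds the top-k eigenvectors of the reference covariance. AI near 1
means the projected epoch's dominant subspace is preserved in the reference
frame (within-manifold re-association); AI near 0 means reconfiguration into
an orthogonal subspace. Baseline self-alignment is cross-validated (PCs from
one half of the trials, variance from the other) so that comparisons with
other phases are not inflated by overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .offline_recon import PopulationSelector
from .synthetic_session import SessionData

__all__ = [
    "AlignmentResult",
    "epoch_covariance",
    "alignment_index",
    "cross_validated_baseline_ai",
    "manifold_preservation",
    "cross_project_planning",
]

SOFT_NORM_SPIKES_PER_BIN = 0.25  # 5 spikes/s at 50 ms bins


@dataclass
class AlignmentResult:
    epoch_pair: tuple
    n_pcs: int
    ai: float
    cross_validated: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.ai < -1e-9:
            raise ValueError("alignment index cannot be negative")
        # sampling noise under cross-validation can push AI slightly above 1
        self.flagged = bool(self.ai > 1.05)


def _epoch_matrix(session: SessionData, idx: np.ndarray, trials: np.ndarray,
                  period: str, soft_normalize: bool, trial_average: bool) -> np.ndarray:
    """Activity substrate: per-target trial averages, bins concatenated.

    Returns (n_samples, n_units) mean-centered columns."""
    table = session.trial_table
    blocks = []
    groups = ([trials[table["target"].to_numpy()[trials] == k] for k in range(8)]
              if trial_average else [np.array([t]) for t in trials])
    for grp in groups:
        if grp.size == 0:
            continue
        per_trial = []
        plan_window = session.config.planning_bins  # fixed 400 ms pre-go
        for t in grp:
            bins = (session.movement_bins(t) if period == "movement"
                    else session.planning_bins(t, window_bins=plan_window))
            per_trial.append(session.counts[t][bins][:, idx])
        blocks.append(np.mean(per_trial, axis=0))
    if not blocks:
        raise ValueError("empty epoch")
    X = np.vstack(blocks)
    if soft_normalize:
        rng_ = X.max(axis=0) - X.min(axis=0)
        X = X / (rng_ + SOFT_NORM_SPIKES_PER_BIN)
    return X - X.mean(axis=0)


def epoch_covariance(session: SessionData, selector: PopulationSelector,
                     phase: str = "baseline", period: str = "movement",
                     trials: np.ndarray | None = None,
                     soft_normalize: bool = True,
                     trial_average: bool = True) -> np.ndarray:
    """Unit-by-unit covariance of an epoch's (trial-averaged) activity.

    The substrate is per-target trial averages over the epoch's trials, bins
    concatenated, soft-normalized (range + 5 spikes/s) and mean-centered.
    ``phase`` may be 'baseline'/'rotation'/'washout' or 'late_rotation' (the
    last 50% of rotation trials). An explicit ``trials`` array overrides it.
    """
    idx = selector.indices(session)
    if trials is None:
        trials = (session.late_rotation_trials() if phase == "late_rotation"
                  else session.trials_in_phase(phase))
    trials = np.asarray(trials, dtype=int)
    if trials.size < 2:
        raise ValueError("need at least 2 trials in the epoch")
    X = _epoch_matrix(session, idx, trials, period, soft_normalize, trial_average)
    return X.T @ X / max(X.shape[0] - 1, 1)


def _top_eigvecs(cov: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order[:n_pcs]]


def alignment_index(cov_reference: np.ndarray, cov_projected: np.ndarray,
                    n_pcs: int = 4, cross_validated: bool = False,
                    epoch_pair: tuple = ("reference", "projected")) -> AlignmentResult:
    """Variance of the projected epoch captured by the reference top PCs."""
    cov_reference = np.asarray(cov_reference, dtype=float)
    cov_projected = np.asarray(cov_projected, dtype=float)
    if cov_reference.shape != cov_projected.shape or cov_reference.ndim != 2:
        raise ValueError("covariances must be square and of equal size")
    n = cov_reference.shape[0]
    if n_pcs > n:
        raise ValueError("n_pcs exceeds matrix size")
    vals_p, _ = _top_eigvecs(cov_projected, n_pcs)
    top_var = float(vals_p[:n_pcs].sum())
    if top_var <= 0:
        raise ValueError("projected covariance has no variance in top PCs")
    _, P = _top_eigvecs(cov_reference, n_pcs)
    captured = float(np.trace(P.T @ cov_projected @ P))
    return AlignmentResult(epoch_pair=epoch_pair, n_pcs=n_pcs,
                           ai=captured / top_var, cross_validated=cross_validated)


def cross_validated_baseline_ai(session: SessionData, selector: PopulationSelector,
                                n_pcs: int = 4, n_splits: int = 10,
                                period: str = "movement",
                                rng: np.random.Generator | None = None) -> AlignmentResult:
    """Baseline self-alignment with held-out variance.

    Baseline trials are split in halves stratified by target (so each half's
    per-target averages use balanced trial counts); PCs come from one half
    and the variance ratio is evaluated on the other. Both directions of each
    split are averaged, over ``n_splits`` random splits.
    """
    rng = rng or np.random.default_rng(0)
    trials = session.trials_in_phase("baseline")
    if trials.size < 4:
        raise ValueError("too few baseline trials for cross-validation")
    targets = session.trial_table["target"].to_numpy()
    ais = []
    for _ in range(n_splits):
        half_a, half_b = [], []
        for k in range(8):
            grp = rng.permutation(trials[targets[trials] == k])
            h = grp.size // 2
            half_a.extend(grp[:h])
            half_b.extend(grp[h:])
        cov_a = epoch_covariance(session, selector,
                                 trials=np.array(half_a, dtype=int), period=period)
        cov_b = epoch_covariance(session, selector,
                                 trials=np.array(half_b, dtype=int), period=period)
        ais.append(alignment_index(cov_a, cov_b, n_pcs=n_pcs).ai)
        ais.append(alignment_index(cov_b, cov_a, n_pcs=n_pcs).ai)
    return AlignmentResult(epoch_pair=("baseline", "baseline"), n_pcs=n_pcs,
                           ai=float(np.mean(ais)), cross_validated=True)


def manifold_preservation(session: SessionData, selector: PopulationSelector,
                          n_pcs: int = 4, n_splits: int = 10,
                          period: str = "movement",
                          late_fraction: float = 0.5,
                          rng: np.random.Generator | None = None) -> dict:
    """Matched-sampling comparison of late-rotation vs baseline alignment.

    Both alignment indices are computed with the same finite-sample
    structure so that their difference reflects genuine manifold change
    rather than unequal trial counts: per split, baseline trials are divided
    into stratified halves A/B; the cross-validated baseline index projects
    B onto A's top PCs, and the late-rotation index projects a late-rotation
    subsample with B's per-target trial counts onto the same A-derived PCs.
    Returns the two averaged indices and their absolute difference (both on
    [0, 1]).
    """
    rng = rng or np.random.default_rng(0)
    targets = session.trial_table["target"].to_numpy()
    base = session.trials_in_phase("baseline")
    late = session.late_rotation_trials(fraction=late_fraction)
    if base.size < 4 or late.size < 4:
        raise ValueError("too few trials for the matched comparison")
    cv_ais, late_ais = [], []
    for _ in range(n_splits):
        half_a, half_b, late_sub = [], [], []
        for k in range(8):
            grp = rng.permutation(base[targets[base] == k])
            h = grp.size // 2
            half_a.extend(grp[:h])
            half_b.extend(grp[h:])
            pool = rng.permutation(late[targets[late] == k])
            late_sub.extend(pool[: grp.size - h])
        cov_a = epoch_covariance(session, selector,
                                 trials=np.array(half_a, int), period=period)
        cov_b = epoch_covariance(session, selector,
                                 trials=np.array(half_b, int), period=period)
        cov_l = epoch_covariance(session, selector,
                                 trials=np.array(late_sub, int), period=period)
        cv_ais.append(alignment_index(cov_a, cov_b, n_pcs=n_pcs).ai)
        cv_ais.append(alignment_index(cov_b, cov_a, n_pcs=n_pcs).ai)
        late_ais.append(alignment_index(cov_a, cov_l, n_pcs=n_pcs).ai)
    ai_cv = float(np.mean(cv_ais))
    ai_late = float(np.mean(late_ais))
    return {"ai_baseline_cv": ai_cv, "ai_late_rotation": ai_late,
            "abs_difference": abs(ai_late - ai_cv), "n_pcs": n_pcs,
            "n_splits": n_splits}


def cross_project_planning(session: SessionData, selector: PopulationSelector,
                           n_pcs: int = 4, pc_criterion: str = "top_n",
                           phase: str = "baseline") -> dict:
    """Planning-epoch variance captured by the movement-epoch PCs.

    With ``pc_criterion='top_n'`` the first ``n_pcs`` movement PCs are used;
    with ``'var90'`` the smallest PC set explaining 90% of movement variance.
    Fractions are of each epoch's total variance; the movement self-projection
    is reported alongside for comparison.
    """
    cov_mov = epoch_covariance(session, selector, phase=phase, period="movement")
    cov_plan = epoch_covariance(session, selector, phase=phase, period="planning")
    vals_m, vecs = np.linalg.eigh(cov_mov)
    order = np.argsort(vals_m)[::-1]
    vals_m = vals_m[order]
    vecs = vecs[:, order]
    if pc_criterion == "top_n":
        k = n_pcs
    elif pc_criterion == "var90":
        frac = np.cumsum(vals_m) / vals_m.sum()
        k = int(np.searchsorted(frac, 0.90) + 1)
    else:
        raise ValueError("pc_criterion must be 'top_n' or 'var90'")
    P = vecs[:, :k]
    tot_plan = float(np.trace(cov_plan))
    tot_mov = float(np.trace(cov_mov))
    if tot_plan <= 0 or tot_mov <= 0:
        raise ValueError("epoch with zero variance")
    return {
        "n_pcs": k,
        "planning_fraction": float(np.trace(P.T @ cov_plan @ P)) / tot_plan,
        "movement_fraction": float(np.trace(P.T @ cov_mov @ P)) / tot_mov,
    }
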