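"""Planning-to-movement transfer of adaptation.

Reconstructs hypothetical planning-period trajectories (memory decoder) and
early-movement trajectories for rotation trials in several sessions, then
fits the hierarchical model

    movement_deflection ~ 1 + planning_deflection
                            + planning_deflection:trial_number
                            + (1 | animal/session)

A positive slope means trial-by-trial re-aiming during planning predicts the
subsequent movement correction; a positive interaction means this coupling
strengthens over learning. Planning deflections are in arbitrary units (the
memory decoder is trained on unit vectors), so only relative slopes matter.
"""

import numpy as np

from bcivmr import LearningModel, PerturbationSchedule, TaskConfig, generate_session
from bcivmr.synthetic_session import make_population
from bcivmr.offline_recon import PopulationSelector, planning_movement_table
from bcivmr.stats import planning_movement_model
import pandas as pd

tables = []
for seed in range(6):
    rng = np.random.default_rng(seed)
    specs = make_population(50, "M1", True, rng)
    session = generate_session(
        TaskConfig(), PerturbationSchedule(n_baseline=96, n_rotation=200,
                                           n_washout=0),
        specs, LearningModel(learning_rate=0.02, retention=0.998, seed=seed))
    tables.append(planning_movement_table(
        session, [PopulationSelector(controlling="controlling")],
        session_id=f"s{seed}", animal_id="A" if seed < 3 else "B"))

table = pd.concat(tables, ignore_index=True)
rep = planning_movement_model(table, n_boot=200, rng=np.random.default_rng(0))
print(f"sessions: {rep['n_sessions']}   rotation trials: {rep['n_trials']}")
print(f"slope       = {rep['slope']:+.4f}  (p = {rep['p_slope']:.2e},"
      f" CI {rep['ci_slope'][0]:+.4f} .. {rep['ci_slope'][1]:+.4f})")
print(f"interaction = {rep['interaction']:+.6f} (p = {rep['p_interaction']:.3f})")
if rep["fallback_fixed_effects"]:
    print("note: mixed fit was singular; session-fixed-effects OLS was used.")
print("positive slope: planning re-aiming transfers to movement corrections.")
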