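"""Offline re-decoding of noncontrolling populations: the encoding readout.

Trains a velocity Kalman filter on each population's baseline activity
(against the realized cursor velocities), applies it to late-rotation trials,
and prints the end-of-movement deflection along the perturbation axis plus
the relative gain. Negative deflections mean the population encodes the
adapted motor command (re-association); positive would mean the perturbed
visual cursor; ~0 a stationary signal. The relative gain expresses each
population's final adaptation angle as a percentage of the controlling
population's.
"""

import numpy as np

from bcivmr import LearningModel, PerturbationSchedule, TaskConfig, generate_session
from bcivmr.synthetic_session import make_population
from bcivmr.offline_recon import PopulationSelector, recon_movement, relative_gain
from bcivmr.stats import test_deflections

deflections = {"controlling": [], "M1-PMd noncontrolling": [], "PRR noncontrolling": []}
gains = {"M1-PMd noncontrolling": [], "PRR noncontrolling": []}
for seed in range(8):
    rng = np.random.default_rng(seed)
    specs = (make_population(30, "M1", True, rng)
             + make_population(16, "PMd", False, rng)
             + make_population(16, "PRR", False, rng))
    pop_gains = {"controlling": 1.0, "PMd:noncontrolling": 0.8,
                 "PRR:noncontrolling": 0.4}
    session = generate_session(
        TaskConfig(), PerturbationSchedule(n_baseline=96, n_rotation=160,
                                           n_washout=0),
        specs, LearningModel(learning_rate=0.01, retention=0.999,
                             adaptation_gain_by_population=pop_gains, seed=seed))
    late = session.late_rotation_trials()
    res_ctrl = recon_movement(session, PopulationSelector(controlling="controlling"),
                              trials_test=late)
    res_m1 = recon_movement(session, PopulationSelector(
        areas=("PMd",), controlling="noncontrolling"), trials_test=late)
    res_prr = recon_movement(session, PopulationSelector(
        areas=("PRR",), controlling="noncontrolling"), trials_test=late)
    deflections["controlling"].append(res_ctrl.deflection_end.mean())
    deflections["M1-PMd noncontrolling"].append(res_m1.deflection_end.mean())
    deflections["PRR noncontrolling"].append(res_prr.deflection_end.mean())
    gains["M1-PMd noncontrolling"].append(relative_gain(res_m1, res_ctrl).gain_percent)
    gains["PRR noncontrolling"].append(relative_gain(res_prr, res_ctrl).gain_percent)

for name, vals in deflections.items():
    rep = test_deflections(vals)
    print(f"{name:24s} deflection = {rep['mean']:+6.2f} +- {rep['sd']:.2f} mm"
          f"   t({rep['df']}) = {rep['t']:+.2f}, p = {rep['p']:.2e}")
for name, vals in gains.items():
    print(f"{name:24s} relative gain = {np.mean(vals):5.1f}%"
          f" (generator gains were 80% and 40%)")
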