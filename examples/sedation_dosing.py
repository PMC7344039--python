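"""Learn the sedative-dosing policy and measure dose error against the clinician.

The sedation stage uses 14-dimensional states (the patient state plus the
ventilation action just taken) and a 4-bin propofol dose action. Dose MSE is
the mean squared difference between the predicted and logged dose after
mapping bins onto a unit dose grid; lower means the policy doses closer to
the clinician. SAC's supervised term keeps its dosing near the clinician's,
while pure AC drifts wherever the (weak) sedation reward points.
"""

from icusac import SimulatorConfig, TrainConfig, simulate_cohort, train

cohort = simulate_cohort(SimulatorConfig(n_admissions=200, seed=1))

for alg in ("sac", "ac"):
    result = train(cohort, TrainConfig(stage="sed", algorithm=alg,
                                       epsilon=0.5, n_episodes=60, seed=101))
    row = result.curve.iloc[-1]
    print(f"{alg.upper()}: final dose MSE = {row['mse']:.3f}, final AR = {row['ar']:.4f}")
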