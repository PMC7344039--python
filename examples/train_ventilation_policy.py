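"""Train SAC and AC weaning policies and compare their convergence.

Trains both algorithms on the same 200-admission cohort and prints the
held-out accuracy rate (AR: agreement with the clinician's weaning
decisions) over training, plus the first episode at which each policy
sustains AR >= 0.95. The supervised term in SAC pulls the policy toward
the clinician from the start, so it converges in far fewer episodes.
"""

from icusac import SimulatorConfig, TrainConfig, simulate_cohort, train
from icusac.evaluation import episodes_to_threshold

cohort = simulate_cohort(SimulatorConfig(n_admissions=200, seed=1))

for alg in ("sac", "ac"):
    result = train(cohort, TrainConfig(stage="vent", algorithm=alg,
                                       epsilon=0.5, n_episodes=60, seed=101))
    ep95 = episodes_to_threshold(result.curve, "ar", 0.95)
    print(f"{alg.upper()}: final AR = {result.curve['ar'].iloc[-1]:.4f}, "
          f"episodes to sustained AR 0.95 = {ep95 if ep95 is not None else 'not reached'}")
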