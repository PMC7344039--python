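# Methods

## Decision problems

Two MDPs share a 10-minute decision grid over one ICU admission.

**Ventilation stage.** The state is a 13-vector: respiration rate
(breaths/min), heart rate (beats/min), arterial pH, PEEP set (cmH2O), SpO2
(%), FiO2 (fraction), PaO2 (mmHg), plateau pressure (cmH2O), mean airway
pressure (cmH2O), mean non-invasive blood pressure (mmHg), weight (kg),
age (years), and the current ventilation status bit. The action is binary:
keep the patient on the ventilator (0) or wean (1).

**Sedation stage.** The state is the 13-vector plus the ventilation action
just taken (14 dimensions); the action is a propofol dose discretised into
4 bins (0 lightest … 3 deepest). During training the appended ventilation
action is the clinician's logged one; at evaluation time a learned
ventilation policy's action can be substituted instead (the augmentation is
just the 14th feature, so either source plugs into the same network).

The joint space has 8 composite actions; the two components are one-hot
encoded separately (bit 0 = first category), giving a 2-bit and a 4-bit
block with exactly one active bit each.

## Reward

`r = r_vitals + r_vent_off + r_vent_on`, with

* `r_vitals = w_vitals ·` (fraction of configured vitals inside their
  normal range in the successor state). Defaults: `w_vitals = 1` and the
  ten textbook adult ranges listed in `icusac.mdp.NORMAL_RANGES`; weight
  and age carry no range.
* `r_vent_off`: on a weaning **event** (wean action taken while still
  ventilated), `+B = +10` if no reintubation follows within
  `W = 288` steps (48 h — the horizon clinicians use to call a wean
  failed), `−P = −10` if one does. Paid once per event, not per step spent
  off the ventilator: a per-step reading would pay `+B` on every post-wean
  step and swamp the other two components.
* `r_vent_on = −c = −0.5` for every step the successor state is ventilated.

All constants live in `RewardConfig` and are overridable. The reintubation
look-ahead cannot be computed from a single transition, so the caller
supplies `reintubation_follows` from trajectory look-ahead (the simulator
and data loaders do this); the function itself stays pure.

## Function approximators

Three-layer perceptrons, written directly in numpy (forward and backward):
the actor maps the state through 20 rectifier units to a softmax over the
action classes; the critic maps state ⊕ one-hot action through 20 rectifier
units to a single linear Q-value; the supervisor is a 9-hidden-unit softmax
classifier that can be pre-trained on clinician labels and used in place of
raw labels in the supervised term. By default the supervised term is
computed directly against the labels (the behaviour-cloning reading of the
supervision signal); the trained supervisor is an optional label source.
Weights are He-initialised from a seeded generator; greedy actions break
ties toward the lowest index. Every analytic gradient is validated against
central finite differences (1e-5 relative) in the test suite.

## Training loop

Offline: the cohort is fixed, an episode is one shuffled pass over the
training transitions in minibatches of 32. Per batch the TD target
`y = r + γ Q_tar(s′, μ(s′))` uses a hard-copied target critic (synced every
100 critic steps) and the current actor's greedy action at `s′`
(`bootstrap="expected"` switches to the expectation over the softmax
policy); `y = r` at terminals and when γ = 0. The critic descends the mean
squared TD loss; the actor ascends
`(1−ε)·mean(δ · ∇log π(a|s)) + ε·∇ mean(log π(label|s))`. In the logged
cohort the taken action *is* the clinician action, so the reinforcement
term reinforces/suppresses logged actions by the sign of their TD error
while the supervision term always pulls toward them.

`algorithm="ac"` and `"bc"` run the same loop (same RNG stream) with the
pure reinforcement or pure supervision gradient computed on separate code
paths; the tests check bit-identity of their parameter trajectories with
SAC at ε=0 and ε=1, which guards the blend implementation.

Defaults: γ = 0.95, ε = 0.5, α_critic = 1e-3, α_actor = 3e-3,
target sync every 100 steps, batch 32, 20% of admissions held out.
α_actor was set by requiring that plain-SGD behaviour cloning reach ≥99%
held-out agreement on a noise-free cohort within 200 episodes (the
calibration property of the evaluation stack) while SAC and AC remain
stable; 1e-3 satisfies the stability half but plateaus at 98.96% inside
that budget. States are z-scored with statistics fitted on the training
split; the scaler is saved as part of the policy.

## Synthetic cohort

Each admission evolves a latent health `h_t ∈ [0, 1.05]`:
`h_{t+1} = h_t + ρ(1 − h_t) − 0.004·sed + σ_h(1 − 0.15·sed/3)·ξ_t` with
recovery rate ρ = 0.04, process noise σ_h = 0.02, `ξ_t ~ N(0,1)`, and
`h_0 ~ U(0.15, 0.45)` (sick on admission). Sedation therefore trades noise
damping against a recovery drag, which is what makes the sedation MDP a
real decision problem rather than a labelling exercise.

The ten ranged vitals are affine read-outs
`v_i = mid_i + d_i · 1.5 · (1 − h_t) · half_i + η_i · half_i`, with
per-vital deviation direction `d_i = ±1`, `η_i ~ N(0, 0.08)`: at `h = 1`
every vital sits mid-range, at `h = 0` it sits 1.5 half-widths outside.
Weight and age are per-admission constants. Inverting the read-out and
averaging gives a *health score* that equals `h_t` up to small noise and is
an exact deterministic function of the state — so clinician labels are
learnable from the state alone, and with zero label noise a supervised
learner can reach 100% agreement (the calibration invariant).

The clinician policy thresholds the score: wean once it reaches 0.6, with
hysteresis — an extubated patient is reintubated only if the score falls
0.15 below the threshold (without hysteresis the rule flaps on score noise
and nearly every admission becomes multiple-intubation). The sedative bin
is the score's interval among breakpoints (0.25, 0.5, 0.75), deeper
sedation when sicker; a score exactly at a breakpoint joins the upper
interval. With probability `clinician_noise = 0.05` the logged action is
re-drawn: the dose uniformly, the wean decision uniformly only while
ventilated (a charted deviation does not spuriously reintubate a stable
extubated patient). A wean ordered below threshold fails with probability
0.7, forcing reintubation 1–6 steps later.

Defaults: 200 admissions, stay length ~ N(72, 18²) steps (min 24; 12 h
mean keeps the benchmark desk-scale while covering the full
sick-to-recovered arc), 30% of admissions get noise-free labels and form
the *expert* stratum; the rest split into *single* vs *multiple
intubation* (≥ 2 intubation events), expert taking precedence.

What the simulator does **not** emulate: pharmacokinetics, inter-vital
correlation structure beyond the shared latent, missingness, measurement
artefacts, mortality, or admission heterogeneity beyond `h_0` and
demographics. Passing tests therefore show the learning stack is correct
and that supervision accelerates convergence on data with this structure —
not that the learned policies transfer to real patients.

## Evaluation

**AR** — fraction of test states where the greedy actor action equals the
clinician label (greedy only, no sampling). **Dose MSE** — mean squared
difference after mapping bins through a dose grid (default unit spacing
0,1,2,3, configurable; real bin edges would replace it). **Episodes to
threshold** — first episode at which a curve metric crosses a threshold
and stays there for a 3-episode patience window (truncated windows at the
curve's end count if every remaining episode qualifies); never-reached is
reported explicitly and treated as +∞ in seed medians, censored at the
episode horizon in the JSON summary. Reports are stratified by
expert / single / multiple intubation.

With 5% uniform label noise the achievable ventilation AR is ≈ 0.975
(0.95 + 0.05·½), so the 0.95 convergence threshold sits below the ceiling
but well above chance.

## Numerical choices and degenerate inputs

Softmax is computed with max-shift; `log(0)` is guarded by an additive
1e-300 (never reached for finite logits). Ties in greedy actions go to the
lowest index. Trajectory CSVs write floats with shortest-round-trip
`repr`, so read → write cycles are byte-stable. A measurement series with
fewer than two points resamples as a constant fill with a warning; SVR
resampling beyond the last observation reports the regression's own
prediction. Empty batches, empty datasets, out-of-range ε/γ, unknown
vitals in reward ranges and dimension mismatches raise with specific
messages.

## Problem sizes

The bundled benchmark is 200 admissions (~14k transitions), 60 training
episodes, medians over 5 seeds; behaviour-cloning calibration uses 100
noise-free admissions and up to 200 episodes. These sizes were chosen so
the full suite and the reproduction script each run in minutes on one CPU
while leaving the qualitative contrasts (supervised vs unsupervised
convergence speed, dose error ordering) large and stable across seeds.

## Known limitations

* The reinforcement-only baseline (AC) learns from logged actions only
  (no counterfactual exploration), so its asymptotic AR is limited by how
  well TD errors on clinician actions separate good from bad decisions.
* The supervisor-network path shares the actor's label interface; joint
  actor+supervisor co-training beyond the shared supervised term is not
  implemented.
* Off-policy value estimates of learned policies (e.g. importance
  sampling) are out of scope; reported Q-values are the critic's own.
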