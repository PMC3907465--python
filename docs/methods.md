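# Methods

## Model

The decoder is an actor-critic reinforcement learner for a two-action,
state-based BMI task. The *actor* maps a normalized neural state
`X ∈ [-1,1]^n` to one of two robot actions through a 3-layer feedforward
network: 5 hidden tanh nodes, `OutH_i = tanh(WH_i·X + b_i)`, and 2 output
nodes whose action values read the binarized hidden outputs,
`AV_j = WO_j·S(OutH)` with `S` the sign function. The greedy action is taken
each trial. The *critic* reduces the trial outcome to a single bit
`f ∈ {+1, −1}` (rewarded or not); an ideal critic emits
`f = +1 iff action == target`, and a noisy critic agrees with the ideal one
i.i.d. with a configurable probability in [0.5, 1].

Learning is Hebbian reward/penalty, applied layer-wise with `post` the node's
tanh activation and `pre` its presynaptic vector (`[X; 1]` for the hidden
layer — the bias learns as a weight on a constant +1 input — and `S(OutH)`
for the output layer):

    ΔW = µ · [ f·(S(post) − post) + (f − 1)·post ] · pre
       = µ · (f·S(post) − post) · pre

Properties that define this rule: under reward only the first term is
nonzero and it vanishes as `|post| → 1` (adaptation stops automatically at a
committed, rewarded policy); under punishment both terms act, driving the
node toward the opposite sign at full strength even from saturation; every
weight change is proportional to its learning rate and its presynaptic
activity (locality). The output nodes' postsynaptic activity is `tanh(AV_j)`
— each node, including the outputs, is a tanh processing element — and both
output nodes are updated with the single global feedback. No separate
punishment-scale coefficient is used (implicitly λ = 1).

After each action the session's replay buffer (every completed trial's
normalized state and target, in order) is swept 10 times; each sweep re-runs
the forward pass with the *current* weights, takes the greedy action, and
re-derives feedback from the stored target. Re-evaluation (rather than
replaying stored action/feedback pairs) lets replay reflect the improving
policy; the critic here can always score any action against a known target.
A noisy critic corrupts every feedback event independently, including replay.

## Parameters

| parameter | default | meaning |
|---|---|---|
| hidden nodes | 5 | actor capacity; deliberately parsimonious |
| output nodes | 2 | one per robot action (two-target task) |
| µ_H, µ_O | 0.01, 0.05 | hidden / output learning rates |
| init range | ±0.075 | uniform random initial weights → random exploration |
| replay passes | 10 | buffer sweeps per action ("epoching") |
| n_trials | 30 | session length; evaluation over trials 6–30 |
| sliding window | 5 trials | convergence/recovery readout |
| carry-over trial | 25 | weights snapshot reused by the next session |
| normalizer floor | 1.0 | minimum running-max estimate (no division by zero) |

## Synthetic sessions

The generator emulates the *statistical class structure* of two-target
motor-cortex recordings, not their biophysics: `n_signals = 20` signals
(arrays in this preparation yield ~18–21 usable multiunit/single-unit
signals), spike counts in a 2 s post-go window, Poisson given the trial
class — the minimal model for windowed counts, since no count law is implied
by the recordings themselves. On `B` trials every signal fires at its 8 Hz
baseline; on `A` trials a fixed 60% subset doubles to 16 Hz. These rates are
stand-ins chosen to give strongly separable classes consistent with the ~90%
closed-loop performance regime being emulated; they are not calibrated to any
animal. Labels come in pseudo-random balanced blocks of ten (5 A + 5 B,
shuffled; a final partial block balanced to within one), implementing
"roughly equivalent proportions" in a testable form. All randomness flows
from one session seed through named substreams (profiles, labels, counts).

What the generator does *not* model — correlated populations, rate drift
within a session, non-Poisson dispersion, neurons gradually retuning to the
decoder — bounds what passing tests show: they validate the algorithm's
adaptive behavior under clean stationary-or-abruptly-perturbed inputs, not
performance on real recordings.

Normalization maps count `c` to `2·c/max − 1` against a per-signal running
maximum (the simplest map onto the stated [−1, 1] range with a running-max
estimate). A zero count on a visible channel maps to −1 (a convention; the
range endpoints are not otherwise pinned down). Masked channels — signals
the recording system is not currently detecting — contribute exactly 0 input
and leave the running maximum untouched: an undetected unit is absence of
evidence, not a 0 Hz unit, and zero drive yields zero Hebbian update on its
weights, which is what lets "found" neurons join gracefully later.

## Perturbations, baseline, information

Input perturbations are declarative masks at fixed dimensionality (the actor
never resizes): `loss` hides a seeded random fraction (default 50%) after a
switch trial (default 10); `gain` hides that fraction *through* the switch
trial. Loss and gain specs sharing a channel seed affect identical channels.

The non-adaptive baseline is a Wiener classifier: a least-squares linear map
from `[X; 1]` to one-hot class targets, fitted on the first five normalized
trials of a session and frozen. With 5 equations and n+1 ≥ 21 unknowns per
class the fit is underdetermined; the minimum-norm pseudoinverse solution is
used (parameter-free, deterministic; an optional ridge penalty is exposed).
The baseline consumes the same normalization stream as the adaptive decoder
so comparisons isolate adaptivity. Exact score ties predict class A.

Per-signal mutual information with the binary target uses the plug-in
estimator on a discretized table: raw integer counts as categories when a
signal takes ≤ 16 distinct values, else 8 quantile bins (configurable). No
bias correction — the analyses that matter use large n or relative
quantities. The input-loss curve averages MI over *all* nominal channels
with lost channels contributing zero bits (a zeroed signal is constant),
relative to the intact average; in expectation this is linear in the
surviving fraction, so losing half the signals removes half the available
information. Averaging over survivors only would not have this property and
is rejected.

## Numerical and design choices

- `sign(0) := +1`, fixed so the pipeline is deterministic (probability-zero
  event under continuous weights).
- Hidden outputs are deterministic tanh values binarized inside the
  action-value readout; no layer is stochastically sampled. Action
  *selection* is stochastic only on exact action-value ties, which a fair
  coin resolves (and flags) to avoid systematic bias in a 2-action task.
- Seeds: a master seed plus counter-based child derivation
  (`SeedSequence(master, spawn_key=(counter, …))`), so adding Monte-Carlo
  runs never perturbs earlier runs; every experiment is bit-reproducible
  from its config and master seed.
- Multi-session runs hold the signal profiles fixed across sessions (the
  same population recorded across days) and redraw labels and counts per
  session; weights carry over from trial 25, the replay buffer does not.
- Degenerate inputs: an empty replay buffer is a no-op; a single-class
  Wiener training set fits with a warning; all-silent first trials are
  handled by the normalizer floor.

## Problem sizes

Monte-Carlo analyses use 100 sessions of 30 trials; the information analyses
use one 1000-trial session and 500 random subsets per loss fraction;
multi-session checks use 20 replicates of 5 contiguous sessions. At these
sizes the full test suite runs in ~3 minutes and the acceptance script in
~2 minutes on one CPU.

## Known limitations

- The scrambled-label surrogate control converges to slightly *below* 50%
  (~45–47% rather than exactly chance). Cause: with uninformative inputs,
  replay training tips the policy toward the buffer's current label
  majority, while the balanced-block trial order makes the upcoming labels
  lean toward the buffer minority; majority-matching therefore scores below
  50%. This is an inherent interaction of balanced trial blocks with
  replay-based learning, not a decoding artifact — the control still
  demonstrates that the decoder cannot perform *above* chance without real
  neural structure.
- Recovery times measured by the 5-trial sliding window are flattered
  immediately after a perturbation because the window still contains
  pre-switch successes; the same readout is applied to every condition, so
  comparisons remain fair.
- Two-action architecture only; the update rule generalizes to more actions
  but this artifact does not implement that.
- No robot kinematics, reward-delivery latency, or subject-behavior
  modeling; session length is just `n_trials`.
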