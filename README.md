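# rlbmi

An actor-critic, Hebbian reinforcement-learning decoder for a closed-loop
brain-machine interface (BMI), coupled to a synthetic motor-cortex session
simulator for a two-target reaching task.

## The problem

Most BMI decoders are fitted by supervised learning on a calibration data set
and then frozen. That breaks down in chronic use: electrodes fail, neurons
appear and disappear from recordings, and firing patterns drift, so the frozen
map between neural activity and intended action decays and needs expert
recalibration. This package implements the alternative: a decoder that starts
from random weights and improves itself online from nothing but a binary
"good/bad" feedback signal, so it can self-initialize, track input-space
perturbations (half the input channels abruptly lost, or doubling when "new"
neurons are found), and run for many sessions without being reset.

It is written for computational-neuroscience and neural-engineering work at
desk scale: every experiment runs in seconds to minutes on one CPU against
synthetic spike-count sessions whose class structure mimics the recordings the
architecture was designed for (two trial types: `A` with modulated firing on a
subset of signals, `B` with static baseline firing).

## The decoder

The actor is a fully connected 3-layer network over the normalized spike-count
vector `X ∈ [-1,1]^n` (per-signal running-max normalization, updated every
trial). Five hidden nodes compute

    OutH_i = tanh(WH_i · X + b_i)

and two output nodes score the two robot actions through the *signs* of the
hidden outputs,

    AV_j = WO_j · S(OutH),      S(v) = +1 if v ≥ 0 else -1,

with the highest-valued action executed. A critic reduces the trial to one bit
of feedback, `f = +1` (rewarded) or `f = -1`, which gates a local Hebbian
reward/penalty update applied per layer (post = the node's tanh activation,
pre = its input vector):

    ΔW = µ · [ f·(S(post) − post) + (f − 1)·post ] · pre

Under reward only the first term acts and vanishes as |post| → 1, so
adaptation stops automatically once the policy has committed; under punishment
both terms act, pushing the node toward the opposite sign at full strength.
Learning rates are µ_H = 0.01 (hidden) and µ_O = 0.05 (output); weights start
uniform on ±0.075. After every action the decoder replays a buffer of all the
session's trials ten times ("epoching") to speed early adaptation.

Around the decoder the package provides the full experiment suite: Monte-Carlo
restarts, a label-scrambled surrogate control, abrupt loss/gain input
perturbations with recovery statistics, a static Wiener (least-squares linear)
classifier baseline, per-signal mutual information with the target and its
decay under graded input loss, a critic-accuracy sweep, and a contiguous
multi-session protocol that carries the trial-25 weights into the next session.

## Worked example

```python
from rlbmi import GeneratorConfig, SessionConfig, default_session, run_session

data = default_session(GeneratorConfig())        # 30 trials, 20 signals
res = run_session(data, SessionConfig(seed=1))   # fresh ±0.075 random weights
print("accuracy over trials 6-30:", res.overall_accuracy)
print("per-trial hits:", "".join("+" if r.correct else "." for r in res.records))
```

prints

```
accuracy over trials 6-30: 0.92
per-trial hits: ..+.+..+++++++++++++++++++++++
```

The decoder starts with random actions (misses in the first few trials), finds
an effective mapping within a handful of trials, and then tracks the target
essentially perfectly; 92% of trials 6–30 are correct in this session. The
same engine drives the CLI:

```sh
rlbmi simulate --out session.csv --seed 1          # write a synthetic session
rlbmi run --config config.json --out results/      # run a named experiment
rlbmi report --dir results/                        # tabulate key metrics
```

where `config.json` holds an `ExperimentConfig` (experiment name, generator
and session settings, number of Monte-Carlo runs, master seed); every result
JSON embeds the config and seed that produced it and is byte-reproducible.

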