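"""The session engine: closed-loop trial-by-trial decoding and learning.

Each trial runs the pipeline
    perturbation mask -> normalize -> hidden layer -> action values
    -> greedy action -> critic feedback -> replay-buffer epoching,
logging the action, target, emitted feedback and correctness.  Accuracy
is read out two ways, following the study protocol: the 5-trial sliding
window (convergence/recovery readout) and the overall accuracy over an
evaluation window of trials 6-30 (the first 5 trials being the initial
adaptation period).

Monte-Carlo restarts re-run sessions with fresh random initial weights
under seeds derived from a master seed by a counter-based scheme
(``SeedSequence(master, spawn_key=(run,))``), so adding runs never
perturbs earlier ones.  The contiguous multi-session protocol carries
the weights learned by trial 25 of one session into the next, with the
replay buffer reset per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .actor import ActorWeights, action_values, forward_hidden, init_weights, select_action
from .hebbian import Critic, CriticSpec, LearningRates, ReplayBuffer, epoch_update, make_critic
from .perturbation import PerturbationSpec, mask_for_trial
from .preprocess import NormalizerState, update_and_normalize
from .synth import GeneratorConfig, TrialRecord, default_session, generate_session, make_profiles

__all__ = [
    "SessionConfig",
    "TrialLog",
    "SessionResult",
    "MonteCarloSummary",
    "run_session",
    "sliding_accuracy",
    "run_montecarlo",
    "run_multisession",
    "first_sustained_run",
    "recovery_trials",
    "derive_seed",
]

SNAPSHOT_TRIAL = 25  # weights carried between contiguous sessions


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 30
    eval_window: tuple[int, int] = (6, 30)
    rates: LearningRates = field(default_factory=LearningRates)
    replay_passes: int = 10
    critic: CriticSpec = field(default_factory=CriticSpec)
    perturbation: PerturbationSpec | None = None
    seed: int = 0
    record_weights: bool = False
    record_states: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.eval_window
        if not (1 <= lo <= hi <= self.n_trials):
            raise ValueError("eval_window must lie within [1, n_trials]")
        if self.replay_passes < 0:
            raise ValueError("replay_passes must be >= 0")


@dataclass(frozen=True)
class TrialLog:
    index: int
    target: str
    action: str
    feedback: int
    correct: bool
    tie_broken: bool
    n_visible: int
    delta_w: float


@dataclass
class SessionResult:
    records: list[TrialLog]
    sliding: np.ndarray
    overall_accuracy: float
    final_weights: ActorWeights
    weights_at_trial_25: ActorWeights | None
    weight_trajectory: list[ActorWeights] | None
    config: SessionConfig
    states: list[np.ndarray] | None = None

    def to_dict(self) -> dict:
        return {
            "records": [
                {
                    "trial": r.index,
                    "target": r.target,
                    "action": r.action,
                    "feedback": r.feedback,
                    "correct": bool(r.correct),
                    "tie_broken": bool(r.tie_broken),
                    "n_visible": r.n_visible,
                    "delta_w": r.delta_w,
                }
                for r in self.records
            ],
            "sliding_accuracy": self.sliding.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "eval_window": list(self.config.eval_window),
            "seed": self.config.seed,
            "final_weights": self.final_weights.to_dict(),
        }


@dataclass
class MonteCarloSummary:
    accuracies: np.ndarray
    mean: float
    sd: float
    mean_sliding: np.ndarray
    results: list[SessionResult]


def derive_seed(master_seed: int, *counters: int) -> int:
    """Counter-based child seed (stable under adding later counters)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(counters))
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def sliding_accuracy(records: Sequence[TrialLog] | Sequence[bool], window: int = 5) -> np.ndarray:
    """Trailing-window success rate; early trials use the truncated window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    correct = np.array(
        [bool(getattr(r, "correct", r)) for r in records], dtype=float
    )
    out = np.empty_like(correct)
    for t in range(len(correct)):
        out[t] = correct[max(0, t - window + 1) : t + 1].mean()
    return out


def run_session(
    data: Sequence[TrialRecord],
    config: SessionConfig,
    initial_weights: ActorWeights | None = None,
) -> SessionResult:
    """Run one closed-loop session over ``data``; deterministic given seeds."""
    if len(data) != config.n_trials:
        raise ValueError(
            f"data has {len(data)} trials but config.n_trials={config.n_trials}"
        )
    n = len(data[0].counts)
    ss = np.random.SeedSequence(config.seed)
    ss_init, ss_run = ss.spawn(2)
    rng = np.random.default_rng(ss_run)
    weights = (
        initial_weights.copy()
        if initial_weights is not None
        else init_weights(n, np.random.default_rng(ss_init))
    )
    critic: Critic = make_critic(config.critic)
    pert = config.perturbation or PerturbationSpec(kind="none")
    norm_state = NormalizerState.fresh(n)
    buffer = ReplayBuffer(passes=config.replay_passes)

    records: list[TrialLog] = []
    trajectory: list[ActorWeights] | None = [] if config.record_weights else None
    states: list[np.ndarray] | None = [] if config.record_states else None
    weights_25: ActorWeights | None = None

    for trial in data:
        t = trial.index
        mask = mask_for_trial(pert, t, n)
        state, norm_state = update_and_normalize(trial.counts, norm_state, mask)
        if states is not None:
            states.append(state.x.copy())
        hidden = forward_hidden(weights, state.x)
        decision = select_action(action_values(weights, hidden), rng, hidden)
        f = critic(decision.action, trial.label, rng)
        buffer.append(state, trial.label)
        before = weights
        weights = epoch_update(weights, buffer, critic, config.rates, rng)
        delta = float(
            np.sqrt(
                np.sum((weights.WH - before.WH) ** 2)
                + np.sum((weights.b - before.b) ** 2)
                + np.sum((weights.WO - before.WO) ** 2)
            )
        )
        records.append(
            TrialLog(
                index=t,
                target=trial.label,
                action=decision.action,
                feedback=f,
                correct=decision.action == trial.label,
                tie_broken=decision.tie_broken,
                n_visible=int(mask.sum()),
                delta_w=delta,
            )
        )
        if trajectory is not None:
            trajectory.append(weights.copy())
        if t == SNAPSHOT_TRIAL:
            weights_25 = weights.copy()

    lo, hi = config.eval_window
    eval_correct = [r.correct for r in records[lo - 1 : hi]]
    return SessionResult(
        records=records,
        sliding=sliding_accuracy(records),
        overall_accuracy=float(np.mean(eval_correct)),
        final_weights=weights,
        weights_at_trial_25=weights_25,
        weight_trajectory=trajectory,
        config=config,
        states=states,
    )


def _session_data_for_run(
    generator: GeneratorConfig | None,
    data: Sequence[TrialRecord] | None,
    master_seed: int,
    run: int,
) -> Sequence[TrialRecord]:
    if data is not None:
        return data
    if generator is None:
        raise ValueError("provide either fixed data or a GeneratorConfig")
    return default_session(replace(generator, seed=derive_seed(master_seed, run, 0)))


def run_montecarlo(
    config: SessionConfig,
    n_runs: int,
    generator: GeneratorConfig | None = None,
    data: Sequence[TrialRecord] | None = None,
    data_transform=None,
) -> MonteCarloSummary:
    """Repeat run_session with fresh random initial conditions per run.

    Run ``k`` draws its session data (unless fixed ``data`` is given),
    its weight-init/selection seed, and -- when a perturbation is
    configured -- its affected-channel subset from seeds derived from
    ``config.seed`` and the run counter.  ``data_transform(data, seed)``
    (e.g. the surrogate label-decoupling scramble) is applied per run
    with its own derived seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    for k in range(n_runs):
        run_data = _session_data_for_run(generator, data, config.seed, k)
        if data_transform is not None:
            run_data = data_transform(run_data, derive_seed(config.seed, k, 3))
        run_cfg = replace(config, seed=derive_seed(config.seed, k, 1))
        if config.perturbation is not None and config.perturbation.kind != "none":
            run_cfg = replace(
                run_cfg,
                perturbation=replace(
                    config.perturbation, channel_seed=derive_seed(config.seed, k, 2)
                ),
            )
        results.append(run_session(run_data, run_cfg))
    acc = np.array([r.overall_accuracy for r in results])
    sliding = np.stack([r.sliding for r in results])
    return MonteCarloSummary(
        accuracies=acc,
        mean=float(acc.mean()),
        sd=float(acc.std(ddof=1)) if n_runs > 1 else 0.0,
        mean_sliding=sliding.mean(axis=0),
        results=results,
    )


def run_multisession(
    generator: GeneratorConfig,
    config: SessionConfig,
    n_sessions: int,
) -> list[SessionResult]:
    """Contiguous sessions: carry trial-25 weights forward, reset the buffer.

    The signal population (which channels are modulated) is fixed across
    sessions -- the same neurons are recorded day after day -- while each
    session draws fresh labels and spike counts.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if config.n_trials < SNAPSHOT_TRIAL:
        raise ValueError(
            f"multi-session carry-over needs n_trials >= {SNAPSHOT_TRIAL}"
        )
    profiles = make_profiles(generator)
    results: list[SessionResult] = []
    carried: ActorWeights | None = None
    for s in range(n_sessions):
        data = generate_session(
            profiles,
            generator.n_trials,
            generator.window_s,
            derive_seed(config.seed, s, 10),
        )
        cfg = replace(config, seed=derive_seed(config.seed, s, 11))
        res = run_session(data, cfg, initial_weights=carried)
        results.append(res)
        carried = res.weights_at_trial_25
    return results


# ---------------------------------------------------------------------------
# Readouts used by the convergence and recovery analyses

def first_sustained_run(records: Sequence[TrialLog], run_length: int = 5) -> int | None:
    """1-based index of the first trial opening ``run_length`` straight hits."""
    correct = [r.correct for r in records]
    for t in range(len(correct) - run_length + 1):
        if all(correct[t : t + run_length]):
            return t + 1
    return None


def recovery_trials(
    records: Sequence[TrialLog],
    switch_trial: int,
    threshold: float = 0.8,
    window: int = 5,
) -> int | None:
    """Trials after ``switch_trial`` until the sliding accuracy regains
    ``threshold``; None if it never does within the session."""
    sliding = sliding_accuracy(records, window)
    for t in range(switch_trial, len(records)):  # t is 0-based; trial t+1
        if sliding[t] >= threshold:
            return (t + 1) - switch_trial
    return None
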