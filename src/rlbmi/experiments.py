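"""End-to-end experiment runner and result serialization.

Each figure-level analysis of the study maps to one experiment name:

===================  ======================================================
baseline_session     one closed-loop session, full per-trial log
montecarlo           restart stability: n_runs sessions, fresh random init
scramble_control     surrogate test on label-decoupled (scrambled) sessions
loss_perturbation    abrupt 50% input loss after trial 10, recovery stats
gain_perturbation    50% of inputs hidden through trial 10, then revealed
mi_loss_curve        relative average mutual information vs loss fraction
critic_sweep         mean accuracy as critic accuracy varies 0.5 -> 1.0
multisession         contiguous sessions carrying trial-25 weights forward
wiener_comparison    adaptive decoder vs frozen Wiener baseline post-switch
===================  ======================================================

Configs are JSON (versioned schema, fully self-describing: a result file
embeds the config it was produced from plus a content hash), tabular
outputs are CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import fit_wiener, wiener_session_accuracy
from .closed_loop import (
    SessionConfig,
    derive_seed,
    first_sustained_run,
    recovery_trials,
    run_montecarlo,
    run_multisession,
    run_session,
)
from .hebbian import CriticSpec, LearningRates
from .info_metrics import avg_mi_under_loss
from .perturbation import PerturbationSpec
from .synth import GeneratorConfig, default_session, scramble_session

__all__ = ["EXPERIMENTS", "ExperimentConfig", "run_experiment", "summarize"]

SCHEMA_VERSION = 1

EXPERIMENTS = (
    "baseline_session",
    "montecarlo",
    "scramble_control",
    "loss_perturbation",
    "gain_perturbation",
    "mi_loss_curve",
    "critic_sweep",
    "multisession",
    "wiener_comparison",
)

CRITIC_SWEEP_ACCURACIES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
MI_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    n_runs: int = 100
    n_sessions: int = 5
    mi_trials: int = 1000
    mi_draws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.n_runs < 1 or self.n_sessions < 1:
            raise ValueError("n_runs and n_sessions must be >= 1")
        # the master seed governs every substream; keep the session config in step
        object.__setattr__(self, "session", replace(self.session, seed=self.seed))
        pert = self.session.perturbation
        if (
            self.experiment in ("loss_perturbation", "gain_perturbation", "wiener_comparison")
            and pert is not None
            and pert.switch_trial >= self.session.n_trials
        ):
            raise ValueError("switch_trial must fall before the last trial")
        if (
            self.experiment in ("loss_perturbation", "gain_perturbation", "wiener_comparison")
            and pert is None
            and PerturbationSpec().switch_trial >= self.session.n_trials
        ):
            raise ValueError(
                "default switch_trial falls outside the session; provide a perturbation spec"
            )

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "experiment": self.experiment,
            "generator": dataclasses.asdict(self.generator),
            "session": {
                "n_trials": self.session.n_trials,
                "eval_window": list(self.session.eval_window),
                "rates": dataclasses.asdict(self.session.rates),
                "replay_passes": self.session.replay_passes,
                "critic_accuracy": self.session.critic.accuracy,
                "perturbation": (
                    dataclasses.asdict(self.session.perturbation)
                    if self.session.perturbation
                    else None
                ),
            },
            "n_runs": self.n_runs,
            "n_sessions": self.n_sessions,
            "mi_trials": self.mi_trials,
            "mi_draws": self.mi_draws,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        s = d.get("session", {})
        pert = s.get("perturbation")
        session = SessionConfig(
            n_trials=s.get("n_trials", 30),
            eval_window=tuple(s.get("eval_window", (6, 30))),
            rates=LearningRates(**s.get("rates", {})),
            replay_passes=s.get("replay_passes", 10),
            critic=CriticSpec(accuracy=s.get("critic_accuracy", 1.0)),
            perturbation=PerturbationSpec(**pert) if pert else None,
            seed=d.get("seed", 0),
        )
        return cls(
            experiment=d["experiment"],
            generator=GeneratorConfig(**d.get("generator", {})),
            session=session,
            n_runs=d.get("n_runs", 100),
            n_sessions=d.get("n_sessions", 5),
            mi_trials=d.get("mi_trials", 1000),
            mi_draws=d.get("mi_draws", 500),
            seed=d.get("seed", 0),
        )


def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _seeded_session_cfg(cfg: ExperimentConfig) -> SessionConfig:
    return replace(cfg.session, seed=cfg.seed)


def _mc_table(summary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run": np.arange(len(summary.accuracies)),
            "accuracy": summary.accuracies,
        }
    )


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute one named experiment; write JSON summary + CSV logs.

    Returns the summary dict (also written to ``<out_dir>/result.json``).
    """
    out = Path(out_dir)
    session_cfg = _seeded_session_cfg(cfg)
    summary: dict = {
        "experiment": cfg.experiment,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg.to_dict()),
        "seed": cfg.seed,
    }
    tables: dict[str, pd.DataFrame] = {}

    if cfg.experiment == "baseline_session":
        data = default_session(replace(cfg.generator, seed=derive_seed(cfg.seed, 0, 0)))
        res = run_session(data, session_cfg)
        summary["overall_accuracy"] = res.overall_accuracy
        summary["first_sustained_run"] = first_sustained_run(res.records)
        summary["session"] = res.to_dict()
        tables["trials"] = pd.DataFrame(
            [
                {
                    "trial": r.index,
                    "target": r.target,
                    "action": r.action,
                    "feedback": r.feedback,
                    "correct": r.correct,
                    "sliding_accuracy": s,
                    "delta_w": r.delta_w,
                }
                for r, s in zip(res.records, res.sliding)
            ]
        )

    elif cfg.experiment == "montecarlo":
        mc = run_montecarlo(session_cfg, cfg.n_runs, generator=cfg.generator)
        starts = [first_sustained_run(r.records) for r in mc.results]
        summary["mean_accuracy"] = mc.mean
        summary["sd_accuracy"] = mc.sd
        summary["median_first_sustained_run"] = _median_or_none(starts)
        summary["mean_sliding"] = mc.mean_sliding.tolist()
        tables["runs"] = _mc_table(mc)

    elif cfg.experiment == "scramble_control":
        mc = run_montecarlo(
            session_cfg,
            cfg.n_runs,
            generator=cfg.generator,
            data_transform=scramble_session,
        )
        summary["mean_accuracy"] = mc.mean
        summary["sd_accuracy"] = mc.sd
        tables["runs"] = _mc_table(mc)

    elif cfg.experiment in ("loss_perturbation", "gain_perturbation"):
        kind = "loss" if cfg.experiment == "loss_perturbation" else "gain"
        pert = cfg.session.perturbation or PerturbationSpec(kind=kind)
        pert = replace(pert, kind=kind)
        mc = run_montecarlo(
            replace(session_cfg, perturbation=pert), cfg.n_runs, generator=cfg.generator
        )
        recov = [
            recovery_trials(r.records, pert.switch_trial) for r in mc.results
        ]
        summary["mean_accuracy"] = mc.mean
        summary["median_recovery_trials"] = _median_or_none(recov)
        summary["n_never_recovered"] = sum(r is None for r in recov)
        summary["mean_sliding"] = mc.mean_sliding.tolist()
        tables["runs"] = _mc_table(mc).assign(
            recovery_trials=[r if r is not None else -1 for r in recov]
        )
        tables["sliding"] = pd.DataFrame(
            {"trial": np.arange(1, len(mc.mean_sliding) + 1), "mean_sliding": mc.mean_sliding}
        )

    elif cfg.experiment == "mi_loss_curve":
        gen = replace(
            cfg.generator, n_trials=cfg.mi_trials, seed=derive_seed(cfg.seed, 0, 0)
        )
        session = default_session(gen)
        table = avg_mi_under_loss(
            session, MI_FRACTIONS, n_draws=cfg.mi_draws, seed=derive_seed(cfg.seed, 0, 1)
        )
        summary["mi_curve"] = table.to_dict(orient="records")
        tables["mi_curve"] = table

    elif cfg.experiment == "critic_sweep":
        rows = []
        for i, acc in enumerate(CRITIC_SWEEP_ACCURACIES):
            cfg_i = replace(
                session_cfg,
                critic=CriticSpec(accuracy=acc),
                eval_window=(1, session_cfg.n_trials),
                seed=derive_seed(cfg.seed, 100 + i),
            )
            mc = run_montecarlo(cfg_i, cfg.n_runs, generator=cfg.generator)
            rows.append(
                {"critic_accuracy": acc, "mean_accuracy": mc.mean, "sd_accuracy": mc.sd}
            )
        table = pd.DataFrame(rows)
        summary["sweep"] = rows
        tables["sweep"] = table

    elif cfg.experiment == "multisession":
        results = run_multisession(cfg.generator, session_cfg, cfg.n_sessions)
        rows = []
        for s, res in enumerate(results, start=1):
            first25 = float(np.mean([r.correct for r in res.records[:25]]))
            rows.append(
                {
                    "session": s,
                    "first25_accuracy": first25,
                    "overall_accuracy": res.overall_accuracy,
                }
            )
        summary["sessions"] = rows
        tables["sessions"] = pd.DataFrame(rows)

    elif cfg.experiment == "wiener_comparison":
        kind = (cfg.session.perturbation or PerturbationSpec(kind="loss")).kind
        if kind == "none":
            kind = "loss"
        pert = replace(
            cfg.session.perturbation or PerturbationSpec(kind=kind), kind=kind
        )
        mc = run_montecarlo(
            replace(session_cfg, perturbation=pert, record_states=True),
            cfg.n_runs,
            generator=cfg.generator,
        )
        post = slice(pert.switch_trial, None)
        rl_acc, wi_acc = [], []
        for res in mc.results:
            X = np.stack(res.states)
            labels = [r.target for r in res.records]
            model = fit_wiener(X[:5], labels[:5])
            wi_acc.append(wiener_session_accuracy(model, X, labels, post))
            rl_acc.append(
                float(np.mean([r.correct for r in res.records[post]]))
            )
        summary["rlbmi_post_switch_accuracy"] = float(np.mean(rl_acc))
        summary["wiener_post_switch_accuracy"] = float(np.mean(wi_acc))
        tables["runs"] = pd.DataFrame(
            {"run": np.arange(cfg.n_runs), "rlbmi": rl_acc, "wiener": wi_acc}
        )

    out.mkdir(parents=True, exist_ok=True)
    with open(out / "result.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    return summary


def _median_or_none(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.median(vals)) if vals else None


_KEY_METRICS = (
    "overall_accuracy",
    "mean_accuracy",
    "sd_accuracy",
    "median_first_sustained_run",
    "median_recovery_trials",
    "rlbmi_post_switch_accuracy",
    "wiener_post_switch_accuracy",
)


def summarize(results_dir: str | Path) -> str:
    """Plain-text table of key metrics across all result.json files found."""
    rows = []
    for path in sorted(Path(results_dir).glob("**/result.json")):
        try:
            with open(path) as fh:
                res = json.load(fh)
        except (json.JSONDecodeError, OSError):
            rows.append({"experiment": f"(corrupt: {path})"})
            continue
        row = {"experiment": res.get("experiment", "?")}
        for key in _KEY_METRICS:
            if res.get(key) is not None:
                row[key] = res[key]
        rows.append(row)
    if not rows:
        return "(no results found)\n"
    frame = pd.DataFrame(rows).sort_values("experiment")
    return frame.to_string(index=False) + "\n"
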