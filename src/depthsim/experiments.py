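"""Trial runner, model variants, metrics and comparison reports.

Three variants are compared, in uniform or nonuniform fovea conditions:

* ``infer_parallel`` — eyes fixed straight ahead, perception only;
* ``infer_vergence`` — eyes start verged on the target, action enabled;
* ``active_vision``  — eyes start at random angles, action enabled.

A fourth ``simultaneous`` variant runs estimation and fixation with all
pathways open at every step (no action/perception cycling); it exists to
demonstrate why the cycling is needed and is not part of the default grid.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import environment as env
from ._fast import run_fast_trial
from .agent import AgentConfig, DepthAgent, Phase, PhaseSchedule, schedule_phase
from .environment import FoveaMode, FoveaNoiseModel, WorldState
from .inference import DivergenceError


class Variant(enum.Enum):
    INFER_PARALLEL = "infer_parallel"
    INFER_VERGENCE = "infer_vergence"
    ACTIVE_VISION = "active_vision"
    SIMULTANEOUS = "simultaneous"


@dataclass(frozen=True)
class Condition:
    variant: Variant = Variant.ACTIVE_VISION
    resolution: FoveaMode = FoveaMode.NONUNIFORM
    n_trials: int = 100
    cycle_length: int = 100
    n_cycles: int = 150
    master_seed: int = 0
    threshold: float = 0.1
    k: float = 1.5
    sigma0: float = 0.05
    far_clip: float = 10.0
    depth_range: tuple = (2.0, 6.0)
    lateral_range: tuple = (-2.0, 2.0)
    angle_init_range: float = 0.3
    agent: AgentConfig = field(default_factory=AgentConfig)

    @property
    def n_steps(self) -> int:
        return 2 * self.cycle_length * self.n_cycles

    def trial_seed(self, trial_index: int) -> int:
        return self.master_seed + trial_index


@dataclass(frozen=True)
class TrialResult:
    success: bool
    final_error: float
    steps_to_criterion: Optional[int]  # None = criterion never reached


@dataclass(frozen=True)
class ConditionSummary:
    """Aggregate metrics of one condition.

    ``mean_time`` is right-censored: a trial that never reaches the success
    criterion contributes the full trial length, so conditions that fail
    often report honestly long estimation times instead of a mean over their
    few (easy) successes.  ``mean_time_reached`` is the uncensored mean over
    successful trials only.
    """

    variant: str
    resolution: str
    n_trials: int
    accuracy: float
    mean_error: float
    std_error: float
    mean_time: float
    std_time: float
    mean_time_reached: float  # NaN when no trial reached the criterion


def _steps_to_criterion(errors: np.ndarray, threshold: float) -> Optional[int]:
    """First step after which the error stays below threshold for good."""
    above = np.nonzero(errors >= threshold)[0]
    if len(above) == 0:
        return 0
    last_bad = int(above[-1])
    if last_bad == len(errors) - 1:
        return None
    return last_bad + 1


def run_trial(
    cond: Condition,
    trial_index: int,
    trace_path: Optional[Path] = None,
) -> TrialResult:
    """Run one full trial of the condition (deterministic per seed).

    The scalar fast path carries the default run; when a per-step trace is
    requested the array-based reference agent is used instead (the two are
    pinned step-for-step by the regression suite).
    """
    rng = np.random.default_rng(cond.trial_seed(trial_index))
    cfg = cond.agent
    target = np.array(
        [
            rng.uniform(*cond.depth_range),
            rng.uniform(*cond.lateral_range),
        ]
    )
    # depth belief always starts wrong: random depth, zero lateral offset
    init_pos = np.array([rng.uniform(*cond.depth_range), 0.0])

    if cond.variant is Variant.INFER_PARALLEL:
        angles = np.zeros(2)
        mode = "perception"
    elif cond.variant is Variant.INFER_VERGENCE:
        angles = env.fixation_angles(target, cfg.L)
        mode = "cycled"
    else:
        angles = rng.uniform(-cond.angle_init_range, cond.angle_init_range, size=2)
        mode = (
            "simultaneous" if cond.variant is Variant.SIMULTANEOUS else "cycled"
        )

    if trace_path is not None:
        return _run_trial_traced(cond, target, init_pos, angles, rng, trace_path)

    errors, _agent, diverged = run_fast_trial(
        cfg,
        target,
        init_pos,
        angles,
        cond.n_steps,
        cond.cycle_length,
        rng,
        cond.k,
        cond.resolution is FoveaMode.NONUNIFORM,
        sigma0=cond.sigma0,
        variant=mode,
        far_clip=cond.far_clip,
    )
    return _result_from_errors(errors, cond.threshold, diverged)


def _result_from_errors(
    errors: np.ndarray, threshold: float, diverged: bool
) -> TrialResult:
    final_error = np.inf if diverged else float(errors[-1])
    success = bool(np.isfinite(final_error) and final_error < threshold)
    steps = None if diverged else _steps_to_criterion(errors, threshold)
    return TrialResult(
        success=success, final_error=float(final_error), steps_to_criterion=steps
    )


def _run_trial_traced(
    cond: Condition,
    target: np.ndarray,
    init_pos: np.ndarray,
    angles: np.ndarray,
    rng: np.random.Generator,
    trace_path: Path,
) -> TrialResult:
    """Reference-path trial with a per-step CSV trace."""
    cfg = cond.agent
    world = WorldState(
        target=target,
        eye_angles_true=angles.copy(),
        L=cfg.L,
        cam=cfg.camera,
        far_clip=cond.far_clip,
    )
    noise = FoveaNoiseModel(
        k=cond.k, mode=cond.resolution, sigma0=cond.sigma0
    )
    agent = DepthAgent(cfg, init_pos, angles.copy())
    sched = PhaseSchedule(cycle_length=cond.cycle_length)
    errors = np.full(cond.n_steps, np.inf)
    rows = []
    diverged = False
    for t in range(cond.n_steps):
        if cond.variant is Variant.INFER_PARALLEL:
            phase = Phase.PERCEPTION
        elif cond.variant is Variant.SIMULTANEOUS:
            phase = Phase.SIMULTANEOUS
        else:
            phase = schedule_phase(t, sched)
        try:
            obs = env.observe(world, noise, rng)
            agent.step(obs.sp, list(obs.sv), phase, obs.sp_prime)
        except (DivergenceError, env.ObservationError):
            diverged = True
            break
        world = env.apply_action(world, agent.action, cfg.dt)
        err = float(np.linalg.norm(agent.estimate() - world.target))
        errors[t] = err if np.isfinite(err) else np.inf
        rows.append(
            (
                t,
                phase.value,
                agent.mu_a.mu[0],
                agent.mu_a.mu[1],
                agent.mu_theta.mu[0],
                agent.mu_theta.mu[1],
                agent.mu_c[0].mu[1],
                agent.mu_c[1].mu[1],
                agent.free_energy,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "step",
            "phase",
            "mu_a_x",
            "mu_a_y",
            "theta_a",
            "theta_v",
            "c0",
            "c1",
            "free_energy",
        ],
    ).to_csv(trace_path, index=False)
    return _result_from_errors(errors, cond.threshold, diverged)


def run_condition(cond: Condition, out_dir: Optional[Path] = None) -> ConditionSummary:
    """Aggregate ``n_trials`` seeded trials; optionally write CSV artifacts."""
    if cond.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rows = []
    for i in range(cond.n_trials):
        r = run_trial(cond, i)
        rows.append(
            {
                "trial": i,
                "seed": cond.trial_seed(i),
                "success": r.success,
                "final_error": r.final_error,
                "steps_to_criterion": -1
                if r.steps_to_criterion is None
                else r.steps_to_criterion,
            }
        )
    df = pd.DataFrame(rows)
    summary = summarize(cond, df)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{cond.variant.value}_{cond.resolution.value}"
        df.to_csv(out_dir / f"trials_{stem}.csv", index=False)
        pd.DataFrame([asdict(summary)]).to_csv(
            out_dir / f"summary_{stem}.csv", index=False
        )
    return summary


def summarize(cond: Condition, trials: pd.DataFrame) -> ConditionSummary:
    """Reduce a per-trial table to the reported metrics."""
    reached = trials[trials["steps_to_criterion"] >= 0]["steps_to_criterion"]
    censored = trials["steps_to_criterion"].where(
        trials["steps_to_criterion"] >= 0, cond.n_steps
    )
    return ConditionSummary(
        variant=cond.variant.value,
        resolution=cond.resolution.value,
        n_trials=len(trials),
        accuracy=float(trials["success"].mean()),
        mean_error=float(trials["final_error"].mean()),
        std_error=float(trials["final_error"].std(ddof=0)),
        mean_time=float(censored.mean()),
        std_time=float(censored.std(ddof=0)),
        mean_time_reached=float(reached.mean()) if len(reached) else float("nan"),
    )


def _compare(a: float, b: float) -> str:
    if np.isnan(a) or np.isnan(b):
        return "undefined"
    if a > b:
        return "greater"
    if a < b:
        return "less"
    return "tie"


def ordering_verdicts(summaries: List[ConditionSummary]) -> dict:
    """Machine-readable comparison of the qualitative Fig-style orderings.

    Each entry compares one metric between two variants within a resolution;
    the value is "greater"/"less"/"tie" for the first-named variant.
    """
    by_key = {(s.variant, s.resolution): s for s in summaries}
    verdicts = {}
    pairs = [
        ("nonuniform", "accuracy", "active_vision", "infer_parallel"),
        ("nonuniform", "accuracy", "infer_vergence", "infer_parallel"),
        ("nonuniform", "mean_time", "active_vision", "infer_vergence"),
        ("uniform", "accuracy", "infer_parallel", "active_vision"),
        ("uniform", "mean_time", "infer_parallel", "active_vision"),
    ]
    for res, metric, v1, v2 in pairs:
        s1, s2 = by_key.get((v1, res)), by_key.get((v2, res))
        if s1 is None or s2 is None:
            continue
        verdicts[f"{res}_{metric}_{v1}_vs_{v2}"] = _compare(
            getattr(s1, metric), getattr(s2, metric)
        )
    return verdicts


def compare_report(
    summaries: List[ConditionSummary], out_dir: Path, plot: bool = True
) -> dict:
    """Emit the summary table, bar-chart figure and ordering verdicts."""
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([asdict(s) for s in summaries])
    table.to_csv(out_dir / "comparison.csv", index=False)
    verdicts = ordering_verdicts(summaries)
    with open(out_dir / "verdicts.json", "w") as fh:
        json.dump(verdicts, fh, indent=2, sort_keys=True)
    if plot:
        _plot_panels(table, out_dir / "comparison.png")
    return verdicts


def _plot_panels(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [("accuracy", "Accuracy"), ("mean_error", "Mean error"), ("mean_time", "Time (steps)")]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    variants = list(dict.fromkeys(table["variant"]))
    resolutions = list(dict.fromkeys(table["resolution"]))
    width = 0.8 / max(len(resolutions), 1)
    for ax, (metric, label) in zip(axes, metrics):
        for j, res in enumerate(resolutions):
            sub = table[table["resolution"] == res].set_index("variant")
            vals = [sub[metric].get(v, np.nan) for v in variants]
            vals = [v if np.isfinite(v) else np.nan for v in vals]
            ax.bar(np.arange(len(variants)) + j * width, vals, width, label=res)
        ax.set_xticks(np.arange(len(variants)) + width * (len(resolutions) - 1) / 2)
        ax.set_xticklabels(variants, rotation=20, ha="right", fontsize=8)
        ax.set_title(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
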