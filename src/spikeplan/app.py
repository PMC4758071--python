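"""Experiment recipes, configuration and command-line interface.

Four desk-scale experiment recipes are provided, each reproducible
bit-for-bit from (config, seed):

* ``track-finite``   -- online reward-modulated learning of the 9-state
  linear-track passage task, followed by a 100-trial evaluation.
* ``maze-infinite``  -- offline eligibility-trace learning of the
  15 x 20 grid maze, followed by sampling 12 fresh trajectories.
* ``sweep``          -- the hippocampal-sweep simulation (no learning).
* ``robot-surrogate``-- contrastive-divergence learning of a transition
  model from synthetic demonstrations, then goal-directed planning
  with obstacle inhibition in a 70 x 70 cm workspace.

Configuration is a YAML mapping with the documented keys below;
unknown keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import network, plasticity, population, sweep, tasks, transition_cd
from .evaluation import success_rate

logger = logging.getLogger(__name__)

EXPERIMENTS = ("track-finite", "maze-infinite", "sweep", "robot-surrogate")

#: iterations the recipes default to (the published training budgets)
DEFAULT_ITERATIONS = {
    "track-finite": 5000,
    "maze-infinite": 10000,
    "sweep": 1,
    "robot-surrogate": 60,
}

_TOP_KEYS = {"experiment", "seed", "out_dir", "iterations", "task", "learning"}
_TASK_KEYS = {
    "track-finite": {"K", "T", "passage_mid", "passage_end", "start_state", "eps"},
    "maze-infinite": {
        "rows", "cols", "obstacles", "start", "target", "T_max", "gamma", "r_goal",
    },
    "sweep": {
        "rows", "cols", "init_window", "poisson_rate", "sigma_trans",
        "weight_scale", "weight_slope", "n_active", "start", "home", "horizon",
    },
    "robot-surrogate": {"n_traj", "step_scale", "path_len", "obstacle_boxes", "horizon"},
}
_LEARN_KEYS = {"eta", "L", "mode", "gamma", "trace_decay"}


class ConfigError(ValueError):
    """Raised for malformed, out-of-range or inconsistent configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one experiment run."""

    experiment: str = "track-finite"
    seed: int = 0
    out_dir: str = "runs"
    iterations: int | None = None
    task: dict = dc_field(default_factory=dict)
    learning: dict = dc_field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return (
            self.iterations
            if self.iterations is not None
            else DEFAULT_ITERATIONS[self.experiment]
        )

    def canonical(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "iterations": self.n_iterations,
            "task": self.task,
            "learning": self.learning,
        }

    def config_hash(self) -> str:
        # out_dir is where artifacts land, not part of what they contain
        payload = {k: v for k, v in self.canonical().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return (
            f"spikeplan experiment={self.experiment} seed={self.seed} "
            f"config_hash={self.config_hash()}"
        )


def validate_config(raw: str) -> RunConfig:
    """Parse and schema-check a YAML config; empty input means all
    defaults.  Every rejection names the offending field."""
    data = yaml.safe_load(raw) if raw.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    experiment = data.get("experiment", "track-finite")
    if experiment not in EXPERIMENTS:
        raise ConfigError(
            f"experiment must be one of {EXPERIMENTS}, got {experiment!r}"
        )
    seed = data.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        raise ConfigError(f"seed must be a non-negative integer, got {seed!r}")
    iterations = data.get("iterations")
    if iterations is not None and (not isinstance(iterations, int) or iterations < 1):
        raise ConfigError(f"iterations must be a positive integer, got {iterations!r}")
    task = data.get("task", {}) or {}
    if not isinstance(task, dict):
        raise ConfigError("task must be a mapping")
    unknown = set(task) - _TASK_KEYS[experiment]
    if unknown:
        raise ConfigError(
            f"unknown task keys for {experiment}: {sorted(unknown)}"
        )
    learning = data.get("learning", {}) or {}
    if not isinstance(learning, dict):
        raise ConfigError("learning must be a mapping")
    unknown = set(learning) - _LEARN_KEYS
    if unknown:
        raise ConfigError(f"unknown learning keys: {sorted(unknown)}")

    cfg = RunConfig(
        experiment=experiment,
        seed=seed,
        out_dir=str(data.get("out_dir", "runs")),
        iterations=iterations,
        task=task,
        learning=learning,
    )
    # construct the domain objects now so range and consistency errors
    # (gamma outside (0,1), sealed-off targets, ...) surface at load time
    try:
        _build_task(cfg)
        _learn_config(cfg)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    logger.info("config validated: %s", cfg.canonical())
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    return validate_config(Path(path).read_text() if path else "")


def _build_task(cfg: RunConfig):
    t = dict(cfg.task)
    if cfg.experiment == "track-finite":
        return tasks.LinearTrackTask(**t)
    if cfg.experiment == "maze-infinite":
        if "obstacles" in t:
            t["obstacles"] = frozenset(map(tuple, t["obstacles"]))
        for key in ("start", "target"):
            if key in t:
                t[key] = tuple(t[key])
        return tasks.GridMazeTask(**t)
    if cfg.experiment == "sweep":
        t.pop("horizon", None)
        for key in ("start", "home"):
            if key in t:
                t[key] = tuple(t[key])
        return sweep.SweepConfig(**t)
    return dict(t)  # robot-surrogate: plain parameter dict


def _learn_config(cfg: RunConfig) -> plasticity.LearnConfig:
    defaults = {"track-finite": {"eta": 0.2, "L": 1, "mode": "online"}}.get(
        cfg.experiment, {"eta": 1.0, "L": 10, "mode": "offline", "gamma": 0.98}
    )
    return plasticity.LearnConfig(**{**defaults, **cfg.learning})


def _write_csv(path: Path, df, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {cfg.provenance()}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

def run_experiment(cfg: RunConfig) -> dict:
    """Execute one named recipe end to end; returns the summary dict
    that is also written to ``<out_dir>/summary.json``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    runner = {
        "track-finite": _run_track,
        "maze-infinite": _run_maze,
        "sweep": _run_sweep,
        "robot-surrogate": _run_robot,
    }[cfg.experiment]
    summary = runner(cfg, out, rng)
    summary = {"provenance": cfg.provenance(), "config": cfg.canonical(), **summary}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    logger.info("experiment %s finished: %s", cfg.experiment, summary)
    return summary


def _run_track(cfg: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    task = _build_task(cfg)
    lcfg = _learn_config(cfg)
    params = tasks.track_params(task)
    schedule = tasks.track_context_schedule(task)
    v0 = network.one_hot(task.start_state, task.K)

    params, curve = plasticity.train_episodic(
        params,
        lambda r: v0,
        schedule,
        task.T,
        lambda train: tasks.track_reward(train, task),
        lcfg,
        cfg.n_iterations,
        rng,
    )
    curve.seed = cfg.seed
    _write_csv(out / "learning_curve.csv", curve.to_frame(), cfg)

    def trial(r: np.random.Generator) -> float:
        train = network.sample_trajectory(params, v0, schedule, task.T, r)
        return tasks.track_reward(train, task)

    sr = success_rate(trial, 100, rng)
    sample = network.sample_trajectory(params, v0, schedule, task.T, rng)
    network.write_spike_train(
        out / "spike_train.csv", sample, activation=params.activation, seed=cfg.seed
    )
    return {
        "success_rate": sr.rate,
        "wilson_interval": [sr.low, sr.high],
        "n_eval_trials": sr.n,
    }


def _run_maze(cfg: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    task = _build_task(cfg)
    lcfg = _learn_config(cfg)
    params = tasks.maze_params(task)
    params, curve = plasticity.train_maze(params, task, lcfg, cfg.n_iterations, rng)
    curve.seed = cfg.seed
    _write_csv(out / "learning_curve.csv", curve.to_frame(), cfg)

    code = population.grid_code(
        task.rows, task.cols, ((0.0, float(task.cols)), (0.0, float(task.rows)))
    )
    n_reached = 0
    import pandas as pd

    rows = []
    for i in range(12):
        path, reached = tasks.sample_maze_episode(params, task, rng)
        n_reached += reached
        for t, s in enumerate(path):
            r, c = task.index_cell(s)
            rows.append((i, t, c + 0.5, r + 0.5, reached))
    _write_csv(
        out / "trajectories.csv",
        pd.DataFrame(rows, columns=["traj_id", "t", "x", "y", "reached"]),
        cfg,
    )
    np.savetxt(out / "theta_field.csv", params.Theta[:, 0].reshape(task.rows, task.cols),
               delimiter=",")
    return {"n_sampled": 12, "n_reached_target": int(n_reached)}


def _run_sweep(cfg: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    horizon = int(cfg.task.get("horizon", 40))
    scfg = _build_task(cfg)
    train, path = sweep.simulate_sweep(scfg, horizon, rng)
    network.write_spike_train(
        out / "spike_train.csv", train, activation="sigmoid", seed=cfg.seed
    )
    population.write_path_csv(out / "decoded_path.csv", path, header=cfg.provenance())
    sweep.write_activity_map(out / "activity_map.csv", sweep.activity_map(train, scfg))
    final_dist = float(np.linalg.norm(path[-1] - np.asarray(scfg.home)))
    return {
        "horizon": horizon,
        "final_distance_to_home_m": final_dist,
        "initial_distance_m": float(
            np.linalg.norm(np.asarray(scfg.start) - np.asarray(scfg.home))
        ),
    }


def _run_robot(cfg: RunConfig, out: Path, rng: np.random.Generator) -> dict:
    t = _build_task(cfg)
    code = transition_cd.robot_place_code()
    demos = transition_cd.generate_demonstrations(
        code,
        n_traj=int(t.get("n_traj", 20)),
        step_scale=float(t.get("step_scale", 0.05)),
        rng=rng,
        path_len=int(t.get("path_len", 50)),
    )
    transition_cd.write_demos(out / "demonstrations.csv", demos)
    W = transition_cd.cd_learn(demos, eta=0.5, epochs=cfg.n_iterations, rng=rng)

    start = np.array([0.1, 0.1])
    target = np.array([0.6, 0.6])
    boxes = t.get("obstacle_boxes", [(0.25, 0.25, 0.45, 0.45)])
    bias = sweep.distance_weights(code, target, 1.0, 5.0)
    bias = bias + transition_cd.obstacle_bias(code, boxes)
    params = network.NetworkParams(
        W=W,
        Theta=bias[:, None],
        theta0=np.zeros(code.K),
        activation=network.Activation.SOFTMAX_WTA,
    )
    horizon = int(t.get("horizon", 65))  # 1.3 s at 20 ms/step
    v0 = network.one_hot(code.nearest_cell(start), code.K)
    always_on = np.ones(1, dtype=np.int8)
    train = network.sample_trajectory(params, v0, lambda _: always_on, horizon, rng)
    path = population.decode_trajectory(train, code, initial=start)
    population.write_path_csv(out / "plan_path.csv", path, header=cfg.provenance())
    network.write_spike_train(
        out / "spike_train.csv", train, activation=params.activation, seed=cfg.seed
    )
    return {
        "n_demo_pairs": len(demos),
        "final_distance_to_target_m": float(np.linalg.norm(path[-1] - target)),
    }


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def build_cli():
    """Construct the click command group (one subcommand per recipe)."""
    import click

    @click.group(name="spikeplan")
    def cli() -> None:
        """Recurrent spiking-network planner: experiment runner."""

    def make_command(name: str):
        @click.command(name=name)
        @click.option("--config", "config_path", type=click.Path(exists=True),
                      default=None, help="YAML config file.")
        @click.option("--seed", type=int, default=None, help="Override the seed.")
        @click.option("--out", "out_dir", type=click.Path(), default=None,
                      help="Output directory.")
        @click.option("--iterations", type=int, default=None,
                      help="Override the training budget.")
        @click.option("--quiet", is_flag=True, help="Log warnings only.")
        def cmd(config_path, seed, out_dir, iterations, quiet):
            logging.basicConfig(
                level=logging.WARNING if quiet else logging.INFO,
                format="%(levelname)s %(name)s: %(message)s",
            )
            try:
                cfg = load_config(config_path)
            except ConfigError as exc:
                raise click.ClickException(f"invalid config: {exc}")
            overrides = {"experiment": name}
            if seed is not None:
                overrides["seed"] = seed
            if out_dir is not None:
                overrides["out_dir"] = out_dir
            if iterations is not None:
                overrides["iterations"] = iterations
            from dataclasses import replace

            cfg = replace(cfg, **overrides)
            try:
                _build_task(cfg)
            except (ValueError, TypeError) as exc:
                raise click.ClickException(f"invalid config: {exc}")
            summary = run_experiment(cfg)
            click.echo(json.dumps(summary, indent=1, default=float))

        return cmd

    for name in EXPERIMENTS:
        cli.add_command(make_command(name))
    return cli


def main(argv: list[str] | None = None) -> int:
    return build_cli().main(args=argv, standalone_mode=True)


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
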