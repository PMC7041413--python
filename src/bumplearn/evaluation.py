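"""Error estimation, learning-curve metrics, and experiment drivers.

The *error* of a learned network is the expected feedback E[L(x, y)] under
uniform random inputs x, with y drawn from the attractor activation of the
frozen network.  It is estimated by Monte Carlo with fresh activations;
estimation never mutates the synaptic state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .network import SynapseState, activate
from .population import PopulationGrid, encode_value, make_bump
from .tasks import TaskSpec

__all__ = [
    "LearningRun",
    "estimate_error",
    "samples_to_error",
    "samples_to_threshold",
    "run_experiment",
]


@dataclass
class LearningRun:
    """One training run: config snapshot, seed, learning curve, outcome."""

    config: dict
    seed: Optional[int]
    curve: List[Tuple[int, float]]
    converged: bool
    final_metric: float

    def curve_array(self) -> np.ndarray:
        return np.asarray(self.curve, dtype=float)

    def to_csv(self, path, columns=("sample", "estimated_error")) -> None:
        import pandas as pd

        pd.DataFrame(self.curve, columns=list(columns)).to_csv(path, index=False)


WidthFn = Callable[[int], Tuple[int, int]]


def _estimate_error_1d(
    state: SynapseState,
    task: TaskSpec,
    m: int,
    rng: np.random.Generator,
    width_fn: WidthFn,
) -> Tuple[float, float]:
    """Batched Monte-Carlo error for 1-D bounded input/output populations."""
    n_in, n_out = state.grid_in.n, state.grid_out.n
    x_all = rng.random(m)
    centers = np.clip(np.floor(x_all * n_in + 0.5).astype(int), 1, n_in)
    # width_fn takes the flat (0-based) row of the center neuron
    kab = np.array([width_fn(int(c) - 1) for c in centers])
    kA, kB = kab[:, 0], kab[:, 1]
    errs = np.empty(m)
    a = np.arange(1, n_out + 1)
    # When p only takes the values {0, p_init, 1} (pruning/consolidation
    # states), each output neuron's synaptic input is
    # n_consolidated + Binomial(n_live, p_init); draw it directly from
    # per-column prefix counts instead of per-synapse Bernoulli variables.
    p = state.p
    three_valued = bool(
        np.all((p == 0.0) | (p == 1.0) | (p == state.p_init))
    )
    if three_valued:
        one_cs = np.concatenate(
            [np.zeros((1, n_out), dtype=np.int32),
             np.cumsum(p == 1.0, axis=0, dtype=np.int32)], axis=0
        )
        init_cs = np.concatenate(
            [np.zeros((1, n_out), dtype=np.int32),
             np.cumsum((p > 0.0) & (p < 1.0), axis=0, dtype=np.int32)], axis=0
        )
    done = 0
    while done < m:
        kmax = int(kA[done:].max()) + 1
        per_sample = n_out if three_valued else kmax * n_out
        chunk = max(1, int(4_000_000 // max(1, per_sample)))
        sl = slice(done, min(m, done + chunk))
        b = sl.stop - sl.start
        c_b = centers[sl]
        rlo = np.maximum(1, np.ceil(c_b - kA[sl] / 2).astype(int)) - 1
        rhi = np.minimum(n_in, np.floor(c_b + kA[sl] / 2).astype(int))
        if three_valued:
            counts = (one_cs[rhi] - one_cs[rlo]) + rng.binomial(
                init_cs[rhi] - init_cs[rlo], state.p_init
            )
        else:
            width = rhi - rlo
            wmax = int(width.max())
            rows = rlo[:, None] + np.arange(wmax)[None, :]
            valid = np.arange(wmax)[None, :] < width[:, None]
            probs = state.p[np.where(valid, rows, 0)] * valid[:, :, None]
            X = rng.random(probs.shape) < probs
            counts = X.sum(axis=1)
        cs = np.concatenate(
            [np.zeros((b, 1), dtype=np.int64), np.cumsum(counts, axis=1)], axis=1
        )
        kb = kB[sl][:, None]
        wlo = np.maximum(1, np.ceil(a[None, :] - kb / 2).astype(int))
        whi = np.minimum(n_out, np.floor(a[None, :] + kb / 2).astype(int))
        scores = np.take_along_axis(cs, whi, axis=1) - np.take_along_axis(
            cs, wlo - 1, axis=1
        )
        keys = scores + rng.random(scores.shape)
        win = np.argmax(keys, axis=1) + 1
        y = win / n_out
        if task.f is not None and task.d_B == 1:
            errs[sl] = np.abs(np.asarray(task.f(x_all[sl])).reshape(-1) - y)
        else:
            errs[sl] = [task.feedback(x_all[sl][s], y[s]) for s in range(b)]
        done = sl.stop
    return float(errs.mean()), float(errs.std(ddof=1) / math.sqrt(m)) if m > 1 else 0.0


def estimate_error(
    state: SynapseState,
    task: TaskSpec,
    m: int,
    rng: np.random.Generator,
    width_fn: WidthFn,
) -> Tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of E[L(x, y)].

    ``width_fn`` maps the flat position of a sampled input center to the
    bump widths (k_A, k_B) to evaluate with, so evaluation uses the same
    width rule as training.  The synaptic state is not modified.
    """
    if m < 1:
        raise ValueError("need at least one evaluation sample")
    if (
        state.grid_in.d == 1
        and state.grid_out.d == 1
        and state.grid_in.topology == "bounded"
        and state.grid_out.topology == "bounded"
    ):
        return _estimate_error_1d(state, task, m, rng, width_fn)
    errs = np.empty(m)
    for s in range(m):
        x = rng.random(state.grid_in.d)
        center = encode_value(x, state.grid_in)
        k_A, k_B = width_fn(state.grid_in.ravel(center))
        I = make_bump(center, k_A, state.grid_in)
        sample = activate(I, k_B, state, rng)
        errs[s] = task.feedback(x, sample.y)
    return float(errs.mean()), float(errs.std(ddof=1) / math.sqrt(m)) if m > 1 else 0.0


def samples_to_error(curve: Sequence[Tuple[int, float]], threshold: float):
    """Smallest sample count at which the recorded error reaches ``threshold``.

    Linear interpolation between recorded points; returns None if the curve
    never reaches the threshold (undefined metric).
    """
    pts = list(curve)
    if not pts:
        return None
    if pts[0][1] <= threshold:
        return float(pts[0][0])
    for (s0, e0), (s1, e1) in zip(pts, pts[1:]):
        if e1 <= threshold:
            if e0 == e1:
                return float(s1)
            frac = (e0 - threshold) / (e0 - e1)
            return float(s0 + frac * (s1 - s0))
    return None


def samples_to_threshold(curve: Sequence[Tuple[int, float]], factor: float = 1.5):
    """Samples needed to reach ``factor`` times the final recorded error.

    The relative target skips the slow tail before final convergence when
    comparing sample efficiency across bump widths.
    """
    pts = list(curve)
    if not pts:
        return None
    target = factor * pts[-1][1]
    out = samples_to_error(pts, target)
    return float(pts[-1][0]) if out is None else out


# -- experiment driver --------------------------------------------------------

_REQUIRED_KEYS = {"algorithm", "seed", "replicates"}


def _validate_config(cfg: dict) -> None:
    missing = _REQUIRED_KEYS - set(cfg)
    bad = []
    if missing:
        bad.extend(sorted(missing))
    algo = cfg.get("algorithm")
    if algo in {"static", "dynamic", "theory-static", "theory-dynamic"}:
        if "task" not in cfg:
            bad.append("task")
    elif algo == "rl":
        if "env" not in cfg:
            bad.append("env")
    elif algo is not None:
        bad.append("algorithm")
    if bad:
        raise ValueError(f"invalid config; offending keys: {bad}")


def _one_replicate(cfg: dict, seed: int) -> LearningRun:
    from . import adaptive, rl, tasks, theory

    algo = cfg["algorithm"]
    rng = np.random.default_rng(seed)
    if algo == "rl":
        env = {"mountain_car": tasks.mountain_car_env, "cartpole": tasks.cartpole_env}[
            cfg["env"]
        ]()
        rcfg = rl.RLConfig(**cfg.get("hyperparameters", {}))
        _, _, run = rl.rl_train(env, rcfg, rng)
        run.seed = seed
        return run
    task = dict(tasks.mapping_tasks(), throw_ball=tasks.throw_ball_task(),
                robotic_arm=tasks.robotic_arm_task())[cfg["task"]]
    gi = PopulationGrid(task.d_A, cfg.get("n_in", 100), cfg.get("topology", "bounded"))
    go = PopulationGrid(task.d_B, cfg.get("n_out", cfg.get("n_in", 100)),
                        cfg.get("topology", "bounded"))
    hp = dict(cfg.get("hyperparameters", {}))
    if algo in ("static", "dynamic"):
        acfg = adaptive.AdaptiveConfig(**hp)
        state, run = adaptive.adaptive_train(
            task, gi, go, acfg, variant=algo, rng=rng,
            eval_samples=cfg.get("eval_samples", 1000),
        )
        run.seed = seed
        run.config["state"] = state
        return run
    if algo == "theory-static":
        k = hp.get("k", 10)
        state = theory.static_theory_train(task, gi, go, k_A=k, rng=rng)
        wf = lambda row: (k, max(1, math.ceil(task.C * k)))
        err, _ = estimate_error(state, task, cfg.get("eval_samples", 1000), rng, wf)
        run = LearningRun(
            config={"task": task.name, "algorithm": algo, "k": k, "n": gi.n},
            seed=seed,
            curve=[(theory.theory_sample_count(gi.n, k, task.d_A, task.d_B, task.C), err)],
            converged=True,
            final_metric=err,
        )
        run.config["state"] = state
        return run
    # theory-dynamic
    tcfg = theory.TheoryConfig(
        C=task.C,
        ell=hp.get("ell", 0.05),
        c_k=hp.get("c_k"),
        sample_budget_scale=hp.get("sample_budget_scale", 1.0),
    )
    m_eval = cfg.get("eval_samples", 1000)
    err_fn = lambda st, kA, kB: estimate_error(
        st, task, m_eval, rng, lambda row: (kA, kB)
    )[0]
    state, log = theory.dynamic_theory_train(task, gi, go, tcfg, rng, error_fn=err_fn)
    curve = [(rec["cumulative_samples"], rec["error"]) for rec in log]
    run = LearningRun(
        config={"task": task.name, "algorithm": algo, "n": gi.n, "ell": tcfg.ell},
        seed=seed,
        curve=curve,
        converged=True,
        final_metric=curve[-1][1],
    )
    run.config["state"] = state
    run.config["phase_log"] = log
    return run


def run_experiment(config, out_dir) -> List[LearningRun]:
    """Execute replicated runs from a declarative config; write artifacts.

    ``config`` is a dict or a path to a JSON/YAML file with keys: algorithm
    (static | dynamic | theory-static | theory-dynamic | rl), task or env,
    n_in / n_out, hyperparameters, seed, replicates.  Writes per-replicate
    curve CSVs, an aggregate mean/sd CSV, final synapse snapshots and a JSON
    manifest.  Deterministic given the seed.
    """
    import pandas as pd

    if not isinstance(config, dict):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs = []
    xcol = "episode" if config["algorithm"] == "rl" else "sample"
    ycol = "total_reward" if config["algorithm"] == "rl" else "estimated_error"
    for rep in range(int(config["replicates"])):
        seed = int(config["seed"]) + rep
        run = _one_replicate(config, seed)
        run.to_csv(out / f"curve_rep{rep}.csv", columns=(xcol, ycol))
        state = run.config.pop("state", None)
        if state is not None and rep == 0:
            state.to_csv(out / "synapses_rep0.csv")
        run.config.pop("phase_log", None)
        runs.append(run)
    # aggregate on the union of recorded x-values
    grid = np.unique(np.concatenate([r.curve_array()[:, 0] for r in runs]))
    mat = np.vstack(
        [
            np.interp(grid, r.curve_array()[:, 0], r.curve_array()[:, 1])
            for r in runs
        ]
    )
    pd.DataFrame(
        {xcol: grid, "mean": mat.mean(axis=0),
         "sd": mat.std(axis=0, ddof=1) if len(runs) > 1 else np.zeros(len(grid))}
    ).to_csv(out / "aggregate.csv", index=False)
    manifest = {
        "config": {k: v for k, v in config.items()},
        "seeds": [int(config["seed"]) + r for r in range(int(config["replicates"]))],
        "version": __import__("bumplearn").__version__,
        "final_metrics": [r.final_metric for r in runs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return runs
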