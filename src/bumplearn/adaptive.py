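"""Adaptive bump learning: the simulation algorithm.

Compared to the counter-based variants, this algorithm handles feedback
functions whose magnitude varies across inputs, and it adapts continuously
instead of in discrete phases.  Five mechanisms act on every sample
(input bump I with center x, activated output bump J with center y,
feedback L = L(x, y)):

1. every input neuron i carries a running error threshold L_hat_i, the
   exponential moving average (decay alpha) of the feedbacks seen while i
   was active;
2. if L >= L_hat_i, the synapses from i into J are pruned immediately
   (the comparison uses the threshold *before* the current update);
3. inactivity counters d_ij grow while i fires without j (i in I, j not in
   J) and reset when the pair co-fires; synapses with d_ij >= theta_prune
   are pruned;
4. in the *dynamic* variant the bump widths follow the learning progress:
   k is a constant fraction of the surviving synapse count of the center
   neuron (per output axis), so well-learned inputs use narrow bumps;
   the *static* variant keeps k fixed;
5. once an input neuron's surviving synapse count drops below theta_syn its
   probabilities are set to 1 and the neuron is frozen (consolidation).

Learning stops when the mean of the running thresholds falls below the
target precision ell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np

from .network import SynapseState, activate, consolidate
from .population import PopulationGrid, encode_value, make_bump
from .tasks import TaskSpec

__all__ = [
    "AdaptiveConfig",
    "update_error_threshold",
    "adaptive_width",
    "adaptive_step",
    "adaptive_train",
    "width_policy",
]


@dataclass
class AdaptiveConfig:
    """Hyperparameters of the adaptive algorithm.

    Defaults were fixed once by a coarse grid search on the 1-D mapping
    tasks and are exposed for per-task tuning.  ``L_hat_init`` defaults to
    the task's feedback bound: thresholds start at the worst possible
    feedback (no pruning on a neuron's first sample) and decay toward its
    running error.  ``theta_prune`` must be large enough that a neuron's
    threshold becomes informative (roughly ln(L_init/L_typ)/alpha
    activations) before inactivity pruning collapses its synapses onto the
    few most recently co-active bands.
    """

    alpha: float = 0.1
    c_A: float = 0.15
    c_B: Optional[float] = None  # defaults to C * c_A
    theta_prune: int = 30
    theta_syn: int = 10
    L_hat_init: Optional[float] = None
    ell: float = 0.01
    k_static: Optional[int] = None
    max_samples: int = 200_000
    p_init: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0,1], got {self.alpha}")
        if self.theta_prune < 1 or self.theta_syn < 1:
            raise ValueError("theta_prune and theta_syn must be positive")

    def resolved_c_B(self, C: float) -> float:
        return self.c_B if self.c_B is not None else C * self.c_A

    def resolved_L_hat_init(self, task: TaskSpec) -> float:
        if self.L_hat_init is not None:
            return self.L_hat_init
        return task.feedback_bound


def update_error_threshold(L_hat_i: float, L: float, alpha: float) -> float:
    """Exponential moving average: L_hat <- alpha L + (1 - alpha) L_hat."""
    return alpha * L + (1.0 - alpha) * L_hat_i


def adaptive_width(live_count: int, c: float, d_out: int = 1) -> int:
    """Bump width as a fraction of the surviving synapse count.

    The count spreads over a d_out-dimensional output grid, so the per-axis
    width uses its d_out-th root; d_out = 1 gives k = floor(c * count).
    Floored at 1 so degenerate neurons still form a bump.
    """
    if live_count <= 0:
        return 1
    return max(1, int(c * live_count ** (1.0 / d_out)))


def width_policy(
    state: SynapseState, config: AdaptiveConfig, task: TaskSpec, variant: str
) -> Callable[[int], Tuple[int, int]]:
    """Per-input-row bump widths (k_A, k_B) under a variant's rule."""
    n_out = state.grid_out.n
    if variant == "static":
        if config.k_static is None:
            raise ValueError("static variant requires k_static")
        kA = min(config.k_static, state.grid_in.n - 1)
        kB = min(max(1, round(task.C * kA)), n_out - 1)
        return lambda row: (kA, kB)
    c_B = config.resolved_c_B(task.C)
    d_out = state.grid_out.d

    def widths(row: int) -> Tuple[int, int]:
        count = int((state.p[row] > 0).sum())
        kA = min(adaptive_width(count, config.c_A, d_out), state.grid_in.n - 1)
        kB = min(adaptive_width(count, c_B, d_out), n_out - 1)
        return kA, kB

    return widths


def _fast_sample_1d(
    state: SynapseState, center: int, k_A: int, k_B: int, rng: np.random.Generator
):
    """Attractor activation for 1-D bounded grids without per-synapse draws.

    Probabilities only take the values {0, p_init, 1} here, so the synaptic
    input of each output neuron is n_consolidated + Binomial(n_live, p_init),
    distributed identically to summing per-synapse Bernoulli draws.
    Returns (input rows, output cols, winning center, decoded y).
    """
    n_in, n_out = state.grid_in.n, state.grid_out.n
    rlo = max(1, math.ceil(center - k_A / 2)) - 1
    rhi = min(n_in, math.floor(center + k_A / 2))
    sub = state.p[rlo:rhi]
    n_one = (sub == 1.0).sum(axis=0)
    n_live = (sub > 0.0).sum(axis=0) - n_one
    counts = n_one + rng.binomial(n_live, state.p_init)
    cs = np.concatenate([[0], np.cumsum(counts)])
    a = np.arange(1, n_out + 1)
    wlo = np.maximum(1, np.ceil(a - k_B / 2).astype(int))
    whi = np.minimum(n_out, np.floor(a + k_B / 2).astype(int))
    keys = (cs[whi] - cs[wlo - 1]) + rng.random(n_out)
    win = int(np.argmax(keys)) + 1
    rows = np.arange(rlo, rhi)
    cols = np.arange(wlo[win - 1] - 1, whi[win - 1])
    return rows, cols, win, np.array([win / n_out])


@dataclass
class StepRecord:
    x: np.ndarray
    y: np.ndarray
    L: float
    k_A: int
    k_B: int
    pruned_rows: int
    consolidated_rows: int
    reseeded_rows: int


def _reseed_row(state: SynapseState, row: int, width: int, center_col: int) -> None:
    """Re-seed a degenerate row with p_init on a band around ``center_col``."""
    n_out = state.grid_out.size
    lo = max(0, center_col - width // 2)
    hi = min(n_out, lo + width)
    state.p[row, lo:hi] = state.p_init
    state.d_inact[row, lo:hi] = 0


def adaptive_step(
    state: SynapseState,
    task: TaskSpec,
    config: AdaptiveConfig,
    variant: str,
    rng: np.random.Generator,
    widths: Optional[Callable[[int], Tuple[int, int]]] = None,
    last_out: Optional[np.ndarray] = None,
) -> StepRecord:
    """One sample of the adaptive algorithm; mutates ``state`` in place.

    ``last_out`` (per-row flat output positions) tracks each row's most
    recent co-active output center, used to place re-seed bands for rows
    that lose every synapse before consolidation.
    """
    grid_in, grid_out = state.grid_in, state.grid_out
    if widths is None:
        widths = width_policy(state, config, task, variant)
    x = rng.random(grid_in.d)
    center = encode_value(x, grid_in)
    row0 = grid_in.ravel(center)
    k_A, k_B = widths(row0)
    fast = (
        grid_in.d == 1
        and grid_out.d == 1
        and grid_in.topology == "bounded"
        and grid_out.topology == "bounded"
    )
    if fast:
        rows, cols, win, y = _fast_sample_1d(state, int(center[0]), k_A, k_B, rng)
        out_center_flat = win - 1
    else:
        I = make_bump(center, k_A, grid_in)
        sample = activate(I, k_B, state, rng)
        rows = I.flat_indices()
        cols = sample.output_bump.flat_indices()
        out_center_flat = grid_out.ravel(sample.output_bump.center)
        y = sample.y
    L = float(task.feedback(x, y))
    nc = rows[~state.consolidated[rows]]  # rows still plastic

    # (2) immediate error pruning against the pre-update thresholds
    bad = nc[L >= state.L_hat[nc]]
    if bad.size:
        state.p[np.ix_(bad, cols)] = 0.0
    # (3) running-threshold update for every active input neuron
    state.L_hat[rows] = config.alpha * L + (1.0 - config.alpha) * state.L_hat[rows]
    # (4) inactivity bookkeeping and pruning
    if nc.size:
        sub_p = state.p[nc]
        live = sub_p > 0.0
        dsub = state.d_inact[nc]
        dsub[live] += 1
        dsub[:, cols] = 0
        stale = live & (dsub >= config.theta_prune)
        if stale.any():
            sub_p[stale] = 0.0
            state.p[nc] = sub_p
        state.d_inact[nc] = dsub
    # (5) consolidation / degenerate re-seed
    n_cons = n_reseed = 0
    if last_out is not None:
        last_out[nc] = out_center_flat
    for r in nc:
        count = int((state.p[r] > 0).sum())
        if count == 0:
            seed_center = int(last_out[r]) if last_out is not None else state.grid_out.size // 2
            _reseed_row(state, int(r), config.theta_syn, seed_center)
            n_reseed += 1
        elif count < config.theta_syn:
            consolidate(state, int(r))
            n_cons += 1
    return StepRecord(
        x=x, y=y, L=L, k_A=k_A, k_B=k_B,
        pruned_rows=int(bad.size), consolidated_rows=n_cons, reseeded_rows=n_reseed,
    )


def adaptive_train(
    task: TaskSpec,
    grid_in: PopulationGrid,
    grid_out: PopulationGrid,
    config: AdaptiveConfig,
    variant: str = "dynamic",
    rng: Optional[np.random.Generator] = None,
    eval_samples: int = 1000,
    eval_points: int = 30,
    record_curve: bool = True,
):
    """Run the adaptive algorithm until mean L_hat < ell or max_samples.

    Returns ``(state, run)`` where ``run`` is an
    :class:`~bumplearn.evaluation.LearningRun` whose curve holds
    (sample_count, estimated_error) pairs at log-spaced checkpoints.
    """
    from .evaluation import LearningRun, estimate_error

    rng = rng if rng is not None else np.random.default_rng()
    L0 = config.resolved_L_hat_init(task)
    state = SynapseState.create(grid_in, grid_out, p_init=config.p_init, L_hat_init=L0)
    last_out = np.full(grid_in.size, grid_out.size // 2, dtype=np.int64)
    checkpoints = set()
    if record_curve:
        pts = np.unique(
            np.round(np.geomspace(10, config.max_samples, eval_points)).astype(int)
        )
        checkpoints = set(int(v) for v in pts)
    curve: List[Tuple[int, float]] = []
    converged = False
    t = 0
    widths = width_policy(state, config, task, variant)
    while t < config.max_samples:
        t += 1
        adaptive_step(state, task, config, variant, rng, widths=widths, last_out=last_out)
        if t in checkpoints:
            err, _ = estimate_error(state, task, eval_samples, rng, widths)
            curve.append((t, err))
        if float(state.L_hat.mean()) < config.ell:
            converged = True
            break
    final_err, _ = estimate_error(state, task, eval_samples, rng, widths)
    if not curve or curve[-1][0] != t:
        curve.append((t, final_err))
    run = LearningRun(
        config={
            "task": task.name, "variant": variant,
            "n_in": grid_in.n, "n_out": grid_out.n,
            "alpha": config.alpha, "c_A": config.c_A,
            "c_B": config.resolved_c_B(task.C),
            "theta_prune": config.theta_prune, "theta_syn": config.theta_syn,
            "ell": config.ell, "k_static": config.k_static,
            "max_samples": config.max_samples,
        },
        seed=None,
        curve=curve,
        converged=converged,
        final_metric=final_err,
    )
    return state, run
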