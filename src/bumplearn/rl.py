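"""Reinforcement-learning bump agent: k-step TD returns drive a bump policy.

The policy maps the (bump-coded) environment state to a (bump-coded) action
through probabilistic synapses with a *static* bump width.  A tabular value
function v(S) supplies the baseline: the k-step return

    G_t = R_{t+1} + ... + R_{t+k} + v(S_{t+k}) - v(S_t)

estimates the reward attributable to the action at time t (bootstrap term 0
and truncated sum at episode end).  G_t updates the value table,
v(S_t) <- v(S_t) + alpha G_t, and nudges the synaptic probabilities of the
co-active state/action bumps:

    p <- p + (0.9 - p) min(beta G, 1)   if G >= 0
    p <- p + (p - 0.1) max(beta G, -1)  if G < 0

so every probability stays inside [0.1, 0.9] — synapses are never pruned or
saturated, and exploration comes solely from the probabilistic transmission
and attractor tie-breaking (no added action noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import SynapseState, bump_scores
from .population import PopulationGrid, interval_k
from .tasks import Environment

__all__ = [
    "ValueTable",
    "RLConfig",
    "compute_return",
    "value_update",
    "policy_probability_update",
    "rl_train",
]

P_LO = 0.1
P_HI = 0.9


class StateCorruptionError(RuntimeError):
    """A synaptic probability left the [0.1, 0.9] clip interval."""


@dataclass
class ValueTable:
    """Tabular value function over a discretized state box (nearest cell)."""

    low: np.ndarray
    high: np.ndarray
    bins: int = 50
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if self.v is None:
            self.v = np.zeros((self.bins,) * len(self.low))

    def cell(self, state: np.ndarray) -> Tuple[int, ...]:
        z = (np.asarray(state, dtype=float) - self.low) / (self.high - self.low)
        idx = np.clip((z * self.bins).astype(int), 0, self.bins - 1)
        return tuple(int(i) for i in idx)

    def __getitem__(self, cell) -> float:
        return float(self.v[cell])

    def __setitem__(self, cell, value: float) -> None:
        self.v[cell] = value


@dataclass
class RLConfig:
    """Hyperparameters of the RL bump agent.

    ``n_state`` is the neurons per state axis, ``n_action`` per action axis;
    ``k_policy`` / ``k_action`` the static bump widths.  ``beta`` is scaled
    so |beta G| is a moderate step at typical return magnitudes; the goal
    reward saturates the update (clip at 1).  Defaults were fixed once by a
    coarse search on the mountain-car task.  A fast value step (``alpha_v``)
    matters there: frequently visited low-value states make k-step returns
    positive for actions that leave them, which is the exploration pressure
    that first drives the car out of the valley.
    """

    td_k: int = 10
    alpha_v: float = 0.5
    beta: float = 0.1
    k_policy: int = 5
    k_action: int = 10
    n_state: int = 30
    n_action: int = 100
    value_bins: int = 50
    episodes: int = 300
    p_init: float = 0.5

    def __post_init__(self) -> None:
        if self.td_k < 1:
            raise ValueError("td_k must be >= 1")
        if not P_LO <= self.p_init <= P_HI:
            raise ValueError(f"p_init must lie in [{P_LO}, {P_HI}]")


def compute_return(
    rewards: Sequence[float], v_boot: float, v_t: float
) -> float:
    """k-step return G_t = R_{t+1} + ... + R_{t+k} + v(S_{t+k}) - v(S_t).

    For steps within k of episode end the caller passes the truncated reward
    list and ``v_boot = 0``.
    """
    return float(sum(rewards) + v_boot - v_t)


def value_update(v_t: float, G: float, alpha_v: float) -> float:
    """Tabular TD update v <- v + alpha G."""
    return v_t + alpha_v * G


def policy_probability_update(p, G: float, beta: float):
    """Clipped reinforce-type probability update; result stays in [0.1, 0.9]."""
    p = np.asarray(p, dtype=float)
    if np.any(p < P_LO - 1e-12) or np.any(p > P_HI + 1e-12):
        raise StateCorruptionError(f"probability outside [{P_LO}, {P_HI}]")
    if G >= 0:
        out = p + (P_HI - p) * min(beta * G, 1.0)
    else:
        out = p + (p - P_LO) * max(beta * G, -1.0)
    # the rule keeps p in [0.1, 0.9] exactly; clip only repairs float rounding
    return np.clip(out, P_LO, P_HI)


def _encode_state(state, env: Environment, grid: PopulationGrid) -> Tuple[int, ...]:
    low, high = env.state_box
    z = np.clip((np.asarray(state, dtype=float) - low) / (high - low), 0.0, 1.0)
    return tuple(int(v) for v in np.clip(np.floor(z * grid.n + 0.5), 1, grid.n).astype(int))


def rl_train(
    env: Environment,
    config: RLConfig,
    rng: Optional[np.random.Generator] = None,
    probe=None,
):
    """Train the RL bump agent; returns (state, value table, LearningRun).

    The learning curve records (episode, total reward).  ``probe(state)``,
    if given, is called once per episode (e.g. to audit invariants).
    """
    from .evaluation import LearningRun

    rng = rng if rng is not None else np.random.default_rng()
    d_state = len(env.state_box[0])
    d_action = len(env.action_box[0])
    grid_in = PopulationGrid(d_state, config.n_state)
    grid_out = PopulationGrid(d_action, config.n_action)
    syn = SynapseState.create(grid_in, grid_out, p_init=config.p_init)
    table = ValueTable(env.state_box[0], env.state_box[1], bins=config.value_bins)
    a_low, a_high = env.action_box

    rows_cache: Dict[Tuple[int, ...], np.ndarray] = {}
    cols_cache: Dict[int, np.ndarray] = {}

    def bump_rows(center: Tuple[int, ...]) -> np.ndarray:
        rows = rows_cache.get(center)
        if rows is None:
            axes = [interval_k(a, config.k_policy, grid_in) - 1 for a in center]
            mesh = np.meshgrid(*axes, indexing="ij")
            rows = np.ravel_multi_index([g.ravel() for g in mesh], grid_in.shape)
            rows_cache[center] = rows
        return rows

    def bump_cols(center_flat: int) -> np.ndarray:
        cols = cols_cache.get(center_flat)
        if cols is None:
            center = grid_out.unravel(center_flat)
            axes = [interval_k(a, config.k_action, grid_out) - 1 for a in center]
            mesh = np.meshgrid(*axes, indexing="ij")
            cols = np.ravel_multi_index([g.ravel() for g in mesh], grid_out.shape)
            cols_cache[center_flat] = cols
        return cols

    def finalize(t0: int, cells, pairs, rewards, v_boot: float) -> None:
        G = compute_return(rewards[t0 : t0 + config.td_k], v_boot, table[cells[t0]])
        table[cells[t0]] = value_update(table[cells[t0]], G, config.alpha_v)
        if config.beta != 0.0:
            r, c = pairs[t0]
            syn.p[np.ix_(r, c)] = policy_probability_update(
                syn.p[np.ix_(r, c)], G, config.beta
            )

    curve: List[Tuple[int, float]] = []
    for ep in range(config.episodes):
        s = env.reset(rng)
        cells: List[Tuple[int, ...]] = []
        pairs: List[Tuple[np.ndarray, np.ndarray]] = []
        rewards: List[float] = []
        done = False
        t = 0
        while not done:
            cells.append(table.cell(s))
            center = _encode_state(s, env, grid_in)
            rows = bump_rows(center)
            draw = rng.random((len(rows), grid_out.size)) < syn.p[rows]
            counts = draw.sum(axis=0).astype(np.int64)
            scores = bump_scores(counts, config.k_action, grid_out).ravel()
            keys = scores + rng.random(scores.shape)
            win = int(np.argmax(keys))
            pairs.append((rows, bump_cols(win)))
            y = (np.array(grid_out.unravel(win), dtype=float)) / grid_out.n
            action = a_low + y * (a_high - a_low)
            s, r, done = env.step(action)
            rewards.append(float(r))
            if t - config.td_k + 1 >= 0 and not done:
                finalize(t - config.td_k + 1, cells, pairs, rewards, table[table.cell(s)])
            t += 1
        # flush the tail with truncated sums and zero bootstrap
        start = max(0, t - config.td_k)
        for t0 in range(start, t):
            finalize(t0, cells, pairs, rewards, 0.0)
        curve.append((ep + 1, float(sum(rewards))))
        if probe is not None:
            probe(syn)
    run = LearningRun(
        config={"algorithm": "rl", "episodes": config.episodes,
                "td_k": config.td_k, "alpha_v": config.alpha_v,
                "beta": config.beta, "k_policy": config.k_policy,
                "k_action": config.k_action, "n_state": config.n_state,
                "n_action": config.n_action, "value_bins": config.value_bins},
        seed=None,
        curve=curve,
        converged=True,
        final_metric=curve[-1][1] if curve else 0.0,
    )
    return syn, table, run
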