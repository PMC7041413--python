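"""Counter-based bump learning: the analytically tractable variants.

The *static* variant fixes the bump widths k_A, k_B (with k_B/k_A equal to
the Lipschitz constant C of the target mapping) and a single error threshold
L_hat.  For each of M random samples it activates an output bump through the
probabilistic synapses and increments the counters c_ij of every synapse
between the two bumps if the feedback L(x, y) is at most L_hat, otherwise
decrements them.  After

    M = ceil(c * (n/k)^(dA+dB) * ln n),    c = (dA+dB+1) (2C)^dA (dA+dB)^(dA+dB)

samples, all synapses with non-positive counters are pruned.  This leaves
each input neuron connected to a band of outputs around its target and gives
final error below 3k/n with high probability.

The *dynamic* variant runs the static procedure in phases, halving the width
and the threshold each phase, so the surviving band around the target
shrinks geometrically; error epsilon is reached after on the order of
epsilon^(-dA) * log n samples in total.  Because each phase explores only
the band left by the previous one, the (n/k)^dB output-candidate factor in
the sample count is replaced by (band/k_B)^dB from the second phase on (see
docs/methods.md).

Counter updates within a phase are pure summation over i.i.d. samples (the
probabilities change only at phase boundaries), so the sample loop is
processed in vectorised batches; tie-breaking uses independent uniform keys,
which realises the uniform-over-maximizers rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

import numpy as np

from .network import SynapseState, activate, bump_scores
from .population import PopulationGrid, encode_value, make_bump
from .tasks import TaskSpec

__all__ = [
    "TheoryConfig",
    "theory_sample_count",
    "static_theory_train",
    "dynamic_theory_train",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class TheoryConfig:
    """Hyperparameters of the counter-based algorithms.

    c_k sets the starting width k_0 = floor(c_k * n) of the dynamic variant
    and must satisfy 0 < c_k <= 2 / (3 (dA + dB)).  ell is the desired final
    error; the per-phase error threshold is the bound scale 3k/n times
    ``threshold_scale``.  ``sample_budget_scale`` multiplies the formula
    sample count M (1 reproduces the formula; smaller values give desk-scale
    runs with correspondingly weaker guarantees).
    """

    C: float = 1.0
    ell: float = 0.05
    c_k: Optional[float] = None
    threshold_scale: float = 1.0
    sample_budget_scale: float = 1.0
    eval_samples: int = 1000

    def resolved_c_k(self, d_A: int, d_B: int) -> float:
        bound = 2.0 / (3.0 * (d_A + d_B))
        ck = bound if self.c_k is None else self.c_k
        if not 0.0 < ck <= bound + 1e-12:
            raise ConfigurationError(
                f"c_k={ck} outside (0, {bound}] for d_A={d_A}, d_B={d_B}"
            )
        return ck


def theory_sample_count(n: int, k: int, d_A: int, d_B: int, C: float) -> int:
    """Sample count M = ceil(c (n/k)^(dA+dB) ln n) of the static algorithm."""
    if k >= n:
        raise ConfigurationError(f"need k < n, got k={k}, n={n}")
    if k < 1:
        raise ConfigurationError(f"need k >= 1, got k={k}")
    c = (d_A + d_B + 1) * (2.0 * C) ** d_A * (d_A + d_B) ** (d_A + d_B)
    return math.ceil(c * (n / k) ** (d_A + d_B) * math.log(n))


def _phase_sample_count(
    n: int, k_A: int, k_B: int, d_A: int, d_B: int, C: float,
    out_candidates_per_axis: float, scale: float,
) -> int:
    """Static-formula count with the output-candidate factor made explicit."""
    c = (d_A + d_B + 1) * (2.0 * C) ** d_A * (d_A + d_B) ** (d_A + d_B)
    r = min(out_candidates_per_axis, n / k_B)
    r = max(r, 1.0)
    return max(1, math.ceil(scale * c * (n / k_A) ** d_A * r**d_B * math.log(n)))


def _counter_pass_1d(
    task: TaskSpec,
    state: SynapseState,
    k_A: int,
    k_B: int,
    L_threshold: float,
    M: int,
    rng: np.random.Generator,
) -> None:
    """Vectorised counter updates for 1-D bounded populations."""
    n_in, n_out = state.grid_in.n, state.grid_out.n
    f = task.f
    batch = max(1, int(4_000_000 // max(1, n_out)))
    # output-window bounds per candidate center (0-based, half-open)
    a = np.arange(1, n_out + 1)
    wlo = np.maximum(1, np.ceil(a - k_B / 2).astype(int)) - 1
    whi = np.minimum(n_out, np.floor(a + k_B / 2).astype(int))
    # p is fixed during a pass (pruning happens afterwards) and equals p_init
    # on every live synapse, so each output neuron's synaptic input is
    # Binomial(live rows in the input bump, p_init): precompute a per-column
    # prefix count of live rows and draw binomials directly.
    live_cs = np.concatenate(
        [np.zeros((1, n_out), dtype=np.int32),
         np.cumsum(state.p > 0.0, axis=0, dtype=np.int32)],
        axis=0,
    )
    done = 0
    while done < M:
        b = min(batch, M - done)
        x = rng.random(b)
        centers = np.clip(np.floor(x * n_in + 0.5).astype(int), 1, n_in)
        rlo = np.maximum(1, np.ceil(centers - k_A / 2).astype(int)) - 1
        rhi = np.minimum(n_in, np.floor(centers + k_A / 2).astype(int))
        counts = rng.binomial(live_cs[rhi] - live_cs[rlo], state.p_init)
        cs = np.concatenate(
            [np.zeros((b, 1), dtype=np.int64), np.cumsum(counts, axis=1)], axis=1
        )
        scores = cs[:, whi] - cs[:, wlo]
        keys = scores + rng.random(scores.shape)  # uniform tie-break
        win = np.argmax(keys, axis=1) + 1  # 1-based output center
        y = win / n_out
        fx = np.asarray(f(x)).reshape(-1) if f is not None else None
        if fx is not None:
            L = np.abs(fx - y)
        else:
            L = np.array([task.feedback(x[s], y[s]) for s in range(b)])
        good = L <= L_threshold
        clo = np.maximum(1, np.ceil(win - k_B / 2).astype(int)) - 1
        chi = np.minimum(n_out, np.floor(win + k_B / 2).astype(int))
        for s in range(b):
            delta = 1 if good[s] else -1
            state.c[rlo[s]:rhi[s], clo[s]:chi[s]] += delta
        done += b


def _counter_pass_generic(
    task: TaskSpec,
    state: SynapseState,
    k_A: int,
    k_B: int,
    L_threshold: float,
    M: int,
    rng: np.random.Generator,
) -> None:
    grid_in, grid_out = state.grid_in, state.grid_out
    for _ in range(M):
        x = rng.random(grid_in.d)
        I = make_bump(encode_value(x, grid_in), k_A, grid_in)
        sample = activate(I, k_B, state, rng)
        L = task.feedback(x, sample.y)
        if not np.isscalar(L) or not math.isfinite(float(L)):
            raise ValueError(f"feedback must be a finite scalar, got {L!r}")
        delta = 1 if L <= L_threshold else -1
        state.c[np.ix_(I.flat_indices(), sample.output_bump.flat_indices())] += delta


def static_theory_train(
    task: TaskSpec,
    grid_in: PopulationGrid,
    grid_out: PopulationGrid,
    k_A: int,
    L_threshold: Optional[float] = None,
    M: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    state: Optional[SynapseState] = None,
    k_B: Optional[int] = None,
    p_init: float = 0.5,
) -> SynapseState:
    """Run the static counter-based algorithm and prune non-positive counters.

    L_threshold defaults to the bound scale 3 k_A / n; M defaults to the
    formula count; k_B defaults to ceil(C * k_A).  Passing an existing state
    continues on its surviving synapses (counters are reset first).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if k_B is None:
        k_B = max(1, math.ceil(task.C * k_A))
    if L_threshold is None:
        L_threshold = 3.0 * k_A / grid_in.n
    if M is None:
        M = theory_sample_count(grid_in.n, k_A, grid_in.d, grid_out.d, task.C)
    if state is None:
        state = SynapseState.create(grid_in, grid_out, p_init=p_init)
    state.c[:] = 0
    fast = (
        grid_in.d == 1
        and grid_out.d == 1
        and grid_in.topology == "bounded"
        and grid_out.topology == "bounded"
    )
    passer = _counter_pass_1d if fast else _counter_pass_generic
    passer(task, state, k_A, k_B, L_threshold, M, rng)
    state.p[state.c <= 0] = 0.0
    return state


def dynamic_theory_train(
    task: TaskSpec,
    grid_in: PopulationGrid,
    grid_out: PopulationGrid,
    config: TheoryConfig,
    rng: Optional[np.random.Generator] = None,
    error_fn: Optional[Callable[[SynapseState, int, int], float]] = None,
) -> Tuple[SynapseState, List[dict]]:
    """Phase-halving counter algorithm (widths and thresholds divided by 2).

    Stops once the phase error scale 3k/n falls to the target precision ell.
    Returns the trained state and a phase log with one record per phase:
    phase index, k_A, k_B, L_hat, samples used, cumulative samples and
    (if ``error_fn`` is given) the measured post-phase error.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = grid_in.n
    if config.ell < 3.0 / n:
        raise ConfigurationError(
            f"ell={config.ell} below the resolution scale 3/n={3.0 / n}"
        )
    ck = config.resolved_c_k(grid_in.d, grid_out.d)
    k = max(1, int(ck * n))
    state = SynapseState.create(grid_in, grid_out)
    log: List[dict] = []
    cumulative = 0
    phase = 0
    prev_band: Optional[float] = None  # surviving outputs per row, per axis
    while True:
        phase += 1
        k_B = max(1, math.ceil(task.C * k))
        L_hat = config.threshold_scale * 3.0 * k / n
        if prev_band is None:
            r = n / k_B
        else:
            r = prev_band / k_B
        M = _phase_sample_count(
            n, k, k_B, grid_in.d, grid_out.d, task.C, r, config.sample_budget_scale
        )
        static_theory_train(
            task, grid_in, grid_out, k_A=k, L_threshold=L_hat, M=M,
            rng=rng, state=state, k_B=k_B,
        )
        cumulative += M
        live = state.live_counts()
        active_rows = live[live > 0]
        mean_live = float(active_rows.mean()) if active_rows.size else 0.0
        prev_band = max(1.0, mean_live ** (1.0 / grid_out.d))
        rec = {
            "phase": phase,
            "k_A": k,
            "k_B": k_B,
            "L_hat": L_hat,
            "M_used": M,
            "cumulative_samples": cumulative,
            "mean_live": mean_live,
        }
        if error_fn is not None:
            rec["error"] = float(error_fn(state, k, k_B))
        log.append(rec)
        if 3.0 * k / n <= config.ell:
            break
        k = max(1, k // 2)
    return state, log
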