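"""Probabilistic synapses between two bump-coded populations.

Populations A (input) and B (output) are all-to-all connected.  Each synapse
(i, j) has a fixed weight of 1 and a plastic transmission probability
``p_ij``: on every trial the synapse is active with probability ``p_ij``,
independently (a Bernoulli draw, modelling stochastic neurotransmitter
release).  Given an input bump I, each candidate output bump J of width k_B
receives total synaptic input ``s(I, J) = sum of active synapses from I into
J``; an abstract continuous-attractor mechanism activates the candidate bump
with maximal input, ties broken uniformly at random.  The candidate scores
are computed with a separable box-sum (moving-window) over the per-output-
neuron input counts, which is exactly equivalent to the naive double sum.

The state additionally carries the bookkeeping used by the learning rules:
integer counters ``c_ij`` (counter-based rules), inactivity counters
``d_ij``, per-input-neuron consolidation flags and running error thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .population import BumpActivation, PopulationGrid, make_bump, decode_center

__all__ = [
    "SynapseState",
    "TransmissionDraw",
    "ActivationSample",
    "sample_transmission",
    "total_input",
    "bump_scores",
    "activate",
    "prune_pairs",
    "prune_block",
    "consolidate",
    "DegenerateNeuronError",
]

MAX_DENSE_ENTRIES = 10_000_000


class DegenerateNeuronError(RuntimeError):
    """Consolidation requested for an input neuron with no surviving synapses."""


@dataclass
class SynapseState:
    """Dense synaptic state between an input and an output population.

    ``p`` has shape ``(N_A, N_B)`` with flat (row-major, 0-based) neuron
    positions; a pruned synapse has ``p == 0``.  Synaptic weights are fixed
    to 1 and therefore not stored.
    """

    grid_in: PopulationGrid
    grid_out: PopulationGrid
    p: np.ndarray
    c: np.ndarray
    d_inact: np.ndarray
    consolidated: np.ndarray
    L_hat: np.ndarray
    p_init: float = 0.5

    @classmethod
    def create(
        cls,
        grid_in: PopulationGrid,
        grid_out: PopulationGrid,
        p_init: float = 0.5,
        L_hat_init: float = 0.0,
    ) -> "SynapseState":
        n_in, n_out = grid_in.size, grid_out.size
        if n_in * n_out > MAX_DENSE_ENTRIES:
            raise ValueError(
                f"dense synapse matrix {n_in}x{n_out} exceeds "
                f"{MAX_DENSE_ENTRIES} entries; reduce n or d"
            )
        if not 0.0 <= p_init <= 1.0:
            raise ValueError(f"p_init must be in [0,1], got {p_init}")
        return cls(
            grid_in=grid_in,
            grid_out=grid_out,
            p=np.full((n_in, n_out), p_init, dtype=np.float64),
            c=np.zeros((n_in, n_out), dtype=np.int32),
            d_inact=np.zeros((n_in, n_out), dtype=np.int32),
            consolidated=np.zeros(n_in, dtype=bool),
            L_hat=np.full(n_in, L_hat_init, dtype=np.float64),
            p_init=p_init,
        )

    @property
    def live(self) -> np.ndarray:
        """Boolean mask of surviving (unpruned) synapses."""
        return self.p > 0.0

    def live_counts(self) -> np.ndarray:
        """Number of surviving synapses per input neuron."""
        return (self.p > 0.0).sum(axis=1)

    # -- snapshot interchange -------------------------------------------------

    def to_csv(self, path, sidecar: Optional[str] = None) -> None:
        """Write surviving synapses as CSV plus a JSON sidecar.

        CSV columns: i_index, j_index (1-based flat positions), p, c,
        d_inact.  The sidecar holds grid geometry and per-neuron fields.
        """
        import pandas as pd

        rows, cols = np.nonzero(self.p)
        pd.DataFrame(
            {
                "i_index": rows + 1,
                "j_index": cols + 1,
                "p": self.p[rows, cols],
                "c": self.c[rows, cols],
                "d_inact": self.d_inact[rows, cols],
            }
        ).to_csv(path, index=False)
        side = Path(sidecar) if sidecar else Path(path).with_suffix(".json")
        side.write_text(
            json.dumps(
                {
                    "grid_in": {"d": self.grid_in.d, "n": self.grid_in.n,
                                "topology": self.grid_in.topology},
                    "grid_out": {"d": self.grid_out.d, "n": self.grid_out.n,
                                 "topology": self.grid_out.topology},
                    "p_init": self.p_init,
                    "consolidated": self.consolidated.astype(int).tolist(),
                    "L_hat": self.L_hat.tolist(),
                }
            )
        )

    @classmethod
    def from_csv(cls, path, sidecar: Optional[str] = None) -> "SynapseState":
        import pandas as pd

        side = Path(sidecar) if sidecar else Path(path).with_suffix(".json")
        meta = json.loads(side.read_text())
        gi = PopulationGrid(**meta["grid_in"])
        go = PopulationGrid(**meta["grid_out"])
        state = cls.create(gi, go, p_init=meta["p_init"])
        state.p[:] = 0.0
        df = pd.read_csv(path)
        r = df["i_index"].to_numpy() - 1
        c = df["j_index"].to_numpy() - 1
        state.p[r, c] = df["p"].to_numpy()
        state.c[r, c] = df["c"].to_numpy()
        state.d_inact[r, c] = df["d_inact"].to_numpy()
        state.consolidated[:] = np.asarray(meta["consolidated"], dtype=bool)
        state.L_hat[:] = np.asarray(meta["L_hat"], dtype=float)
        return state


@dataclass
class TransmissionDraw:
    """One Bernoulli draw of active synapses from an input bump."""

    rows: np.ndarray  # flat positions of the input-bump neurons
    active: np.ndarray  # bool, shape (len(rows), N_B)


@dataclass
class ActivationSample:
    """Outcome of one attractor activation: the winning output bump."""

    input_bump: BumpActivation
    output_bump: BumpActivation
    y: np.ndarray  # decoded output value
    n_maximizers: int = 1


def sample_transmission(
    I: BumpActivation, state: SynapseState, rng: np.random.Generator
) -> TransmissionDraw:
    """Draw synapse activity from bump ``I``: each (i, j) active w.p. p_ij."""
    rows = I.flat_indices()
    sub = state.p[rows]
    active = rng.random(sub.shape) < sub
    return TransmissionDraw(rows=rows, active=active)


def total_input(draw: TransmissionDraw, J: BumpActivation) -> int:
    """Total synaptic input received by bump ``J`` under ``draw`` (weights 1)."""
    return int(draw.active[:, J.flat_indices()].sum())


def _axis_window_sum(arr: np.ndarray, axis: int, k: int, grid: PopulationGrid) -> np.ndarray:
    """Windowed sum along one axis: out[a] = sum over interval_k(a) of arr."""
    import math

    n = grid.n
    a = np.arange(1, n + 1)
    lo = np.ceil(a - k / 2).astype(np.int64)
    hi = np.floor(a + k / 2).astype(np.int64)
    arr = np.moveaxis(arr, axis, -1)
    if grid.topology == "circular":
        if k >= n:
            out = np.broadcast_to(arr.sum(axis=-1, keepdims=True), arr.shape).copy()
            return np.moveaxis(out, -1, axis)
        cs = np.concatenate(
            [np.zeros(arr.shape[:-1] + (1,), dtype=arr.dtype),
             np.cumsum(np.concatenate([arr, arr], axis=-1), axis=-1)],
            axis=-1,
        )
        # shift the window start into [1, n]; the end then stays within 2n
        lo_s = (lo - 1) % n + 1
        hi_s = lo_s + (hi - lo)
        out = cs[..., hi_s] - cs[..., lo_s - 1]
    else:
        lo = np.maximum(1, lo)
        hi = np.minimum(n, hi)
        cs = np.concatenate(
            [np.zeros(arr.shape[:-1] + (1,), dtype=arr.dtype),
             np.cumsum(arr, axis=-1)],
            axis=-1,
        )
        out = cs[..., hi] - cs[..., lo - 1]
    return np.moveaxis(out, -1, axis)


def bump_scores(counts: np.ndarray, k: int, grid: PopulationGrid) -> np.ndarray:
    """Score s(I, Int_k(b)) for every candidate center b.

    ``counts`` holds the per-output-neuron active-synapse counts (shape
    ``grid.shape``); the result is the separable box-sum over each candidate
    bump, bit-exact equal to the naive double sum.
    """
    counts = counts.reshape(grid.shape)
    out = counts
    for ax in range(grid.d):
        out = _axis_window_sum(out, ax, k, grid)
    return out


def activate(
    I: BumpActivation,
    k_B: int,
    state: SynapseState,
    rng: np.random.Generator,
    draw: Optional[TransmissionDraw] = None,
) -> ActivationSample:
    """Sample an output bump from the activation distribution Act(I, k_B, P).

    One shared transmission draw scores every candidate bump; the attractor
    activates an argmax bump, breaking ties uniformly at random (an all-zero
    draw is a global tie, hence a uniform random bump).
    """
    if draw is None:
        draw = sample_transmission(I, state, rng)
    counts = draw.active.sum(axis=0).astype(np.int64)
    scores = bump_scores(counts, k_B, state.grid_out)
    flat = scores.ravel()
    maximizers = np.flatnonzero(flat == flat.max())
    pick = maximizers[rng.integers(len(maximizers))]
    center = state.grid_out.unravel(int(pick))
    J = make_bump(center, k_B, state.grid_out)
    return ActivationSample(
        input_bump=I,
        output_bump=J,
        y=decode_center(center, state.grid_out),
        n_maximizers=len(maximizers),
    )


def prune_pairs(state: SynapseState, rows: np.ndarray, cols: np.ndarray) -> None:
    """Prune the listed (row, col) synapse pairs (set p to 0). Idempotent."""
    state.p[np.asarray(rows), np.asarray(cols)] = 0.0


def prune_block(state: SynapseState, rows: np.ndarray, cols: np.ndarray) -> None:
    """Prune every synapse in the cross product rows x cols. Idempotent."""
    state.p[np.ix_(np.asarray(rows), np.asarray(cols))] = 0.0


def consolidate(state: SynapseState, row: int) -> None:
    """Set every surviving synapse of input neuron ``row`` to p=1 and freeze it.

    Raises :class:`DegenerateNeuronError` if the neuron has no survivors.
    """
    mask = state.p[row] > 0.0
    if not mask.any():
        raise DegenerateNeuronError(f"input neuron {row} has no surviving synapses")
    state.p[row, mask] = 1.0
    state.consolidated[row] = True
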