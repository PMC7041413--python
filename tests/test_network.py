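"""Synaptic transmission, attractor activation, pruning and consolidation."""

import itertools

import numpy as np
import pytest

from bumplearn.network import (
    DegenerateNeuronError,
    SynapseState,
    TransmissionDraw,
    activate,
    bump_scores,
    consolidate,
    prune_block,
    prune_pairs,
    sample_transmission,
    total_input,
)
from bumplearn.population import PopulationGrid, make_bump


def make_state(n_in=10, n_out=10, d_in=1, d_out=1, p=0.5, topology="bounded"):
    gi = PopulationGrid(d_in, n_in, topology)
    go = PopulationGrid(d_out, n_out, topology)
    return SynapseState.create(gi, go, p_init=p)


def test_transmission_deterministic_extremes(rng):
    state = make_state(p=1.0)
    I = make_bump((5,), 4, state.grid_in)
    draw = sample_transmission(I, state, rng)
    assert draw.active.all()
    state.p[:] = 0.0
    assert not sample_transmission(I, state, rng).active.any()


def test_transmission_binomial_fraction(rng):
    """Active fraction of p=0.5 synapses concentrates as a binomial."""
    state = make_state(n_in=100, n_out=100, p=0.5)
    I = make_bump((50,), 100, state.grid_in)
    draw = sample_transmission(I, state, rng)
    frac = draw.active.mean()
    assert draw.active.size == 10_000
    assert abs(frac - 0.5) < 0.02


def test_total_input_counts(rng):
    state = make_state(p=1.0)
    I = make_bump((5,), 2, state.grid_in)  # 3 neurons
    J = make_bump((5,), 3, state.grid_out)  # 3 neurons (odd k)
    draw = sample_transmission(I, state, rng)
    assert total_input(draw, J) == 9
    empty = TransmissionDraw(rows=I.flat_indices(),
                             active=np.zeros_like(draw.active))
    assert total_input(empty, J) == 0


def test_total_input_equals_bruteforce_recount(rng):
    state = make_state(n_in=8, n_out=12, p=0.4)
    I = make_bump((4,), 4, state.grid_in)
    draw = sample_transmission(I, state, rng)
    J = make_bump((7,), 5, state.grid_out)
    manual = sum(
        int(draw.active[ri, state.grid_out.ravel(j)])
        for ri in range(len(draw.rows))
        for j in J
    )
    assert total_input(draw, J) == manual


def brute_force_scores(draw, k_B, grid_out):
    counts = draw.active.sum(axis=0)
    out = np.empty(grid_out.size, dtype=np.int64)
    for flat in range(grid_out.size):
        J = make_bump(grid_out.unravel(flat), k_B, grid_out)
        out[flat] = counts[J.flat_indices()].sum()
    return out.reshape(grid_out.shape)


@pytest.mark.parametrize("topology", ["bounded", "circular"])
def test_boxsum_scores_match_bruteforce(rng, topology):
    """Separable box-sum scoring is bit-exact against naive enumeration."""
    for trial in range(30):
        d = int(rng.integers(1, 3))
        n = int(rng.integers(4, 21 if d == 1 else 9))
        k_B = int(rng.integers(0, 5))
        state = make_state(n_in=6, n_out=n, d_out=d, p=0.5, topology=topology)
        I = make_bump((3,), 3, state.grid_in)
        draw = sample_transmission(I, state, rng)
        scores = bump_scores(draw.active.sum(axis=0).astype(np.int64), k_B, state.grid_out)
        assert np.array_equal(scores, brute_force_scores(draw, k_B, state.grid_out))


def test_activate_unique_band_wins(rng):
    """A single all-on column band under one input row forces its center."""
    state = make_state(n_in=10, n_out=20, p=0.0)
    target = 13
    band = make_bump((target,), 4, state.grid_out).flat_indices()
    state.p[4, band] = 1.0
    I = make_bump((5,), 0, state.grid_in)  # only row index 5 -> flat 4
    for _ in range(5):
        out = activate(I, 4, state, rng)
        assert out.output_bump.center == (target,)
        assert np.allclose(out.y, target / 20)


def test_activate_never_beaten_under_frozen_draw(rng):
    """The chosen bump's score is maximal among all candidates (oracle check)."""
    for _ in range(20):
        state = make_state(n_in=7, n_out=15, p=0.6)
        I = make_bump((4,), 4, state.grid_in)
        draw = sample_transmission(I, state, rng)
        out = activate(I, 3, state, rng, draw=draw)
        scores = brute_force_scores(draw, 3, state.grid_out).ravel()
        assert scores[state.grid_out.ravel(out.output_bump.center)] == scores.max()


def test_activate_tie_breaking_uniform(rng):
    """With an all-ones frozen draw every interior center ties; the winner is uniform."""
    from scipy.stats import chisquare

    state = make_state(n_in=5, n_out=10, p=1.0)
    I = make_bump((3,), 2, state.grid_in)
    k_B = 2
    draw = sample_transmission(I, state, rng)  # deterministic all-ones
    scores = brute_force_scores(draw, k_B, state.grid_out).ravel()
    winners = np.flatnonzero(scores == scores.max())
    hits = np.zeros(state.grid_out.size)
    trials = 4000
    for _ in range(trials):
        out = activate(I, k_B, state, rng, draw=draw)
        hits[state.grid_out.ravel(out.output_bump.center)] += 1
    assert hits[np.setdiff1d(np.arange(10), winners)].sum() == 0
    assert chisquare(hits[winners]).pvalue > 1e-3


def test_all_zero_draw_uniform_over_all_bumps(rng):
    """Pruning a whole row makes activation a global tie -> any center possible."""
    state = make_state(n_in=5, n_out=8, p=0.5)
    prune_block(state, np.arange(5), np.arange(8))
    I = make_bump((3,), 0, state.grid_in)
    centers = {activate(I, 1, state, rng).output_bump.center[0] for _ in range(200)}
    assert len(centers) == 8


def test_prune_idempotent_and_consolidate():
    state = make_state(n_in=6, n_out=6, p=0.5)
    prune_pairs(state, np.array([0, 1]), np.array([2, 3]))
    snap = state.p.copy()
    prune_pairs(state, np.array([0, 1]), np.array([2, 3]))
    assert np.array_equal(snap, state.p)
    prune_block(state, np.array([2]), np.arange(5))  # row 2 keeps one survivor
    consolidate(state, 2)
    assert state.consolidated[2]
    assert state.p[2, 5] == 1.0 and (state.p[2, :5] == 0).all()
    consolidate(state, 2)  # idempotent
    assert state.p[2, 5] == 1.0
    prune_block(state, np.array([3]), np.arange(6))
    with pytest.raises(DegenerateNeuronError):
        consolidate(state, 3)


def test_consolidated_band_maps_deterministically(rng):
    """Rows consolidated onto disjoint bands give a deterministic map."""
    state = make_state(n_in=10, n_out=100, p=0.0)
    for r in range(10):
        band = make_bump((r * 10 + 5,), 4, state.grid_out).flat_indices()
        state.p[r, band] = 1.0
        state.consolidated[r] = True
    for r in [0, 4, 9]:
        I = make_bump((r + 1,), 0, state.grid_in)
        out = activate(I, 4, state, rng)
        assert out.output_bump.center == (r * 10 + 5,)


def test_snapshot_roundtrip(tmp_path, rng):
    state = make_state(n_in=8, n_out=9, p=0.5)
    prune_block(state, np.array([1]), np.arange(4))
    state.c[2, 3] = 7
    state.d_inact[4, 5] = 2
    state.L_hat[:] = rng.random(8)
    consolidate(state, 1)
    path = tmp_path / "snap.csv"
    state.to_csv(path)
    back = SynapseState.from_csv(path)
    assert np.array_equal(back.p, state.p)
    assert np.array_equal(back.c, state.c)
    assert np.array_equal(back.d_inact, state.d_inact)
    assert np.array_equal(back.consolidated, state.consolidated)
    assert np.allclose(back.L_hat, state.L_hat)


def test_dense_size_guard():
    with pytest.raises(ValueError, match="dense"):
        SynapseState.create(PopulationGrid(2, 4000), PopulationGrid(1, 4000))
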