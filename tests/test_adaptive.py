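"""Adaptive algorithm mechanisms: thresholds, pruning, width, consolidation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bumplearn.adaptive import (
    AdaptiveConfig,
    adaptive_step,
    adaptive_train,
    adaptive_width,
    update_error_threshold,
    width_policy,
)
from bumplearn.network import SynapseState
from bumplearn.population import PopulationGrid
from bumplearn.tasks import identity_task


@pytest.mark.parametrize(
    "L_hat,L,alpha,expected",
    [(0.5, 0.5, 0.3, 0.5), (7.0, 0.2, 1.0, 0.2), (1.0, 0.0, 0.1, 0.9)],
)
def test_ema_examples(L_hat, L, alpha, expected):
    assert update_error_threshold(L_hat, L, alpha) == pytest.approx(expected)


@given(st.floats(0, 10), st.floats(0, 10), st.floats(0.01, 1.0))
@settings(max_examples=100, deadline=None)
def test_ema_contraction(L_hat, L, alpha):
    """One EMA step moves the threshold toward L by exactly a factor (1-alpha)."""
    new = update_error_threshold(L_hat, L, alpha)
    assert abs(new - L) == pytest.approx((1 - alpha) * abs(L_hat - L), abs=1e-9)


@pytest.mark.parametrize(
    "count,c,d,expected",
    [(1000, 0.05, 1, 50), (0, 0.3, 1, 1), (7, 0.05, 1, 1), (256, 0.5, 2, 8)],
)
def test_adaptive_width_examples(count, c, d, expected):
    assert adaptive_width(count, c, d) == expected


@given(st.integers(0, 5000), st.integers(0, 5000), st.floats(0.01, 0.5))
@settings(max_examples=100, deadline=None)
def test_adaptive_width_monotone(c1, c2, frac):
    lo, hi = min(c1, c2), max(c1, c2)
    assert adaptive_width(lo, frac) <= adaptive_width(hi, frac)


def make_setup(n=40, **kw):
    task = identity_task()
    gi = go = PopulationGrid(1, n)
    cfg = AdaptiveConfig(k_static=4, **kw)
    state = SynapseState.create(gi, go, L_hat_init=cfg.resolved_L_hat_init(task))
    return task, cfg, state


def test_huge_initial_threshold_blocks_error_pruning(rng):
    """With L_hat_init far above any feedback, the first samples never error-prune."""
    task, cfg, state = make_setup(L_hat_init=100.0, theta_prune=10**6)
    before = state.live_counts().sum()
    for _ in range(5):
        rec = adaptive_step(state, task, cfg, "static", rng)
        assert rec.pruned_rows == 0
    assert state.live_counts().sum() == before


def test_theta_prune_one_collapses_rows_to_last_output(rng):
    """theta_prune=1 prunes every synapse outside the current output bump."""
    task, cfg, state = make_setup(L_hat_init=100.0, theta_prune=1)
    rec = adaptive_step(state, task, cfg, "static", rng)
    rows = np.flatnonzero(state.live_counts() < state.grid_out.n)
    assert rows.size >= cfg.k_static  # the activated input bump
    for r in rows:
        live = np.flatnonzero(state.p[r] > 0)
        # exactly the output bump: one clamped interval of width k_B
        assert rec.k_B // 2 + 1 <= live.size <= rec.k_B + 1
        assert live[-1] - live[0] + 1 == live.size


def test_consolidated_rows_are_frozen(rng):
    task, cfg, state = make_setup(L_hat_init=0.0)  # always error-prune
    state.p[:] = 0.0
    band = np.arange(10, 15)
    for r in range(state.grid_in.size):
        state.p[r, band] = 1.0
        state.consolidated[r] = True
    snap = state.p.copy()
    for _ in range(30):
        adaptive_step(state, task, cfg, "static", rng)
    assert np.array_equal(state.p, snap)


def test_degenerate_row_reseeded(rng):
    """A row that loses every synapse is re-seeded with a p_init band."""
    task, cfg, state = make_setup(L_hat_init=1e-9, theta_prune=10**6, theta_syn=3)
    # all feedback >= L_hat -> every activated bump pruned immediately
    reseeds = 0
    for _ in range(300):
        reseeds += adaptive_step(state, task, cfg, "static", rng).reseeded_rows
    assert reseeds > 0
    assert (state.live_counts() > 0).any()


def test_live_counts_nonincreasing_without_reseeds(rng):
    """Pruning only removes: per-row live counts never grow (absent re-seeds)."""
    task, cfg, state = make_setup(L_hat_init=100.0, theta_prune=5)
    prev = state.live_counts().copy()
    widths = width_policy(state, cfg, task, "static")
    for _ in range(200):
        rec = adaptive_step(state, task, cfg, "static", rng, widths=widths)
        assert rec.reseeded_rows == 0
        cur = state.live_counts()
        assert (cur <= prev).all()
        prev = cur


def test_stopping_rule_and_convergence_flag():
    task = identity_task()
    gi = go = PopulationGrid(1, 50)
    cfg = AdaptiveConfig(k_static=5, ell=0.2, max_samples=30000)
    state, run = adaptive_train(task, gi, go, cfg, "static",
                                rng=np.random.default_rng(3), eval_samples=300)
    assert run.converged
    assert state.L_hat.mean() < cfg.ell
    # estimated true error at stopping within EMA-lag tolerance of target
    assert run.final_metric <= 2 * cfg.ell


def test_nonconvergence_flag_at_sample_cap():
    task = identity_task()
    gi = go = PopulationGrid(1, 50)
    cfg = AdaptiveConfig(k_static=5, ell=1e-6, max_samples=500)
    _, run = adaptive_train(task, gi, go, cfg, "static",
                            rng=np.random.default_rng(3), eval_samples=100,
                            record_curve=False)
    assert not run.converged
    assert run.curve[-1][0] == 500


def test_dynamic_width_follows_live_count():
    task = identity_task()
    gi = go = PopulationGrid(1, 100)
    cfg = AdaptiveConfig(c_A=0.1)
    state = SynapseState.create(gi, go)
    widths = width_policy(state, cfg, task, "dynamic")
    assert widths(50) == (10, 10)
    state.p[50, 50:] = 0.0  # halve row 50's live count
    assert widths(50) == (5, 5)


def test_config_validation():
    with pytest.raises(ValueError):
        AdaptiveConfig(alpha=0.0)
    with pytest.raises(ValueError):
        AdaptiveConfig(theta_prune=0)
    with pytest.raises(ValueError):
        width_policy(
            SynapseState.create(PopulationGrid(1, 10), PopulationGrid(1, 10)),
            AdaptiveConfig(),
            identity_task(),
            "static",
        )
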