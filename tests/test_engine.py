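"""Synchronous tissue dynamics, event detection, and the refusal walk."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriasim.cells import CellPhase, InteractionThresholds, RefusePolicy
from atriasim.engine import (
    SimConfig,
    WalkSpec,
    detect_avn_event,
    initial_state,
    run,
    scale_rr,
    step_tissue,
    walk_refuse,
)
from atriasim.tissue import LatticeSpec, NodeRegions, build_lattice

F = int(CellPhase.F)
A = int(CellPhase.A)


def _reference_step(state, tissue, thresholds, p_refuse, rng):
    """Straightforward per-cell update: snapshot, count, apply cell_step."""
    n = tissue.n_cells
    u = rng.random(n)
    firing = state.phase == F
    new_phase = np.empty_like(state.phase)
    new_clock = np.empty_like(state.clock)
    for i in range(n):
        nf = int(firing[tissue.in_neighbors(i)].sum())
        ph, x = _scalar(state, tissue, i, nf, thresholds, u[i], p_refuse)
        new_phase[i] = int(ph)
        new_clock[i] = x
    return dataclasses.replace(state, phase=new_phase, clock=new_clock)


def _scalar(state, tissue, i, nf, thresholds, draw, p_refuse):
    """Per-cell rule written directly against the per-cell guard arrays."""
    from atriasim.cells import CellTimers, interact_step

    timers = CellTimers(f=tissue.f[i], r0=tissue.r[i], a=tissue.a[i])
    ph, x, _ = interact_step(
        CellPhase(int(state.phase[i])), int(state.clock[i]), nf, thresholds,
        timers, r=tissue.r[i], refuse_draw=draw, p_refuse=p_refuse,
    )
    return ph, x


class TestStepTissue:
    def test_all_resting_cells_just_advance_clocks(self, small_config):
        tissue = build_lattice(small_config.spec, small_config.regions,
                               small_config.san_timers,
                               small_config.atrial_timers, seed=1)
        state = initial_state(tissue)
        rng = np.random.default_rng(0)
        refusable = np.ones(tissue.n_cells, dtype=bool)
        nxt = step_tissue(state, tissue, small_config.thresholds, 0.0,
                          refusable, rng)
        assert (nxt.phase == state.phase).all()
        assert (nxt.clock == 1).all()

    @pytest.mark.parametrize("p_refuse", [0.0, 0.35])
    def test_matches_per_cell_reference_state_for_state(self, p_refuse):
        """Vectorised engine equals the scalar per-cell rule over 500 steps."""
        spec = LatticeSpec(L=12, p_H=0.5, p_L=0.5)
        regions = NodeRegions(san_rows=(2, 6), san_cols=(1, 3),
                              avn_rows=(10, 12), avn_cols=(4, 8), avn_k=3)
        cfg = SimConfig(spec=spec, regions=regions, seed=5)
        tissue = build_lattice(spec, regions, cfg.san_timers,
                               cfg.atrial_timers, seed=5)
        refusable = np.ones(tissue.n_cells, dtype=bool)
        rng_a = np.random.default_rng(99)
        rng_b = np.random.default_rng(99)
        state_a = initial_state(tissue)
        state_b = initial_state(tissue)
        for t in range(500):
            state_a = step_tissue(state_a, tissue, cfg.thresholds, p_refuse,
                                  refusable, rng_a)
            state_b = _reference_step(state_b, tissue, cfg.thresholds,
                                      p_refuse, rng_b)
            assert np.array_equal(state_a.phase, state_b.phase), f"phases differ at step {t}"
            assert np.array_equal(state_a.clock, state_b.clock), f"clocks differ at step {t}"

    def test_single_firing_neighbor_forces_rest_cell(self, dense_config):
        tissue = build_lattice(dense_config.spec, dense_config.regions,
                               dense_config.san_timers,
                               dense_config.atrial_timers, seed=2)
        state = initial_state(tissue)
        j = tissue.flat(20, 20)
        state.phase[j] = F
        nbr = tissue.flat(21, 20)
        rng = np.random.default_rng(0)
        refusable = np.ones(tissue.n_cells, dtype=bool)
        nxt = step_tissue(state, tissue, InteractionThresholds(N_F=0), 0.0,
                          refusable, rng)
        assert nxt.phase[nbr] == F and nxt.clock[nbr] == 0
        # with certain refusal the neighbour never fires
        nxt = step_tissue(state, tissue, InteractionThresholds(N_F=0), 1.0,
                          refusable, np.random.default_rng(0))
        assert nxt.phase[nbr] == A


class TestDetectAvnEvent:
    def run_counts(self, counts, k):
        armed, events = True, []
        for t, c in enumerate(counts):
            event, armed = detect_avn_event(c, armed, k)
            if event:
                events.append(t)
        return events

    def test_edge_triggered_events(self):
        assert self.run_counts([0, 1, 3, 4, 3, 1, 0, 3], k=3) == [2, 7]

    def test_sustained_crossing_counts_once(self):
        assert self.run_counts([3, 3, 3], k=3) == [0]

    def test_no_event_below_threshold(self):
        assert self.run_counts([2, 1, 2, 0, 2], k=3) == []


class TestRun:
    def test_certain_refusal_everywhere_kills_the_rhythm(self, small_config):
        cfg = dataclasses.replace(small_config,
                                  refuse=RefusePolicy(p_refuse=1.0),
                                  total_steps=600)
        result = run(cfg)
        assert result.rr.size == 0
        assert result.avn_event_times.size == 0

    def test_full_density_rr_locks_to_pacemaker_period(self, dense_config, t_san):
        result = run(dense_config)
        assert result.rr.size > 5
        assert (result.rr == t_san).all()
        # conservation of fronts: every pacemaker firing after the first
        # in-window one yields exactly one AVN event
        expected = (dense_config.total_steps - 1 - result.t_avn_first) // t_san + 1
        assert result.avn_event_times.size == expected

    def test_same_seed_bit_identical_result(self, small_config):
        r1 = run(small_config)
        r2 = run(small_config)
        assert np.array_equal(r1.avn_event_times, r2.avn_event_times)
        assert np.array_equal(r1.rr, r2.rr)
        assert r1.t_bottom_first == r2.t_bottom_first
        assert r1.t_avn_first == r2.t_avn_first

    def test_walk_trace_recorded_and_bounded(self, small_config):
        walk = WalkSpec(p_walk=0.05, eps=0.05, z=0.45)
        cfg = dataclasses.replace(small_config, total_steps=800)
        result = run(cfg, walk)
        trace = result.p_refuse_trace
        assert trace.shape == (800,)
        assert (trace >= 0).all() and (trace <= 0.45 + 1e-12).all()
        assert np.unique(trace).size > 1  # the walk actually moved


class TestWalkRefuse:
    walk = WalkSpec(p_walk=0.5, eps=0.05, z=0.45)

    def test_no_move_probability_zero(self):
        frozen = WalkSpec(p_walk=0.0, eps=0.05, z=0.45)
        p = 0.2
        for zeta in (0.0, 0.5, 0.99):
            assert walk_refuse(p, frozen, zeta, +1) == p

    def test_move_outside_interval_rejected_not_clamped(self):
        assert walk_refuse(0.44, self.walk, zeta=0.1, sign=+1) == 0.44

    def test_accepted_move_shifts_by_eps(self):
        assert walk_refuse(0.2, self.walk, zeta=0.1, sign=+1) == pytest.approx(0.25)
        assert walk_refuse(0.2, self.walk, zeta=0.1, sign=-1) == pytest.approx(0.15)

    def test_accepted_move_count_matches_binomial(self):
        """Interior walk: accepted moves ~ Binomial(n, p_walk)."""
        walk = WalkSpec(p_walk=0.001, eps=1e-6, z=1.0)
        rng = np.random.default_rng(2024)
        n = 1_000_000
        p, accepted = 0.5, 0
        zetas = rng.random(n)
        signs = np.where(rng.random(n) < 0.5, 1, -1)
        for zeta, sign in zip(zetas, signs):
            p_next = walk_refuse(p, walk, zeta, sign)
            if p_next != p:
                accepted += 1
            p = p_next
        assert abs(accepted - 1000) <= 3 * np.sqrt(1000)

    @settings(derandomize=True, max_examples=40)
    @given(z=st.floats(0.1, 1.0), eps=st.floats(0.01, 0.3),
           seed=st.integers(0, 2**31 - 1))
    def test_walk_never_leaves_interval(self, z, eps, seed):
        """Bounds hold by rejection even when eps does not divide z."""
        walk = WalkSpec(p_walk=1.0, eps=eps, z=z)
        rng = np.random.default_rng(seed)
        p = float(rng.uniform(0, z))
        for _ in range(300):
            p = walk_refuse(p, walk, rng.random(),
                            1 if rng.random() < 0.5 else -1)
            assert 0.0 <= p <= z + 1e-12


class TestScaleRR:
    def test_default_factor_seven(self):
        assert scale_rr(np.array([115, 115])).tolist() == [805.0, 805.0]

    def test_empty_and_identity(self):
        assert scale_rr(np.array([])).size == 0
        assert scale_rr(np.array([100, 120]), 1.0).tolist() == [100.0, 120.0]

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            scale_rr(np.array([1.0]), 0.0)
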