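import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scapd.geometry import contains, disc, ellipse
from scapd.simulator import (
    MODEL_RULES,
    Colony,
    ModelSpec,
    PlacementError,
    SimParams,
    TMINUS,
    TPLUS,
    border_turn,
    compute_force,
    init_colony,
    neighbor_fraction,
    run_model,
    sample_direction,
    step,
    velocity_ratio,
)


def brute_force_sum(focal, others, R, sign):
    """Independent per-pair inverse-square summation."""
    fx = fy = 0.0
    s = 1.0 if sign == "push" else -1.0
    for xo, yo in others:
        dx, dy = focal[0] - xo, focal[1] - yo
        d = math.hypot(dx, dy)
        if d <= R:
            fx += s * (dx / d) / d**2
            fy += s * (dy / d) / d**2
    return fx, fy


class TestModelSpec:
    def test_rule_table_round_trips(self):
        for n in range(1, 17):
            assert ModelSpec.from_number(n).model_number == n

    def test_known_combinations(self):
        assert MODEL_RULES[1] == (False, False, False, False)
        assert MODEL_RULES[7] == (True, False, True, False)
        assert MODEL_RULES[14] == (True, False, True, True)
        assert MODEL_RULES[16] == (True, True, True, True)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_number(17)


class TestInitColony:
    def test_counts_types_and_separation(self, disc_pattern, rng):
        colony = init_colony(disc_pattern, 6, 0.5, SimParams(), rng)
        assert colony.n_cells == 6
        assert sum(t == TPLUS for t in colony.types) == 3
        pos = colony.positions()
        for i in range(6):
            assert contains(disc_pattern, pos[i, 0], pos[i, 1], 0.0)
            for j in range(i + 1, 6):
                assert np.hypot(*(pos[i] - pos[j])) >= 2.0

    def test_single_cell(self, ellipse_pattern, rng):
        colony = init_colony(ellipse_pattern, 1, 1.0, SimParams(), rng)
        assert colony.n_cells == 1
        assert colony.types == [TPLUS]

    def test_deterministic_under_seed(self, disc_pattern):
        a = init_colony(disc_pattern, 6, 0.5, SimParams(), np.random.default_rng(5))
        b = init_colony(disc_pattern, 6, 0.5, SimParams(), np.random.default_rng(5))
        assert a.xs == b.xs and a.ys == b.ys and a.headings == b.headings

    def test_infeasible_packing_raises(self, rng):
        tiny = disc(radius=3.0, interior_margin=0.5)
        with pytest.raises(PlacementError):
            init_colony(tiny, 50, 0.5, SimParams(), rng, max_attempts=50)


class TestComputeForce:
    def test_symmetric_neighbours_cancel(self):
        fx, fy = compute_force((0.0, 0.0), [(5.0, 0.0), (-5.0, 0.0)], 50.0, "push")
        assert fx == pytest.approx(0.0, abs=1e-12)
        assert fy == pytest.approx(0.0, abs=1e-12)

    def test_inverse_square_ratio(self):
        near = compute_force((0.0, 0.0), [(1.0, 0.0)], 50.0, "push")
        far = compute_force((0.0, 0.0), [(2.0, 0.0)], 50.0, "push")
        assert abs(near[0]) / abs(far[0]) == pytest.approx(4.0)

    def test_pull_points_toward_neighbour(self):
        fx, _ = compute_force((0.0, 0.0), [(10.0, 0.0)], 50.0, "pull")
        assert fx > 0

    def test_outside_radius_ignored(self):
        assert compute_force((0.0, 0.0), [(60.0, 0.0)], 50.0, "push") == (0.0, 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            focal = tuple(rng.uniform(-50, 50, 2))
            others = [tuple(p) for p in rng.uniform(-60, 60, size=(5, 2))]
            sign = "push" if rng.random() < 0.5 else "pull"
            got = compute_force(focal, others, 40.0, sign)
            want = brute_force_sum(focal, others, 40.0, sign)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_coincident_neighbour_rejected(self):
        with pytest.raises(ValueError):
            compute_force((1.0, 1.0), [(1.0, 1.0)], 50.0, "push")


class TestSampleDirection:
    def test_noiseless_returns_force_angle(self, rng):
        assert sample_direction((1.0, 0.0), 0.0, rng) == pytest.approx(0.0)
        assert sample_direction((0.0, 1.0), 0.0, rng) == pytest.approx(90.0)
        assert sample_direction((-1.0, 0.0), 0.0, rng) == pytest.approx(180.0)

    def test_zero_force_is_uniform(self, rng):
        draws = np.array([sample_direction((0.0, 0.0), 5.0, rng) for _ in range(4000)])
        assert draws.min() >= 0.0 and draws.max() < 360.0
        # uniformity: compare quartile counts
        counts, _ = np.histogram(draws, bins=4, range=(0, 360))
        assert counts.min() > 800

    def test_noise_distribution(self):
        """Mean and circular SD of the heading match the stated normal law."""
        rng = np.random.default_rng(42)
        draws = np.array([sample_direction((1.0, 0.0), 5.0, rng) for _ in range(100_000)])
        wrapped = (draws + 180.0) % 360.0 - 180.0
        assert abs(wrapped.mean()) <= 0.1
        assert abs(wrapped.std() - 5.0) <= 0.2


class TestVelocityRatio:
    def test_closed_forms(self):
        assert velocity_ratio([(3.0, 4.0)]) == pytest.approx(1.0)
        assert velocity_ratio([(1.0, 0.0), (-1.0, 0.0)]) == pytest.approx(0.0)
        assert velocity_ratio([(1.0, 0.0), (0.0, 1.0)]) == pytest.approx(math.sqrt(2) / 2)
        assert velocity_ratio([]) == 1.0

    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)), max_size=8))
    @settings(max_examples=300, derandomize=True)
    def test_bounded_unit_interval(self, forces):
        assert 0.0 <= velocity_ratio(forces) <= 1.0


class TestBorderTurn:
    @pytest.mark.parametrize(
        "current, escape, alpha, expected",
        [
            (0.0, 30.0, 20.0, 340.0),  # escape CCW of current -> turn clockwise
            (0.0, 330.0, 20.0, 20.0),  # escape CW of current -> turn counter-clockwise
            (45.0, 45.0, 20.0, 65.0),  # exact tie -> counter-clockwise
            (350.0, 10.0, 30.0, 320.0),  # wrap-around difference
        ],
    )
    def test_turns_away_from_escape(self, current, escape, alpha, expected):
        assert border_turn(current, escape, alpha) == pytest.approx(expected)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            border_turn(0.0, 10.0, 0.0)


class TestStep:
    def test_displacement_bound_random_model(self, disc_pattern):
        rng = np.random.default_rng(3)
        params = SimParams()
        colony = init_colony(disc_pattern, 6, 0.5, params, rng)
        model = ModelSpec.from_number(1)
        for _ in range(20):
            before = colony.positions()
            step(colony, model, params, rng)
            moved = np.hypot(*(colony.positions() - before).T)
            assert np.all(moved <= 10.0 + 1e-9)  # T- default speed for all cells

    def test_pushed_cell_moves_away_from_neighbour(self, disc_pattern):
        """A T+ cell with one neighbour due east and no noise moves due west."""
        params = SimParams(
            tplus=SimParams().tplus.__class__(
                v=100.0, persistence_time=105.0, sensing_radius=50.0, sigma=0.0,
                force_sign="push",
            ),
        )
        colony = Colony(
            disc_pattern,
            ids=[0, 1],
            types=[TPLUS, TMINUS],
            xs=[0.0, 10.0],
            ys=[0.0, 0.0],
            headings=[0.0, 0.0],
            repoll=[0, 1],  # T+ re-polls immediately
        )
        rng = np.random.default_rng(0)
        step(colony, ModelSpec.from_number(7), params, rng)
        assert colony.xs[0] < -10.0  # moved west
        assert colony.ys[0] == pytest.approx(0.0, abs=1e-9)

    def test_contracts_inside_and_separated(self, ellipse_pattern):
        rng = np.random.default_rng(9)
        params = SimParams()
        model = ModelSpec.from_number(16)
        colony = init_colony(ellipse_pattern, 6, 0.5, params, rng)
        for _ in range(30):
            step(colony, model, params, rng)
            pos = colony.positions()
            for i in range(6):
                assert contains(ellipse_pattern, pos[i, 0], pos[i, 1], 0.0)
                for j in range(i + 1, 6):
                    assert np.hypot(*(pos[i] - pos[j])) >= 2.0 - 1e-9


class TestRunModel:
    def test_reproducible_trajectories(self, disc_pattern):
        params = SimParams(n_steps=30)
        a = run_model(ModelSpec.from_number(7), params, disc_pattern, 3,
                      np.random.default_rng(11))
        b = run_model(ModelSpec.from_number(7), params, disc_pattern, 3,
                      np.random.default_rng(11))
        for ca, cb in zip(a, b):
            assert ca.xs == cb.xs and ca.ys == cb.ys

    def test_returns_final_snapshots(self, disc_pattern, rng):
        params = SimParams(n_steps=10)
        finals = run_model(ModelSpec.from_number(1), params, disc_pattern, 4, rng)
        assert len(finals) == 4
        assert all(c.n_cells == 6 and c.timestamp == 10 for c in finals)

    def test_emergent_edge_preference_of_pushed_cells(self, disc_pattern):
        """Neighbour-driven motility (model 7) sends T+ cells to the disc rim."""
        radii = {}
        for mn in (1, 7):
            rng = np.random.default_rng(123)
            finals = run_model(ModelSpec.from_number(mn), SimParams(), disc_pattern,
                               50, rng)
            rs = [
                math.hypot(c.xs[i], c.ys[i])
                for c in finals
                for i in range(c.n_cells)
                if c.types[i] == TPLUS
            ]
            radii[mn] = np.mean(rs)
        assert radii[7] > radii[1]


class TestNeighborFraction:
    def test_pair_examples(self):
        assert neighbor_fraction(np.array([[0.0, 0.0], [1.0, 0.0]]), 2.0) == 1.0
        assert neighbor_fraction(np.array([[0.0, 0.0], [5.0, 0.0]]), 2.0) == 0.0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(-50, 50, size=(200, 2))
        r = 8.0
        d = np.hypot(pts[:, 0][:, None] - pts[:, 0], pts[:, 1][:, None] - pts[:, 1])
        np.fill_diagonal(d, np.inf)
        expected = np.mean((d <= r).any(axis=1))
        assert neighbor_fraction(pts, r) == pytest.approx(expected)
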