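"""Division law, plane orientation policies, and pixel-level mitosis."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from epipotts import (
    SimulationParameters,
    choose_division_plane,
    divide_cell,
    division_probability,
    generate_fixture,
    initialize_simulation,
    proliferation_sweep,
    recount_cell_statistics,
)


class TestDivisionProbability:
    def test_half_saturation_point(self, default_params):
        # gamma*sqrt(A0) = 2*15 = 30 adhesion pixels -> exactly P_max/2
        assert division_probability(30, default_params) == pytest.approx(0.05)

    def test_detached_cell_never_divides(self, default_params):
        assert division_probability(0, default_params) == 0.0

    def test_strongly_adhered_cell(self, default_params):
        # n_s = 60 = 2x half-saturation with k=10: P = 0.1 * 2^10/(2^10+1)
        expected = 0.1 * 2**10 / (2**10 + 1)
        assert division_probability(60, default_params) == pytest.approx(expected)
        assert division_probability(60, default_params) == pytest.approx(0.0999, abs=1e-4)

    def test_monotone_and_saturating(self, default_params):
        probs = [division_probability(n, default_params) for n in range(0, 200)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[-1] <= default_params.P_max
        assert division_probability(10_000, default_params) == pytest.approx(0.1, rel=1e-6)


class TestChooseDivisionPlane:
    def test_fixed_modes(self, default_params):
        state = initialize_simulation(default_params)
        cell = state.cells[1]
        rng = np.random.default_rng(0)
        assert choose_division_plane(cell, state, "vertical", rng) == (1.0, 0.0)
        assert choose_division_plane(cell, state, "horizontal", rng) == (0.0, 1.0)

    def test_major_axis_of_tall_rectangle(self):
        # 3 wide x 7 tall: major axis is z, so the normal is (0, +-1)
        from conftest import make_state

        labels = np.zeros((12, 12), dtype=np.int32)
        labels[2:9, 4:7] = 1
        state = make_state(labels)
        cell = state.cells[1]
        n_x, n_z = choose_division_plane(cell, state, "major_axis", np.random.default_rng(0))
        assert abs(n_x) == pytest.approx(0.0, abs=1e-12)
        assert abs(n_z) == pytest.approx(1.0)

    def test_major_axis_square_degenerates_to_random(self):
        from conftest import make_state

        labels = np.zeros((12, 12), dtype=np.int32)
        labels[2:7, 3:8] = 1
        state = make_state(labels)
        cell = state.cells[1]
        angles = set()
        rng = np.random.default_rng(1)
        for _ in range(10):
            n_x, n_z = choose_division_plane(cell, state, "major_axis", rng)
            angles.add(round(math.atan2(n_z, n_x), 6))
        assert len(angles) > 1  # no deterministic axis for a square

    def test_random_mode_uniform_angles(self, default_params):
        state = initialize_simulation(default_params)
        cell = state.cells[1]
        rng = np.random.default_rng(2024)
        angles = []
        for _ in range(10_000):
            n_x, n_z = choose_division_plane(cell, state, "random", rng)
            angles.append(math.atan2(n_z, n_x) % math.pi)
        stat = kstest(np.array(angles) / math.pi, "uniform")
        assert stat.pvalue > 0.01


class TestDivideCell:
    def test_square_vertical_split(self, default_params):
        state = initialize_simulation(default_params)
        event = divide_cell(state, 1, (1.0, 0.0))
        assert event is not None
        assert sorted(event.daughter_areas) == [105, 120]
        assert sum(event.daughter_areas) == event.mother_area == 225
        # daughters side by side: disjoint x-ranges
        a, b = event.daughter_ids
        ca, cb = state.cells[a], state.cells[b]
        assert ca.x_max < cb.x_min or cb.x_max < ca.x_min

    def test_square_horizontal_split_symmetric(self, default_params):
        state = initialize_simulation(default_params)
        event = divide_cell(state, 1, (0.0, 1.0))
        assert sorted(event.daughter_areas) == [105, 120]
        a, b = event.daughter_ids
        ca, cb = state.cells[a], state.cells[b]
        assert ca.z_max < cb.z_min or cb.z_max < ca.z_min

    def test_domino_split(self):
        state = generate_fixture("domino")
        event = divide_cell(state, 1, (1.0, 0.0))
        assert event.daughter_areas == (1, 1)

    def test_single_pixel_cell_cannot_divide(self):
        from conftest import make_state

        labels = np.zeros((8, 8), dtype=np.int32)
        labels[3, 3] = 1
        state = make_state(labels)
        before = state.labels.copy()
        assert divide_cell(state, 1, (1.0, 0.0)) is None
        assert np.array_equal(state.labels, before)

    def test_pixel_conservation_random_blobs(self):
        """Daughter pixel sets partition the mother's set exactly, for random
        blobs and random plane normals; caches stay recount-exact."""
        from conftest import random_toy_state

        rng = np.random.default_rng(31)
        for trial in range(30):
            state = random_toy_state(rng, n_cells=1)
            zs, xs = state.cell_pixels(1)
            mother = set(zip(zs.tolist(), xs.tolist()))
            if len(mother) < 2:
                continue
            theta = rng.uniform(0, math.pi)
            event = divide_cell(state, 1, (math.cos(theta), math.sin(theta)))
            if event is None:
                continue
            a, b = event.daughter_ids
            za, xa = state.cell_pixels(a)
            zb, xb = state.cell_pixels(b)
            pa = set(zip(za.tolist(), xa.tolist()))
            pb = set(zip(zb.tolist(), xb.tolist()))
            assert pa | pb == mother
            assert not (pa & pb)
            cached = state.area[: state.next_id].copy()
            perims = state.perimeter[: state.next_id].copy()
            recount_cell_statistics(state)
            assert np.array_equal(cached, state.area[: state.next_id])
            assert np.array_equal(perims, state.perimeter[: state.next_id])


class TestProliferationSweep:
    def test_no_eligible_cells_no_events(self, default_params):
        state = initialize_simulation(default_params.replace(A0=226))
        # cell area is 225 < A0: never eligible
        events = proliferation_sweep(state, np.random.default_rng(0), state.params)
        assert events == []

    def test_disabled_mode_skips_sweep(self, default_params):
        p = default_params.replace(division_mode="disabled")
        state = initialize_simulation(p)
        assert proliferation_sweep(state, np.random.default_rng(0), p) == []

    def test_division_frequency_matches_hill(self, default_params):
        """One eligible cell with n_s = 30 divides in a fraction P_max/2 of
        sweeps (state reset each time), within 3 binomial SE."""
        p = default_params.replace(
            lattice_width=80, lattice_height=50, substrate_width=60,
            A0=225, division_mode="vertical",
        )
        base = initialize_simulation(p)
        # reshape the cell to a 30-pixel footprint (area stays 225)
        base.labels[base.labels == 1] = 0
        base.labels[4:9, 10:40] = 1   # 30 wide, 5 tall = 150
        base.labels[9:12, 10:35] = 1  # 25 wide, 3 tall = 75 -> area 225
        recount_cell_statistics(base)
        assert base.cells[1].n_s == 30
        assert base.cells[1].area == 225
        n = 4000
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(n):
            trial = base.copy()
            hits += bool(proliferation_sweep(trial, rng, p))
        p_expect = 0.05
        se = math.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(hits / n - p_expect) < 3 * se
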