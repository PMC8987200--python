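"""Energy functional: closed-form cases and the incremental-vs-full oracle."""

import numpy as np
import pytest

from epipotts import (
    MEDIUM,
    SUBSTRATE,
    WALL,
    SimulationParameters,
    delta_energy,
    initialize_simulation,
    metropolis_probability,
    total_energy,
)
from epipotts.energy import apply_copy

from conftest import make_state, random_toy_state


def _legal_proposals(state):
    """All (source, target) pairs a copy attempt could legally propose."""
    H, W = state.labels.shape
    out = []
    for z in range(H):
        for x in range(W):
            for dz, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                z2, x2 = z + dz, x + dx
                if not (0 <= z2 < H and 0 <= x2 < W):
                    continue
                s, t = int(state.labels[z, x]), int(state.labels[z2, x2])
                if s != t and s not in (WALL, SUBSTRATE) and t not in (WALL, SUBSTRATE):
                    out.append(((z, x), (z2, x2)))
    return out


class TestTotalEnergy:
    def test_isolated_square_cell(self):
        # 15x15 cell surrounded by medium: area term 0, L = 60, no adhesion
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:17, 2:17] = 1
        state = make_state(labels, A0=225, lambda_area=1.0, lambda_cont=3.0,
                           perimeter_neighborhood_order=1)
        eb = total_energy(state)
        assert eb.area_term == 0.0
        assert eb.contractility_term == 3 * 60**2 == 10800.0
        assert eb.adhesion_term == 0.0
        assert eb.total == 10800.0

    def test_empty_lattice(self):
        state = make_state(np.zeros((6, 6), dtype=np.int32))
        assert total_energy(state).total == 0.0

    def test_two_touching_single_pixel_cells(self):
        # order-1 everywhere: each cell contributes L^2 = 16; one cc link
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[3, 2] = 1
        labels[3, 3] = 2
        state = make_state(
            labels, A0=1, lambda_area=1.0, lambda_cont=1.0,
            lambda_adh_cc=-2.0, lambda_adh_cs=0.0,
            contact_neighborhood_order=1, perimeter_neighborhood_order=1,
        )
        eb = total_energy(state)
        assert eb.area_term == 0.0
        assert eb.contractility_term == 32.0
        assert eb.adhesion_term == -2.0
        assert eb.total == 30.0

    def test_zero_adhesion_decouples_cells(self):
        rng = np.random.default_rng(7)
        state = random_toy_state(rng, n_cells=3,
                                 lambda_adh_cc=0.0, lambda_adh_cs=0.0)
        combined = total_energy(state).total
        isolated = 0.0
        for cid in state.live_cell_ids():
            solo = state.labels.copy()
            solo[(solo > 0) & (solo != cid)] = MEDIUM
            isolated += total_energy(make_state(
                solo, A0=9, lambda_adh_cc=0.0, lambda_adh_cs=0.0)).total
        assert combined == pytest.approx(isolated, rel=1e-12)


class TestDeltaEnergy:
    @pytest.mark.parametrize("contact_order,perim_order", [(1, 1), (2, 1), (2, 2), (4, 1)])
    def test_matches_full_recompute(self, contact_order, perim_order):
        """Incremental dE equals total_energy(after) - total_energy(before)
        exactly, over randomized states, proposals and parameter signs."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            state = random_toy_state(
                rng, n_cells=int(rng.integers(1, 5)),
                lambda_area=float(rng.choice([0.0, 1.0, 70.0])),
                lambda_cont=float(rng.choice([0.0, 1.0, 3.0])),
                lambda_adh_cc=float(rng.choice([0.0, -2.0, -150.0])),
                lambda_adh_cs=float(rng.choice([0.0, -3.0, -300.0])),
                contact_neighborhood_order=contact_order,
                perimeter_neighborhood_order=perim_order,
            )
            proposals = _legal_proposals(state)
            if not proposals:
                continue
            for idx in rng.choice(len(proposals), size=min(20, len(proposals)), replace=False):
                src, tgt = proposals[idx]
                dE = delta_energy(state, src, tgt)
                before = total_energy(state).total
                trial = state.copy()
                apply_copy(trial, src, tgt)
                after = total_energy(trial).total
                assert dE == pytest.approx(after - before, abs=1e-9)
                checked += 1

    def test_reverse_move_antisymmetry(self):
        rng = np.random.default_rng(3)
        state = random_toy_state(rng, n_cells=2)
        for src, tgt in _legal_proposals(state)[:50]:
            dE_fwd = delta_energy(state, src, tgt)
            trial = state.copy()
            apply_copy(trial, src, tgt)
            # reversing requires a same-side neighbor still carrying the old label
            s_old = int(state.labels[tgt])
            zs, xs = np.nonzero(trial.labels == s_old)
            rev_src = None
            for z, x in zip(zs, xs):
                if abs(z - tgt[0]) + abs(x - tgt[1]) == 1:
                    rev_src = (int(z), int(x))
                    break
            if rev_src is None:
                continue
            dE_rev = delta_energy(trial, rev_src, tgt)
            assert dE_rev == pytest.approx(-dE_fwd, abs=1e-9)

    def test_cell_death_removes_area_and_perimeter_terms(self):
        # medium swallowing a 1-pixel cell removes its (A-A0)^2 and L^2 terms
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[3, 3] = 1
        state = make_state(labels, A0=9, lambda_area=2.0, lambda_cont=3.0,
                           contact_neighborhood_order=1,
                           perimeter_neighborhood_order=1)
        dE = delta_energy(state, (3, 2), (3, 3))  # medium source
        expected = -(2.0 * (1 - 9) ** 2 + 3.0 * 4**2)
        assert dE == expected
        trial = state.copy()
        apply_copy(trial, (3, 2), (3, 3))
        assert total_energy(trial).total == 0.0

    def test_same_label_proposal_rejected(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        state = make_state(labels)
        with pytest.raises(ValueError):
            delta_energy(state, (2, 2), (2, 3))


class TestMetropolis:
    def test_probability_form(self):
        assert metropolis_probability(-5.0, 50.0) == 1.0
        assert metropolis_probability(0.0, 50.0) == 1.0
        assert metropolis_probability(50.0, 50.0) == pytest.approx(np.exp(-1.0))

    def test_energy_is_state_function_over_cycles(self):
        """Accumulated dE over any closed cycle of applied copies is zero."""
        rng = np.random.default_rng(11)
        state = random_toy_state(rng, n_cells=2)
        start_labels = state.labels.copy()
        e_start = total_energy(state).total
        acc = 0.0
        for _ in range(400):
            proposals = _legal_proposals(state)
            if not proposals:
                return  # every cell died; the cycle cannot be closed
            src, tgt = proposals[int(rng.integers(len(proposals)))]
            acc += delta_energy(state, src, tgt)
            apply_copy(state, src, tgt)
            if np.array_equal(state.labels, start_labels):
                break
        # force-close the cycle by restoring pixels that differ
        diff = np.argwhere(state.labels != start_labels)
        for z, x in diff:
            old = int(start_labels[z, x])
            zs, xs = np.nonzero(state.labels == old)
            src = None
            for zz, xx in zip(zs, xs):
                if abs(zz - z) + abs(xx - x) == 1:
                    src = (int(zz), int(xx))
                    break
            if src is None:
                return  # cycle cannot be closed by single copies; skip silently
            acc += delta_energy(state, src, (int(z), int(x)))
            apply_copy(state, src, (int(z), int(x)))
        if np.array_equal(state.labels, start_labels):
            assert acc == pytest.approx(total_energy(state).total - e_start, abs=1e-9)
            assert acc == pytest.approx(0.0, abs=1e-9)
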