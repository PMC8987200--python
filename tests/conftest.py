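import numpy as np
import pytest

from epipotts import (
    MEDIUM,
    SUBSTRATE,
    WALL,
    LatticeState,
    SimulationParameters,
    initialize_simulation,
)


@pytest.fixture
def default_params():
    return SimulationParameters()


@pytest.fixture
def toy_params():
    """Small lattice with simple integer energies, order-1 everywhere."""
    return SimulationParameters(
        lattice_width=22,
        lattice_height=22,
        substrate_width=16,
        A0=9,
        lambda_area=1.0,
        lambda_cont=1.0,
        lambda_adh_cc=-2.0,
        lambda_adh_cs=-3.0,
        contact_neighborhood_order=1,
        perimeter_neighborhood_order=1,
        division_mode="disabled",
        max_mcs=10,
    )


def make_state(labels, **param_overrides):
    """LatticeState from a raw label array; lattice size inferred."""
    labels = np.asarray(labels, dtype=np.int32)
    H, W = labels.shape
    defaults = dict(
        lattice_width=W,
        lattice_height=H,
        substrate_width=min(W, 4),
        A0=4,
        division_mode="disabled",
    )
    defaults.update(param_overrides)
    params = SimulationParameters(**defaults)
    return LatticeState(labels, params)


def assert_equilibrium_matches_grid(eq, ref, step):
    """Continuous minimizer vs exhaustive grid search.

    Passes when the two argmins agree within one grid step per coordinate,
    or when the continuous minimum is at least as deep as every grid point
    (the grid overestimates the true minimum by its discretization error, so
    in flat valleys its argmin wanders while the energies tie; a continuous
    result no worse than the whole grid certifies the same global basin)."""
    coord_ok = abs(eq.l_star - ref.l_star) <= step + 1e-9 and \
        abs(eq.h_star - ref.h_star) <= step + 1e-9
    scale = abs(ref.energy) + 1.0
    at_least_as_deep = eq.energy <= ref.energy + 1e-9 * scale
    assert coord_ok or at_least_as_deep, (eq, ref)


def random_toy_state(rng, size=20, n_cells=3, **overrides):
    """Randomized small state: wall ring, substrate strip, blobby cells.

    Cells are random connected-ish blobs grown from seeds; medium elsewhere.
    """
    H = W = size
    labels = np.full((H, W), MEDIUM, dtype=np.int32)
    labels[0, :] = WALL
    labels[-1, :] = WALL
    labels[:, 0] = WALL
    labels[:, -1] = WALL
    labels[1:3, 2 : W - 2] = SUBSTRATE
    for cid in range(1, n_cells + 1):
        z = int(rng.integers(3, H - 4))
        x = int(rng.integers(2, W - 3))
        sites = [(z, x)]
        for _ in range(int(rng.integers(3, 12))):
            zz, xx = sites[int(rng.integers(len(sites)))]
            dz, dx = [(0, 1), (0, -1), (1, 0), (-1, 0)][int(rng.integers(4))]
            z2, x2 = zz + dz, xx + dx
            if 3 <= z2 < H - 1 and 1 <= x2 < W - 1:
                sites.append((z2, x2))
        for zz, xx in sites:
            labels[zz, xx] = cid
    defaults = dict(
        lattice_width=W,
        lattice_height=H,
        substrate_width=W - 4,
        A0=9,
        division_mode="disabled",
    )
    defaults.update(overrides)
    return LatticeState(labels, SimulationParameters(**defaults))
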