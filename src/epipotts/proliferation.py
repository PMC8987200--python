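"""Cell division: Hill eligibility law, plane orientation, pixel-level mitosis.

A cell becomes a division candidate once its area reaches the target A0.
The division probability per Monte Carlo step is a Hill function of the
cell's substrate-adhesion pixel count n_s,

    P_div = P_max * n_s^k / (n_s^k + (gamma * sqrt(A0))^k),

zero for cells not touching the substrate, so proliferation can only occur
on the substrate.  Mitosis splits the mother's pixel set by a plane through
its centroid with a prescribed unit normal; the daughters then regrow to A0
through the ordinary Potts dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import SimulationParameters
from .state import CellRecord, LatticeState, recount_cell_statistics

_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class DivisionEvent:
    mcs: int
    mother_id: int
    daughter_ids: tuple[int, int]
    normal: tuple[float, float]  # (n_x, n_z), unit vector
    mother_area: int
    daughter_areas: tuple[int, int]
    mother_n_s: int


def division_probability(cell: CellRecord | int, params: SimulationParameters) -> float:
    """Hill division probability per MCS given the cell's adhesion-site count.

    Accepts a CellRecord or a raw n_s count.  Area eligibility (A >= A0) is
    the caller's responsibility.
    """
    n_s = cell.n_s if isinstance(cell, CellRecord) else int(cell)
    if n_s <= 0:
        return 0.0
    # P_max / (1 + (K/n_s)^k) is the overflow-safe form of the Hill ratio
    K = params.hill_halfsat
    return params.P_max / (1.0 + (K / n_s) ** params.k)


def choose_division_plane(
    cell: CellRecord,
    state: LatticeState,
    mode: str,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Unit normal (n_x, n_z) of the mitotic plane under the orientation policy.

    vertical    -> (1, 0): plane normal along x, daughters side by side.
    horizontal  -> (0, 1): plane normal along z, daughters stacked.
    random      -> normal at a uniform angle in [0, pi).
    major_axis  -> normal along the principal eigenvector of the pixel-position
                   covariance, so daughters separate along the cell's long axis
                   (tall cells stack their daughters, the route to extrusion).
    """
    if mode == "vertical":
        return (1.0, 0.0)
    if mode == "horizontal":
        return (0.0, 1.0)
    if mode == "random":
        theta = rng.uniform(0.0, math.pi)
        return (math.cos(theta), math.sin(theta))
    if mode == "major_axis":
        zs, xs = state.cell_pixels(cell.id)
        if xs.size < 2:
            theta = rng.uniform(0.0, math.pi)
            return (math.cos(theta), math.sin(theta))
        cov = np.cov(np.vstack([xs, zs]).astype(float))
        evals, evecs = np.linalg.eigh(cov)
        spread = max(evals[-1], _DEGENERATE_RTOL)
        if (evals[-1] - evals[0]) / spread < _DEGENERATE_RTOL:
            # isotropic second moments (e.g. a square): no preferred axis
            theta = rng.uniform(0.0, math.pi)
            return (math.cos(theta), math.sin(theta))
        major = evecs[:, -1]  # (x, z) components of the long axis
        return (float(major[0]), float(major[1]))
    raise ValueError(f"unknown division mode {mode!r}")


def divide_cell(
    state: LatticeState,
    cell_id: int,
    normal: tuple[float, float],
) -> DivisionEvent | None:
    """Split the cell by the plane through its centroid with the given normal.

    Pixels with negative signed distance stay with the mother id; the other
    side becomes a fresh id (the fresh id takes the side with larger mean x,
    mean z as tiebreak).  Pixels lying exactly on the plane are assigned as a
    block to the side currently holding fewer pixels, keeping the daughter
    areas as close to A0/2 as the geometry allows.  Returns None (state
    untouched) if one side would be empty.
    """
    zs, xs = state.cell_pixels(cell_id)
    n_pix = xs.size
    if n_pix < 2:
        return None
    n_x, n_z = normal
    norm = math.hypot(n_x, n_z)
    if norm == 0:
        raise ValueError("division plane normal must be nonzero")
    n_x, n_z = n_x / norm, n_z / norm

    cx = state.sum_x[cell_id] / state.area[cell_id]
    cz = state.sum_z[cell_id] / state.area[cell_id]
    dist = (xs - cx) * n_x + (zs - cz) * n_z
    tol = 1e-9 * max(1.0, float(np.abs(dist).max()))
    neg = dist < -tol
    pos = dist > tol
    tie = ~(neg | pos)
    if tie.any():
        if neg.sum() <= pos.sum():
            neg |= tie
        else:
            pos |= tie
    if not neg.any() or not pos.any():
        return None

    # fresh id goes to the side with larger mean x (mean z breaks ties)
    key_neg = (xs[neg].mean(), zs[neg].mean())
    key_pos = (xs[pos].mean(), zs[pos].mean())
    new_side = pos if key_pos >= key_neg else neg

    new_id = state.allocate_cell_id()
    state.labels[zs[new_side], xs[new_side]] = new_id
    _recount_pair(state, cell_id, new_id)

    a_mother = int(state.area[cell_id])
    a_daughter = int(state.area[new_id])
    return DivisionEvent(
        mcs=state.mcs_clock,
        mother_id=cell_id,
        daughter_ids=(cell_id, new_id),
        normal=(n_x, n_z),
        mother_area=n_pix,
        daughter_areas=(a_mother, a_daughter),
        mother_n_s=int(state.n_s[cell_id] + state.n_s[new_id]),
    )


def _recount_pair(state: LatticeState, id_a: int, id_b: int) -> None:
    """Rebuild caches of the two ids touched by a division (local recount)."""
    from .constants import neighborhood

    labels = state.labels
    H, W = labels.shape
    offsets = neighborhood(state.params.perimeter_neighborhood_order)
    for cid in (id_a, id_b):
        zs, xs = np.nonzero(labels == cid)
        state.area[cid] = zs.size
        state.sum_x[cid] = int(xs.sum())
        state.sum_z[cid] = int(zs.sum())
        state.n_s[cid] = int(np.count_nonzero(state.substrate_adjacent[zs, xs]))
        links = 0
        for dz, dx in offsets:
            z = zs + dz
            x = xs + dx
            valid = (z >= 0) & (z < H) & (x >= 0) & (x < W)
            links += int(np.count_nonzero(labels[z[valid], x[valid]] != cid))
        state.perimeter[cid] = links


def proliferation_sweep(
    state: LatticeState,
    rng: np.random.Generator,
    params: SimulationParameters,
) -> list[DivisionEvent]:
    """One per-MCS division pass: each cell with A >= A0 divides with P_div.

    Cells are visited in randomized order; at most one division per cell per
    sweep.  Daughters created during the sweep are not revisited (their area
    is ~A0/2, below threshold anyway).
    """
    if params.division_mode == "disabled":
        return []
    events: list[DivisionEvent] = []
    ids = state.live_cell_ids()
    if ids.size == 0:
        return events
    order = rng.permutation(ids)
    cells = None
    for cid in order:
        cid = int(cid)
        if state.area[cid] < params.A0:
            continue
        p = division_probability(int(state.n_s[cid]), params)
        if p <= 0.0 or rng.random() >= p:
            continue
        if cells is None:
            cells = state.cells
        record = cells.get(cid)
        if record is None or record.area != state.area[cid]:
            # stale record (earlier division in this sweep): rebuild just this one
            record = state.cells[cid]
        normal = choose_division_plane(record, state, params.division_mode, rng)
        event = divide_cell(state, cid, normal)
        if event is not None:
            events.append(event)
            cells = None  # invalidate records after a division
    return events
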