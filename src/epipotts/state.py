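"""Lattice state: compartment label grid plus per-cell cached statistics.

The grid partitions every site into exactly one compartment: MEDIUM (0),
SUBSTRATE (-1), WALL (-2) or a cell (positive id).  Per-cell statistics
(area, boundary links, substrate-adhesion pixels, centroid sums) are cached
incrementally by the dynamics and can always be rebuilt from the raw grid
with :func:`recount_cell_statistics`, which serves as the exactness oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import MEDIUM, SUBSTRATE, WALL, neighborhood
from .params import SimulationParameters


class GeometryError(ValueError):
    """Raised when the requested lattice geometry cannot be constructed."""


@dataclass
class CellRecord:
    """Snapshot of one cell's cached statistics.

    ``boundary_links`` is the number of neighbor pairs (under the perimeter
    neighborhood order, face links by default) joining this cell to any other
    compartment; ``n_s`` is the number of the cell's pixels with at least one
    face-adjacent substrate pixel (its adhesion-site count).
    """

    id: int
    area: int
    boundary_links: int
    n_s: int
    centroid: tuple[float, float]  # (x_bar, z_bar) in pixel units
    x_min: int
    x_max: int
    z_min: int
    z_max: int

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.z_max - self.z_min + 1


class LatticeState:
    """Label grid (``labels[z, x]``, z=0 at the bottom) plus cell caches.

    The cache arrays are indexed by cell id and sized to ``capacity``; a cell
    is alive iff ``1 <= id < next_id`` and ``area[id] > 0``.
    """

    def __init__(self, labels: np.ndarray, params: SimulationParameters, mcs_clock: int = 0):
        labels = np.ascontiguousarray(labels, dtype=np.int32)
        if labels.shape != (params.lattice_height, params.lattice_width):
            raise GeometryError(
                f"label grid shape {labels.shape} does not match lattice "
                f"{params.lattice_height} x {params.lattice_width}"
            )
        self.labels = labels
        self.params = params
        self.mcs_clock = int(mcs_clock)
        max_label = int(labels.max(initial=0))
        self.next_id = max_label + 1
        cap = max(16, 2 * self.next_id)
        self.area = np.zeros(cap, dtype=np.int64)
        self.perimeter = np.zeros(cap, dtype=np.int64)
        self.n_s = np.zeros(cap, dtype=np.int64)
        self.sum_x = np.zeros(cap, dtype=np.int64)
        self.sum_z = np.zeros(cap, dtype=np.int64)
        # substrate is frozen, so substrate adjacency of every site is static
        self.substrate_adjacent = _face_adjacent_to(labels, SUBSTRATE)
        recount_cell_statistics(self)

    # -- bookkeeping --------------------------------------------------------

    @property
    def capacity(self) -> int:
        return self.area.shape[0]

    def ensure_capacity(self, n_ids: int) -> None:
        if n_ids <= self.capacity:
            return
        new_cap = max(n_ids, 2 * self.capacity)
        for name in ("area", "perimeter", "n_s", "sum_x", "sum_z"):
            old = getattr(self, name)
            grown = np.zeros(new_cap, dtype=old.dtype)
            grown[: old.shape[0]] = old
            setattr(self, name, grown)

    def allocate_cell_id(self) -> int:
        cid = self.next_id
        self.next_id += 1
        self.ensure_capacity(self.next_id)
        return cid

    def live_cell_ids(self) -> np.ndarray:
        ids = np.arange(1, self.next_id)
        return ids[self.area[1 : self.next_id] > 0]

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.area[1 : self.next_id] > 0))

    @property
    def cells(self) -> dict[int, CellRecord]:
        """CellRecord per live cell; bounding extents are scanned on demand."""
        out: dict[int, CellRecord] = {}
        for cid in self.live_cell_ids():
            cid = int(cid)
            zs, xs = np.nonzero(self.labels == cid)
            a = int(self.area[cid])
            out[cid] = CellRecord(
                id=cid,
                area=a,
                boundary_links=int(self.perimeter[cid]),
                n_s=int(self.n_s[cid]),
                centroid=(self.sum_x[cid] / a, self.sum_z[cid] / a),
                x_min=int(xs.min()),
                x_max=int(xs.max()),
                z_min=int(zs.min()),
                z_max=int(zs.max()),
            )
        return out

    def cell_pixels(self, cell_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(z, x) index arrays of the cell's pixels."""
        return np.nonzero(self.labels == cell_id)

    def copy(self) -> "LatticeState":
        dup = LatticeState.__new__(LatticeState)
        dup.labels = self.labels.copy()
        dup.params = self.params
        dup.mcs_clock = self.mcs_clock
        dup.next_id = self.next_id
        for name in ("area", "perimeter", "n_s", "sum_x", "sum_z"):
            setattr(dup, name, getattr(self, name).copy())
        dup.substrate_adjacent = self.substrate_adjacent
        return dup

    # -- substrate geometry -------------------------------------------------

    @property
    def substrate_top_row(self) -> int:
        """z index of the highest substrate row (cells rest at z = this + 1)."""
        rows = np.nonzero((self.labels == SUBSTRATE).any(axis=1))[0]
        if rows.size == 0:
            raise GeometryError("state has no substrate")
        return int(rows.max())

    def substrate_top_columns(self) -> np.ndarray:
        """x indices of the top substrate row."""
        top = self.substrate_top_row
        return np.nonzero(self.labels[top] == SUBSTRATE)[0]


def _face_adjacent_to(labels: np.ndarray, code: int) -> np.ndarray:
    """Boolean grid: site has at least one face neighbor with the given label."""
    target = labels == code
    adj = np.zeros_like(target)
    adj[1:, :] |= target[:-1, :]
    adj[:-1, :] |= target[1:, :]
    adj[:, 1:] |= target[:, :-1]
    adj[:, :-1] |= target[:, 1:]
    return adj


def initialize_simulation(params: SimulationParameters) -> LatticeState:
    """Build the standard starting geometry.

    A one-site wall ring frames the lattice; a frozen substrate strip
    (``substrate_width`` wide, ``substrate_thickness`` tall, horizontally
    centered) rests on the bottom wall; one square cell of side
    ``round(sqrt(A0))`` sits on the substrate, horizontally centered;
    everything else is medium.
    """
    params.validate()
    W, H = params.lattice_width, params.lattice_height
    if W < 3 or H < 3:
        raise GeometryError("lattice too small for a wall ring")
    if params.substrate_width > W - 2:
        raise GeometryError(
            f"substrate width {params.substrate_width} exceeds interior width {W - 2}"
        )
    side = int(round(np.sqrt(params.A0)))
    if side > params.substrate_width:
        raise GeometryError(
            f"initial cell side {side} exceeds substrate width {params.substrate_width}"
        )
    z0 = 1 + params.substrate_thickness  # first row above the substrate
    if z0 + side > H - 1:
        raise GeometryError("initial cell does not fit below the top wall")

    labels = np.full((H, W), MEDIUM, dtype=np.int32)
    labels[0, :] = WALL
    labels[-1, :] = WALL
    labels[:, 0] = WALL
    labels[:, -1] = WALL

    sx0 = (W - params.substrate_width) // 2
    labels[1:z0, sx0 : sx0 + params.substrate_width] = SUBSTRATE

    cx0 = (W - side) // 2
    labels[z0 : z0 + side, cx0 : cx0 + side] = 1

    return LatticeState(labels, params)


def recount_cell_statistics(state: LatticeState) -> LatticeState:
    """Recompute every cached per-cell statistic from the raw grid (the oracle).

    Boundary links are counted under the configured perimeter neighborhood
    order; only links between two in-lattice sites exist.
    """
    labels = state.labels
    n = state.next_id
    cells = labels > 0
    flat = np.where(cells, labels, 0).ravel()

    state.area[:] = 0
    state.area[:n] = np.bincount(flat, minlength=n)[:n]

    zz, xx = np.indices(labels.shape)
    state.sum_x[:] = 0
    state.sum_z[:] = 0
    state.sum_x[:n] = np.bincount(flat, weights=xx.ravel(), minlength=n)[:n].astype(np.int64)
    state.sum_z[:n] = np.bincount(flat, weights=zz.ravel(), minlength=n)[:n].astype(np.int64)
    # index 0 collected every non-cell site; MEDIUM carries no statistics
    state.area[0] = state.sum_x[0] = state.sum_z[0] = 0

    state.perimeter[:] = 0
    offsets = neighborhood(state.params.perimeter_neighborhood_order, half=True)
    for dz, dx in offsets:
        a, b = _shift_pair(labels, dz, dx)
        mismatch = a != b
        for side_lab in (a, b):
            sel = mismatch & (side_lab > 0)
            if sel.any():
                state.perimeter[:n] += np.bincount(side_lab[sel], minlength=n)[:n]

    state.n_s[:] = 0
    sel = state.substrate_adjacent & cells
    if sel.any():
        state.n_s[:n] = np.bincount(labels[sel], minlength=n)[:n]
    return state


def _shift_pair(labels: np.ndarray, dz: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a, b) where b is a's neighbor at offset (dz, dx)."""
    H, W = labels.shape
    z0a, z1a = max(0, -dz), min(H, H - dz)
    x0a, x1a = max(0, -dx), min(W, W - dx)
    a = labels[z0a:z1a, x0a:x1a]
    b = labels[z0a + dz : z1a + dz, x0a + dx : x1a + dx]
    return a, b


# -- snapshot I/O -----------------------------------------------------------


def save_snapshot(state: LatticeState, path: str | Path) -> None:
    """Write a plain-text snapshot: '#'-prefixed JSON header, then the grid.

    The grid is written bottom row first (row index = z).  Reserved codes:
    MEDIUM=0, SUBSTRATE=-1, WALL=-2, cells >= 1.
    """
    path = Path(path)
    header = json.dumps({"mcs": state.mcs_clock, "params": state.params.to_dict()})
    with path.open("w") as fh:
        fh.write("# " + header + "\n")
        np.savetxt(fh, state.labels, fmt="%d")


def load_snapshot(path: str | Path) -> LatticeState:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing snapshot header line")
        meta = json.loads(first.lstrip("# "))
        labels = np.loadtxt(fh, dtype=np.int32, ndmin=2)
    params = SimulationParameters.from_dict(meta["params"])
    return LatticeState(labels, params, mcs_clock=meta["mcs"])


def render_snapshot(state: LatticeState, path: str | Path) -> None:
    """Export a PNG with one color per compartment (cells cycled over a map)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = state.labels
    img = np.zeros(labels.shape + (3,), dtype=float)
    img[labels == MEDIUM] = (0.08, 0.08, 0.08)
    img[labels == WALL] = (0.25, 0.25, 0.25)
    img[labels == SUBSTRATE] = (0.20, 0.35, 0.80)
    cmap = plt.get_cmap("tab20")
    for cid in np.unique(labels[labels > 0]):
        img[labels == cid] = cmap(int(cid) % 20)[:3]
    fig, ax = plt.subplots(figsize=(6, 6 * labels.shape[0] / labels.shape[1]))
    ax.imshow(img, origin="lower", interpolation="nearest")
    ax.set_xlabel("x (pixels)")
    ax.set_ylabel("z (pixels)")
    ax.set_title(f"MCS {state.mcs_clock}, {state.n_cells} cells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
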