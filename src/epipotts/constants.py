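"""Reserved compartment labels and neighborhood offset tables.

The lattice is indexed ``labels[z, x]`` with ``z = 0`` the bottom row
(substrate side) and ``x`` running along the substrate.  Cells carry
positive integer labels; the three frozen / passive compartments use the
reserved codes below.
"""

from __future__ import annotations

import numpy as np

MEDIUM = 0
SUBSTRATE = -1
WALL = -2

#: face (von Neumann) neighborhood, order 1
OFFSETS_ORDER1 = ((0, 1), (0, -1), (1, 0), (-1, 0))
#: Moore neighborhood, order 2
OFFSETS_ORDER2 = OFFSETS_ORDER1 + ((1, 1), (1, -1), (-1, 1), (-1, -1))
#: order 3 adds the distance-2 straight neighbors
OFFSETS_ORDER3 = OFFSETS_ORDER2 + ((0, 2), (0, -2), (2, 0), (-2, 0))
#: order 4 adds the distance-sqrt(5) knight neighbors
OFFSETS_ORDER4 = OFFSETS_ORDER3 + (
    (1, 2), (1, -2), (-1, 2), (-1, -2),
    (2, 1), (2, -1), (-2, 1), (-2, -1),
)

_FULL = {1: OFFSETS_ORDER1, 2: OFFSETS_ORDER2, 3: OFFSETS_ORDER3, 4: OFFSETS_ORDER4}
#: half-plane versions: each unordered neighbor pair visited exactly once
_HALF = {
    order: tuple(o for o in offs if o > (0, 0))
    for order, offs in _FULL.items()
}


def neighborhood(order: int, half: bool = False) -> tuple[tuple[int, int], ...]:
    """Return (dz, dx) offsets of the requested neighborhood order (1-4)."""
    table = _HALF if half else _FULL
    try:
        return table[order]
    except KeyError:
        raise ValueError(f"unsupported neighborhood order {order!r} (use 1-4)") from None


def offsets_as_arrays(offsets) -> tuple[np.ndarray, np.ndarray]:
    """Split an offset tuple into int64 (dz, dx) arrays for the numba kernel."""
    dz = np.array([o[0] for o in offsets], dtype=np.int64)
    dx = np.array([o[1] for o in offsets], dtype=np.int64)
    return dz, dx
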