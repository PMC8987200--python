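"""Potts energy functional and the exact incremental change for a pixel copy.

The energy of a configuration is

    E = lambda_area * sum_cells (A_sigma - A0)^2
      + lambda_cont * sum_cells L_sigma^2
      + sum_pairs J(sigma_i, sigma_j) * [sigma_i != sigma_j]

where the last sum runs over unordered neighbor pairs within the contact
neighborhood (order 2 by default), J = lambda_adh_cc for a cell-cell pair,
lambda_adh_cs for a cell-substrate pair, and 0 whenever either site is
medium or wall.  Medium, substrate and wall contribute no area or
contractility terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import MEDIUM, SUBSTRATE, WALL, neighborhood
from .params import SimulationParameters
from .state import LatticeState, _shift_pair


@dataclass(frozen=True)
class EnergyBreakdown:
    area_term: float
    contractility_term: float
    adhesion_term: float

    @property
    def total(self) -> float:
        return self.area_term + self.contractility_term + self.adhesion_term


def total_energy(state: LatticeState, params: SimulationParameters | None = None) -> EnergyBreakdown:
    """Energy of the full configuration, computed directly from the grid.

    Deliberately independent of the incremental caches so it can serve as
    the recomputation oracle for :func:`delta_energy`.
    """
    if params is None:
        params = state.params
    labels = state.labels
    cells = labels > 0
    n = int(labels.max(initial=0)) + 1
    flat = np.where(cells, labels, 0).ravel()
    areas = np.bincount(flat, minlength=n)
    areas[0] = 0

    perim = np.zeros(n, dtype=np.int64)
    for dz, dx in neighborhood(params.perimeter_neighborhood_order, half=True):
        a, b = _shift_pair(labels, dz, dx)
        mismatch = a != b
        for side_lab in (a, b):
            sel = mismatch & (side_lab > 0)
            if sel.any():
                perim += np.bincount(side_lab[sel], minlength=n)

    live = areas > 0
    area_term = params.lambda_area * float(np.sum((areas[live] - params.A0) ** 2))
    cont_term = params.lambda_cont * float(np.sum(perim[live].astype(np.float64) ** 2))

    adh = 0.0
    for dz, dx in neighborhood(params.contact_neighborhood_order, half=True):
        a, b = _shift_pair(labels, dz, dx)
        diff = a != b
        cc = diff & (a > 0) & (b > 0)
        cs = ((a > 0) & (b == SUBSTRATE)) | ((b > 0) & (a == SUBSTRATE))
        adh += params.lambda_adh_cc * int(cc.sum()) + params.lambda_adh_cs * int(cs.sum())

    return EnergyBreakdown(area_term, cont_term, adh)


def _J(a: int, b: int, params: SimulationParameters) -> float:
    """Boundary energy of one unlike neighbor pair (0 if medium/wall involved)."""
    if a > 0 and b > 0:
        return params.lambda_adh_cc
    if (a > 0 and b == SUBSTRATE) or (b > 0 and a == SUBSTRATE):
        return params.lambda_adh_cs
    return 0.0


def delta_energy(
    state: LatticeState,
    source_site: tuple[int, int],
    target_site: tuple[int, int],
    params: SimulationParameters | None = None,
) -> float:
    """Energy change if the source label were copied onto the target site.

    Touches only the terms of the two affected compartments and the local
    neighbor links; does not mutate the state.  The source and target must
    carry different labels and the target must not be frozen (wall/substrate).
    """
    if params is None:
        params = state.params
    labels = state.labels
    H, W = labels.shape
    zi, xi = source_site
    zj, xj = target_site
    s = int(labels[zi, xi])
    t = int(labels[zj, xj])
    if s == t:
        raise ValueError("source and target carry the same label")
    if t in (WALL, SUBSTRATE) or s in (WALL, SUBSTRATE):
        raise ValueError("frozen compartments cannot take part in a copy")

    lam_a, lam_c = params.lambda_area, params.lambda_cont
    A0 = params.A0
    dE = 0.0

    # area terms: a cell shrinking to zero pixels ceases to exist, removing
    # its (A - A0)^2 contribution entirely rather than leaving (0 - A0)^2
    if s > 0:
        A = int(state.area[s])
        dE += lam_a * (((A + 1) - A0) ** 2 - (A - A0) ** 2)
    if t > 0:
        A = int(state.area[t])
        after = ((A - 1) - A0) ** 2 if A > 1 else 0
        dE += lam_a * (after - (A - A0) ** 2)

    # contractility: only links incident to the target site change
    c_s = c_t = n_valid = 0
    for dz, dx in neighborhood(params.perimeter_neighborhood_order):
        z, x = zj + dz, xj + dx
        if not (0 <= z < H and 0 <= x < W):
            continue
        n_valid += 1
        lab = int(labels[z, x])
        if lab == s:
            c_s += 1
        elif lab == t:
            c_t += 1
    if s > 0:
        L = int(state.perimeter[s])
        dL = n_valid - 2 * c_s
        dE += lam_c * ((L + dL) ** 2 - L**2)
    if t > 0:
        L = int(state.perimeter[t])
        dL = -(n_valid - 2 * c_t)
        dE += lam_c * ((L + dL) ** 2 - L**2)

    # adhesion: J of every contact link incident to the target site
    for dz, dx in neighborhood(params.contact_neighborhood_order):
        z, x = zj + dz, xj + dx
        if not (0 <= z < H and 0 <= x < W):
            continue
        lab = int(labels[z, x])
        if lab != s:
            dE += _J(s, lab, params)
        if lab != t:
            dE -= _J(t, lab, params)
    return dE


def apply_copy(state: LatticeState, source_site: tuple[int, int], target_site: tuple[int, int]) -> None:
    """Copy the source label onto the target site, updating caches incrementally."""
    labels = state.labels
    H, W = labels.shape
    zj, xj = target_site
    s = int(labels[source_site])
    t = int(labels[zj, xj])
    params = state.params

    c_s = c_t = n_valid = 0
    for dz, dx in neighborhood(params.perimeter_neighborhood_order):
        z, x = zj + dz, xj + dx
        if not (0 <= z < H and 0 <= x < W):
            continue
        n_valid += 1
        lab = int(labels[z, x])
        if lab == s:
            c_s += 1
        elif lab == t:
            c_t += 1

    labels[zj, xj] = s
    on_substrate = bool(state.substrate_adjacent[zj, xj])
    if s > 0:
        state.area[s] += 1
        state.perimeter[s] += n_valid - 2 * c_s
        state.sum_x[s] += xj
        state.sum_z[s] += zj
        if on_substrate:
            state.n_s[s] += 1
    if t > 0:
        state.area[t] -= 1
        state.perimeter[t] -= n_valid - 2 * c_t
        state.sum_x[t] -= xj
        state.sum_z[t] -= zj
        if on_substrate:
            state.n_s[t] -= 1


def metropolis_probability(dE: float, T: float) -> float:
    """Acceptance probability of the Metropolis rule: 1 if dE <= 0, else e^(-dE/T)."""
    if dE <= 0:
        return 1.0
    return math.exp(-dE / T)


def metropolis_accept(dE: float, T: float, rng: np.random.Generator) -> bool:
    """Draw the accept/reject decision for an elementary step."""
    if dE <= 0:
        return True
    return rng.random() < math.exp(-dE / T)
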