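"""Numba-compiled inner loop: one Monte Carlo step of elementary copy attempts.

Mirrors :func:`epipotts.energy.delta_energy` exactly (the pytest suite checks
the two against each other through cache-coherence and energy bookkeeping
invariants); all cache updates are incremental.  Labels: MEDIUM=0,
SUBSTRATE=-1, WALL=-2, cells positive.

Randomness comes from an inline xorshift64* generator seeded per call via a
splitmix64 scramble of the 31-bit seed the caller draws from the run's
Generator, keeping whole trajectories a pure function of the run seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SUBSTRATE = -1
_WALL = -2

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _next_u64(s):
    # xorshift64*
    s ^= s >> _U64(12)
    s ^= (s << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> _U64(27)
    return s, (s * _U64(2685821657736338717)) & _U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def run_mcs_kernel(
    labels,            # int32 (H, W), mutated
    sub_adj,           # bool (H, W), static substrate face-adjacency
    area, perim, ns, sum_x, sum_z,   # int64 per-id caches, mutated
    lam_area, lam_cont, lam_cc, lam_cs, A0, T,
    perim_dz, perim_dx,              # perimeter neighborhood offsets
    cont_dz, cont_dx,                # contact (J) neighborhood offsets
    n_attempts, seed,
):
    """Run ``n_attempts`` elementary steps; returns step statistics.

    Returns (attempted, rejected_same_label, rejected_frozen, accepted,
    accumulated energy change).
    """
    # splitmix64 scramble so that consecutive small seeds give unrelated streams
    s = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    s = (s ^ (s >> _U64(30))) * _U64(0xBF58476D1CE4E5B9) & _U64(0xFFFFFFFFFFFFFFFF)
    s = (s ^ (s >> _U64(27))) * _U64(0x94D049BB133111EB) & _U64(0xFFFFFFFFFFFFFFFF)
    s = s ^ (s >> _U64(31))
    if s == _U64(0):
        s = _U64(0x9E3779B97F4A7C15)

    H, W = labels.shape
    n_perim = perim_dz.shape[0]
    n_cont = cont_dz.shape[0]
    face_dz = np.array((0, 0, 1, -1), dtype=np.int64)
    face_dx = np.array((1, -1, 0, 0), dtype=np.int64)
    n_choices = _U64(H * W * 4)

    rejected_same = 0
    rejected_frozen = 0
    accepted = 0
    e_delta = 0.0

    for _ in range(n_attempts):
        # one draw encodes (site, face direction); each remains uniform
        s, v = _next_u64(s)
        r = np.int64(((v >> _U64(32)) * n_choices) >> _U64(32))
        d = r & 3
        site = r >> 2
        zi = site // W
        xi = site - zi * W
        zj = zi + face_dz[d]
        xj = xi + face_dx[d]
        if zj < 0 or zj >= H or xj < 0 or xj >= W:
            rejected_frozen += 1
            continue
        lab_s = labels[zi, xi]
        lab_t = labels[zj, xj]
        if lab_s == lab_t:
            rejected_same += 1
            continue
        if lab_s == _WALL or lab_s == _SUBSTRATE or lab_t == _WALL or lab_t == _SUBSTRATE:
            rejected_frozen += 1
            continue

        dE = 0.0
        # area terms (cell death removes the whole (A - A0)^2 contribution)
        if lab_s > 0:
            A = area[lab_s]
            dE += lam_area * (((A + 1) - A0) ** 2 - (A - A0) ** 2)
        if lab_t > 0:
            A = area[lab_t]
            if A > 1:
                dE += lam_area * (((A - 1) - A0) ** 2 - (A - A0) ** 2)
            else:
                dE -= lam_area * (A - A0) ** 2

        # contractility: links incident to the target site
        c_s = 0
        c_t = 0
        n_valid = 0
        for m in range(n_perim):
            z = zj + perim_dz[m]
            x = xj + perim_dx[m]
            if z < 0 or z >= H or x < 0 or x >= W:
                continue
            n_valid += 1
            lab = labels[z, x]
            if lab == lab_s:
                c_s += 1
            elif lab == lab_t:
                c_t += 1
        if lab_s > 0:
            L = perim[lab_s]
            dL = n_valid - 2 * c_s
            dE += lam_cont * ((L + dL) ** 2 - L**2)
        if lab_t > 0:
            L = perim[lab_t]
            dL = -(n_valid - 2 * c_t)
            dE += lam_cont * ((L + dL) ** 2 - L**2)

        # adhesion: J over contact links incident to the target site
        for m in range(n_cont):
            z = zj + cont_dz[m]
            x = xj + cont_dx[m]
            if z < 0 or z >= H or x < 0 or x >= W:
                continue
            lab = labels[z, x]
            if lab != lab_s:
                if lab_s > 0 and lab > 0:
                    dE += lam_cc
                elif (lab_s > 0 and lab == _SUBSTRATE) or (lab > 0 and lab_s == _SUBSTRATE):
                    dE += lam_cs
            if lab != lab_t:
                if lab_t > 0 and lab > 0:
                    dE -= lam_cc
                elif (lab_t > 0 and lab == _SUBSTRATE) or (lab > 0 and lab_t == _SUBSTRATE):
                    dE -= lam_cs

        accept = dE <= 0.0
        if not accept:
            s, v = _next_u64(s)
            u = np.float64(v >> _U64(11)) * _INV53
            accept = u < np.exp(-dE / T)
        if accept:
            labels[zj, xj] = lab_s
            if lab_s > 0:
                area[lab_s] += 1
                perim[lab_s] += n_valid - 2 * c_s
                sum_x[lab_s] += xj
                sum_z[lab_s] += zj
                if sub_adj[zj, xj]:
                    ns[lab_s] += 1
            if lab_t > 0:
                area[lab_t] -= 1
                perim[lab_t] -= n_valid - 2 * c_t
                sum_x[lab_t] -= xj
                sum_z[lab_t] -= zj
                if sub_adj[zj, xj]:
                    ns[lab_t] -= 1
            accepted += 1
            e_delta += dE

    return n_attempts, rejected_same, rejected_frozen, accepted, e_delta
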