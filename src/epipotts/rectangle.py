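"""Closed-form single-cell analysis for an idealized rectangular cell.

For a lone rectangular cell of length l (along the substrate) and height h,
the Potts energy reduces to

    E(l, h) = lambda_area * (l*h - A0)^2
            + lambda_cont * (2l + 2h)^2
            + lambda_adh_cs * l,

since the cell-substrate boundary has length l and every other boundary
faces medium (J = 0).  Its stationary points solve

    dE/dl = 2*lambda_area*h*(l*h - A0) + 8*lambda_cont*(l + h) + lambda_adh_cs = 0
    dE/dh = 2*lambda_area*l*(l*h - A0) + 8*lambda_cont*(l + h)                 = 0,

and the global minimizer (l*, h*) predicts the equilibrium cell shape:
aspect ratio h*/l* < 1 is squamous (flat), ~1 cuboidal, > 1 columnar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import SimulationParameters


@dataclass(frozen=True)
class RectEquilibrium:
    l_star: float
    h_star: float
    energy: float
    on_boundary: bool = False

    @property
    def aspect_ratio(self) -> float:
        return self.h_star / self.l_star

    @property
    def area(self) -> float:
        return self.l_star * self.h_star


def rect_energy(l, h, params: SimulationParameters):
    """Rectangular-cell energy; accepts scalars or numpy arrays (l, h > 0)."""
    l = np.asarray(l, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(l <= 0) or np.any(h <= 0):
        raise ValueError("cell dimensions must be positive")
    E = (
        params.lambda_area * (l * h - params.A0) ** 2
        + params.lambda_cont * (2 * l + 2 * h) ** 2
        + params.lambda_adh_cs * l
    )
    return float(E) if E.ndim == 0 else E


def rect_stationarity_residual(l: float, h: float, params: SimulationParameters) -> tuple[float, float]:
    """The two stationarity left-hand sides (dE/dl, dE/dh) at (l, h)."""
    common = 8.0 * params.lambda_cont * (l + h)
    r_l = 2.0 * params.lambda_area * h * (l * h - params.A0) + common + params.lambda_adh_cs
    r_h = 2.0 * params.lambda_area * l * (l * h - params.A0) + common
    return (r_l, r_h)


def rect_equilibrium(
    params: SimulationParameters,
    search_box: tuple[float, float] | None = None,
    coarse_n: int = 80,
    n_starts: int = 5,
) -> RectEquilibrium:
    """Global minimizer of the rectangular-cell energy over the search box.

    Multi-start local descent (L-BFGS-B) seeded from the best points of a
    coarse grid; the default box is (0, 4*sqrt(A0)] in each coordinate.  A
    minimizer within one part in 1e-6 of the box edge is flagged
    ``on_boundary``.
    """
    if params.lambda_area <= 0 and params.lambda_cont <= 0:
        raise ValueError("energy is unbounded below without area or contractility terms")
    lo, hi = search_box if search_box is not None else (1e-6, 4.0 * math.sqrt(params.A0))
    if not 0 < lo < hi:
        raise ValueError("search box must satisfy 0 < lo < hi")

    grid = np.linspace(lo, hi, coarse_n)
    L, H = np.meshgrid(grid, grid, indexing="ij")
    E = rect_energy(L, H, params)
    order = np.argsort(E, axis=None)[:n_starts]
    starts = [(float(L.flat[i]), float(H.flat[i])) for i in order]

    def fun(v):
        l, h = v
        return (
            params.lambda_area * (l * h - params.A0) ** 2
            + params.lambda_cont * (2 * l + 2 * h) ** 2
            + params.lambda_adh_cs * l
        )

    def jac(v):
        return np.array(rect_stationarity_residual(v[0], v[1], params))

    best = None
    for start in starts:
        res = minimize(fun, np.array(start), jac=jac, method="L-BFGS-B",
                       bounds=[(lo, hi), (lo, hi)])
        if best is None or res.fun < best.fun:
            best = res
    l_star, h_star = float(best.x[0]), float(best.x[1])
    edge_tol = 1e-6 * (hi - lo)
    on_boundary = any(
        min(v - lo, hi - v) <= edge_tol for v in (l_star, h_star)
    )
    return RectEquilibrium(l_star, h_star, float(best.fun), on_boundary)


def brute_force_equilibrium(
    params: SimulationParameters,
    search_box: tuple[float, float] | None = None,
    step: float = 0.01,
    chunk: int = 256,
) -> RectEquilibrium:
    """Exhaustive grid search at fixed step (the certification oracle).

    Evaluates the energy at every grid point of the box, chunked over l to
    bound memory.  Intended for tests; O((box/step)^2) work.
    """
    lo, hi = search_box if search_box is not None else (step, 4.0 * math.sqrt(params.A0))
    axis = np.arange(lo, hi + step / 2, step)
    best_val = math.inf
    best_lh = (axis[0], axis[0])
    h_row = axis[np.newaxis, :]
    for i0 in range(0, axis.size, chunk):
        l_col = axis[i0 : i0 + chunk, np.newaxis]
        E = (
            params.lambda_area * (l_col * h_row - params.A0) ** 2
            + params.lambda_cont * (2 * l_col + 2 * h_row) ** 2
            + params.lambda_adh_cs * l_col
        )
        idx = np.argmin(E)
        val = E.flat[idx]
        if val < best_val:
            best_val = float(val)
            i, j = np.unravel_index(idx, E.shape)
            best_lh = (float(l_col[i, 0]), float(axis[j]))
    return RectEquilibrium(best_lh[0], best_lh[1], best_val)


def analytic_phase_surface(
    lambda_cont_values: Iterable[float],
    lambda_adh_cs_values: Iterable[float],
    lambda_area_values: Iterable[float] = (1.0,),
    base: SimulationParameters | None = None,
) -> pd.DataFrame:
    """Equilibrium aspect ratio and area over a parameter grid (one row each)."""
    if base is None:
        base = SimulationParameters()
    rows = []
    for lam_a, lam_c, lam_cs in product(
        lambda_area_values, lambda_cont_values, lambda_adh_cs_values
    ):
        p = base.replace(lambda_area=lam_a, lambda_cont=lam_c, lambda_adh_cs=lam_cs)
        eq = rect_equilibrium(p)
        rows.append(
            {
                "lambda_area": lam_a,
                "lambda_cont": lam_c,
                "lambda_adh_cs": lam_cs,
                "l_star": eq.l_star,
                "h_star": eq.h_star,
                "aspect_ratio": eq.aspect_ratio,
                "area": eq.area,
                "energy": eq.energy,
                "on_boundary": eq.on_boundary,
            }
        )
    return pd.DataFrame(rows)
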