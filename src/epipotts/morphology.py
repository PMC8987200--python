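"""Snapshot and trajectory quantification: shape metrics, basal/suprabasal
partition, confluence, and the categorical collective-structure label.

A cell is *basal* when it has at least one substrate-adhesion pixel
(n_s > 0) and *suprabasal* otherwise; extrusion moves a cell from basal to
suprabasal, and a re-adhering cell simply counts basal again.  The
collective label distinguishes non-confluent groups (division stalls before
the substrate is covered), self-arresting monolayers of squamous, cuboidal
or columnar cells, and multilayers whose suprabasal population keeps
growing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .state import LatticeState


@dataclass(frozen=True)
class MorphologyReport:
    mcs: int
    n_cells: int
    n_basal: int
    n_suprabasal: int
    coverage: float           # covered substrate-top pixels / substrate width
    mean_area: float
    sd_area: float
    mean_height: float
    sd_height: float
    mean_width: float
    sd_width: float
    mean_aspect: float        # per-cell h/w, averaged
    sd_aspect: float
    mean_basal_n_s: float
    layer_height: int         # max cell z minus substrate top


@dataclass(frozen=True)
class StructureLabel:
    label: str                # one of LABELS
    metrics: dict = field(default_factory=dict)

    LABELS = (
        "non_confluent",
        "monolayer_squamous",
        "monolayer_cuboidal",
        "monolayer_columnar",
        "multilayer",
        "multilayer_slow",
        "inconclusive",
    )


@dataclass(frozen=True)
class ClassifyThresholds:
    """Knobs of the categorical classifier.

    ``aspect_band`` is the half-width delta of the cuboidal aspect-ratio band
    (squamous < 1 - delta, columnar > 1 + delta); ``coverage_confluent`` is
    the coverage fraction counted as confluent (below 1 because thermal
    fluctuations transiently expose single substrate pixels even in a
    fully formed layer); ``suprabasal_tolerance``
    allows transient extrusions in a monolayer; ``ceased_window`` is the
    number of trailing MCS that must be division-free for proliferation to
    count as self-arrested; ``slow_rate_fraction`` marks a multilayer as
    slow-growing when its cell-count growth rate falls below this fraction
    of ``reference_rate`` (if one is supplied, e.g. the fastest corner of a
    sweep).
    """

    aspect_band: float = 0.25
    coverage_confluent: float = 0.95
    suprabasal_tolerance: int = 1
    ceased_window: int = 500
    slow_rate_fraction: float = 0.2
    tail_fraction: float = 0.25


def measure_snapshot(state: LatticeState) -> MorphologyReport:
    """Per-cell shape metrics and the basal/suprabasal partition of one state.

    Heights and widths are bounding extents (z_max - z_min + 1 etc.), robust
    on pixelated shapes.
    """
    cells = state.cells
    sub_top = state.substrate_top_row
    sub_cols = state.substrate_top_columns()
    if sub_cols.size:
        above = state.labels[sub_top + 1, sub_cols]
        coverage = float(np.count_nonzero(above > 0)) / sub_cols.size
    else:
        coverage = 0.0

    if not cells:
        return MorphologyReport(
            mcs=state.mcs_clock, n_cells=0, n_basal=0, n_suprabasal=0,
            coverage=coverage, mean_area=math.nan, sd_area=math.nan,
            mean_height=math.nan, sd_height=math.nan, mean_width=math.nan,
            sd_width=math.nan, mean_aspect=math.nan, sd_aspect=math.nan,
            mean_basal_n_s=math.nan, layer_height=0,
        )

    areas = np.array([c.area for c in cells.values()], dtype=float)
    heights = np.array([c.height for c in cells.values()], dtype=float)
    widths = np.array([c.width for c in cells.values()], dtype=float)
    aspects = heights / widths
    basal = np.array([c.n_s > 0 for c in cells.values()])
    n_basal = int(basal.sum())
    basal_ns = np.array([c.n_s for c in cells.values()], dtype=float)[basal]
    z_top = max(c.z_max for c in cells.values())

    def _sd(v):
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    return MorphologyReport(
        mcs=state.mcs_clock,
        n_cells=len(cells),
        n_basal=n_basal,
        n_suprabasal=len(cells) - n_basal,
        coverage=coverage,
        mean_area=float(areas.mean()), sd_area=_sd(areas),
        mean_height=float(heights.mean()), sd_height=_sd(heights),
        mean_width=float(widths.mean()), sd_width=_sd(widths),
        mean_aspect=float(aspects.mean()), sd_aspect=_sd(aspects),
        mean_basal_n_s=float(basal_ns.mean()) if n_basal else 0.0,
        layer_height=int(z_top - sub_top),
    )


def measure_trajectory(traj: Trajectory) -> list[MorphologyReport]:
    """One MorphologyReport per stored snapshot."""
    return [measure_snapshot(state) for _, state in traj.snapshot_states()]


def classify_trajectory(
    reports: Sequence[MorphologyReport],
    division_mcs: Sequence[int] = (),
    thresholds: ClassifyThresholds | None = None,
    final_mcs: int | None = None,
    reference_rate: float | None = None,
) -> StructureLabel:
    """Categorical collective-structure label of a finished run.

    ``division_mcs`` are the MCS indices of all division events; the run is
    self-arrested when none fall in the trailing ``ceased_window`` MCS.
    The label is a pure function of its inputs.
    """
    th = thresholds or ClassifyThresholds()
    if not reports:
        return StructureLabel("inconclusive", {"reason": "empty trajectory"})
    last = reports[-1]
    if final_mcs is None:
        final_mcs = last.mcs
    if last.n_cells == 0:
        return StructureLabel("inconclusive", {"reason": "no cells in final snapshot"})
    if final_mcs < th.ceased_window:
        return StructureLabel("inconclusive", {"reason": "trajectory shorter than the arrest window"})

    ceased = not any(m > final_mcs - th.ceased_window for m in division_mcs)
    tail = reports[max(1, int(len(reports) * (1 - th.tail_fraction))) :] or [last]
    coverage = float(np.mean([r.coverage for r in tail]))
    suprabasal = float(np.mean([r.n_suprabasal for r in tail]))
    aspect = float(np.mean([r.mean_aspect for r in tail]))
    metrics = {
        "coverage": coverage,
        "mean_suprabasal": suprabasal,
        "mean_aspect": aspect,
        "divisions_ceased": ceased,
        "n_divisions": len(division_mcs),
    }

    # persistent suprabasal growth = multilayer, regardless of confluence
    supra_series = [r.n_suprabasal for r in reports]
    growing = (
        last.n_suprabasal > th.suprabasal_tolerance
        and supra_series[-1] >= max(supra_series) - th.suprabasal_tolerance
        and not ceased
    )
    if growing:
        label = "multilayer"
        if reference_rate is not None:
            rate = _cell_count_rate(reports, th.tail_fraction)
            metrics["growth_rate"] = rate
            if rate < th.slow_rate_fraction * reference_rate:
                label = "multilayer_slow"
        return StructureLabel(label, metrics)

    if ceased:
        if coverage < th.coverage_confluent:
            return StructureLabel("non_confluent", metrics)
        if suprabasal <= th.suprabasal_tolerance:
            if aspect < 1.0 - th.aspect_band:
                return StructureLabel("monolayer_squamous", metrics)
            if aspect > 1.0 + th.aspect_band:
                return StructureLabel("monolayer_columnar", metrics)
            return StructureLabel("monolayer_cuboidal", metrics)
        return StructureLabel("multilayer", metrics)  # arrested but stratified

    return StructureLabel("inconclusive", metrics)


def _cell_count_rate(reports: Sequence[MorphologyReport], tail_fraction: float) -> float:
    """Cell-count growth rate (cells / MCS) over the trailing fraction of a run."""
    tail = reports[max(0, int(len(reports) * (1 - tail_fraction))) :]
    if len(tail) < 2 or tail[-1].mcs == tail[0].mcs:
        return 0.0
    return (tail[-1].n_cells - tail[0].n_cells) / (tail[-1].mcs - tail[0].mcs)


def basal_dynamics(traj: Trajectory) -> pd.DataFrame:
    """Time series of the basal-layer observables (one row per snapshot).

    Columns: mcs, n_basal, n_suprabasal, mean/SD basal area, mean/SD basal
    n_s, and the n_s of every cell that divided at that MCS (joined as a
    comma string; empty when none).
    """
    div_ns: dict[int, list[int]] = {}
    for d in traj.divisions:
        div_ns.setdefault(d.mcs, []).append(d.mother_n_s)
    rows = []
    for mcs, state in traj.snapshot_states():
        cells = state.cells.values()
        basal = [c for c in cells if c.n_s > 0]
        areas = np.array([c.area for c in basal], dtype=float)
        ns = np.array([c.n_s for c in basal], dtype=float)
        rows.append(
            {
                "mcs": mcs,
                "n_basal": len(basal),
                "n_suprabasal": len(list(cells)) - len(basal),
                "mean_basal_area": areas.mean() if areas.size else np.nan,
                "sd_basal_area": areas.std(ddof=1) if areas.size > 1 else 0.0,
                "mean_basal_n_s": ns.mean() if ns.size else np.nan,
                "sd_basal_n_s": ns.std(ddof=1) if ns.size > 1 else 0.0,
                "dividing_n_s": ",".join(str(v) for v in div_ns.get(mcs, [])),
            }
        )
    return pd.DataFrame(rows)


def mean_steady_cell_height(
    traj: Trajectory,
    window: int | None = None,
    exclude_edge_cells: int = 1,
) -> float:
    """Mean basal-cell height (pixels) over the trailing steady snapshots.

    Averages, over the last ``window`` snapshots (default: those inside the
    run's steady window), the per-snapshot mean bounding-extent height of
    basal cells, excluding the ``exclude_edge_cells`` outermost cells on each
    side of the layer (border cells abut bare substrate and are
    systematically wider/flatter than layer-interior cells).
    """
    snaps = list(traj.snapshot_states())
    if not snaps:
        raise ValueError("trajectory holds no snapshots")
    if window is None:
        window = max(1, traj.params.steady_window // max(traj.params.snapshot_every, 1))
    snaps = snaps[-window:]
    per_snapshot = []
    for _, state in snaps:
        basal = [c for c in state.cells.values() if c.n_s > 0]
        if len(basal) <= 2 * exclude_edge_cells:
            continue
        basal.sort(key=lambda c: c.centroid[0])
        interior = basal[exclude_edge_cells: len(basal) - exclude_edge_cells]
        per_snapshot.append(float(np.mean([c.height for c in interior])))
    if not per_snapshot:
        raise ValueError(
            "no snapshot in the window has enough basal cells for an interior height"
        )
    return float(np.mean(per_snapshot))
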