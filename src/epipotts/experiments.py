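"""Experiment orchestration: seeded parameter sweeps and test fixtures.

A sweep runs one simulation per point of a cartesian parameter grid times
the number of replicates, derives every per-run seed deterministically from
the base seed and the grid coordinates, classifies each trajectory, and
collects a master table.  Completed runs are skipped on resume.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd

from .constants import MEDIUM, SUBSTRATE, WALL
from .dynamics import Trajectory, run_simulation
from .morphology import (
    ClassifyThresholds,
    classify_trajectory,
    measure_trajectory,
)
from .params import SimulationParameters, reduced_preset
from .state import LatticeState, save_snapshot


@dataclass
class SweepSpec:
    """A cartesian grid of parameter overrides, replicated over seeds.

    ``axes`` maps SimulationParameters field names to value lists; the
    ``alpha`` pseudo-axis sets ``lambda_adh_cc = lambda_adh_cs / alpha``
    after all real fields are applied.
    """

    axes: dict[str, list[Any]]
    replicates: int = 1
    base_seed: int = 0
    base_params: SimulationParameters = field(default_factory=reduced_preset)
    output_root: Path | None = None
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)

    @property
    def n_runs(self) -> int:
        size = 1
        for vals in self.axes.values():
            size *= len(vals)
        return size * self.replicates

    def points(self) -> Iterator[tuple[tuple[int, ...], dict[str, Any]]]:
        names = list(self.axes)
        for idx in itertools.product(*(range(len(self.axes[n])) for n in names)):
            yield idx, {n: self.axes[n][i] for n, i in zip(names, idx)}


def derive_seed(base_seed: int, grid_index: tuple[int, ...], replicate: int) -> int:
    """Deterministic, well-separated per-run seed below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, grid_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def build_run_params(
    spec: SweepSpec, overrides: dict[str, Any], seed: int
) -> SimulationParameters:
    over = dict(overrides)
    alpha = over.pop("alpha", None)
    p = spec.base_params.replace(**over, seed=seed)
    if alpha is not None:
        p = p.replace(lambda_adh_cc=p.lambda_adh_cs / float(alpha))
    return p


def run_one(params: SimulationParameters, thresholds: ClassifyThresholds | None = None) -> dict[str, Any]:
    """Run one simulation and summarise it as a flat result record."""
    traj = run_simulation(params)
    reports = measure_trajectory(traj)
    label = classify_trajectory(
        reports,
        division_mcs=[d.mcs for d in traj.divisions],
        thresholds=thresholds,
        final_mcs=traj.final_state.mcs_clock,
    )
    last = reports[-1]
    return {
        "seed": params.seed,
        "alpha": params.alpha,
        "label": label.label,
        "final_mcs": traj.final_state.mcs_clock,
        "reached_steady": traj.reached_steady,
        "n_cells": last.n_cells,
        "n_basal": last.n_basal,
        "n_suprabasal": last.n_suprabasal,
        "coverage": last.coverage,
        "mean_aspect": last.mean_aspect,
        "n_divisions": len(traj.divisions),
        **{f"metric_{k}": v for k, v in label.metrics.items()},
    }


def run_sweep(spec: SweepSpec, keep_trajectories: bool = False) -> pd.DataFrame:
    """Execute the sweep; returns the master table (one row per run).

    With an ``output_root``, each run gets a directory holding params.json,
    result.json, the final snapshot, and the morphology/division CSVs; a run
    whose result.json already exists is loaded instead of re-run, making an
    interrupted sweep resumable.  Failures are isolated per run (recorded as
    label="error") so the sweep always completes.
    """
    rows = []
    trajectories = {}
    for grid_index, overrides in spec.points():
        for rep in range(spec.replicates):
            seed = derive_seed(spec.base_seed, grid_index, rep)
            params = build_run_params(spec, overrides, seed)
            run_dir = None
            if spec.output_root is not None:
                tag = "_".join(f"{k}={v}" for k, v in overrides.items())
                run_dir = Path(spec.output_root) / f"{tag}_rep{rep}"
                result_file = run_dir / "result.json"
                if result_file.exists():
                    rows.append(json.loads(result_file.read_text()))
                    continue
            try:
                record = {**overrides, "replicate": rep}
                if run_dir is not None:
                    run_dir.mkdir(parents=True, exist_ok=True)
                    params.to_json(run_dir / "params.json")
                traj = run_simulation(params)
                reports = measure_trajectory(traj)
                label = classify_trajectory(
                    reports,
                    division_mcs=[d.mcs for d in traj.divisions],
                    thresholds=spec.thresholds,
                    final_mcs=traj.final_state.mcs_clock,
                )
                last = reports[-1]
                record.update(
                    seed=seed,
                    alpha=params.alpha,
                    label=label.label,
                    final_mcs=traj.final_state.mcs_clock,
                    reached_steady=traj.reached_steady,
                    n_cells=last.n_cells,
                    n_suprabasal=last.n_suprabasal,
                    coverage=last.coverage,
                    mean_aspect=last.mean_aspect,
                    n_divisions=len(traj.divisions),
                )
                if keep_trajectories:
                    trajectories[(grid_index, rep)] = traj
                if run_dir is not None:
                    save_snapshot(traj.final_state, run_dir / "final_snapshot.txt")
                    traj.stats_frame().to_csv(run_dir / "mcs_stats.csv", index=False)
                    traj.divisions_frame().to_csv(run_dir / "divisions.csv", index=False)
                    (run_dir / "result.json").write_text(json.dumps(record))
            except Exception as exc:  # noqa: BLE001 - isolate per-run failures
                record = {**overrides, "replicate": rep, "seed": seed,
                          "label": "error", "error": repr(exc)}
                if run_dir is not None:
                    run_dir.mkdir(parents=True, exist_ok=True)
                    (run_dir / "result.json").write_text(json.dumps(record))
            rows.append(record)
    table = pd.DataFrame(rows)
    if spec.output_root is not None:
        Path(spec.output_root).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(spec.output_root) / "master_table.csv", index=False)
    if keep_trajectories:
        table.attrs["trajectories"] = trajectories
    return table


def adhesion_ratio_height_experiment(
    lambda_cont: float,
    lambda_adh_cs: float,
    seeds: "list[int] | tuple[int, ...]",
    alphas: tuple[float, float] = (2.0, 20.0),
    base_params: SimulationParameters | None = None,
) -> dict[str, float]:
    """Effect of the adhesion ratio alpha on steady monolayer cell height.

    Runs the simulator at the given contractility and cell-substrate adhesion
    with vertical division, once per seed for each alpha (setting
    ``lambda_adh_cc = lambda_adh_cs / alpha``), on the reduced desk-scale
    preset with a fixed MCS budget so both arms are measured at the same
    simulated time.  Interior basal-cell heights are averaged over the
    trailing steady window of each run and over seeds; returns the per-alpha
    mean heights and their ratio (weak cell-cell adhesion, large alpha,
    flattens cells, so the ratio exceeds 1).
    """
    from .morphology import mean_steady_cell_height

    if base_params is None:
        base_params = reduced_preset()
    base_params = base_params.replace(
        lambda_cont=lambda_cont,
        lambda_adh_cs=lambda_adh_cs,
        lambda_area=1.0,
        division_mode="vertical",
        stop_at_steady=False,
    )
    means = []
    for alpha in alphas:
        heights = []
        for seed in seeds:
            p = base_params.replace(
                seed=int(seed), lambda_adh_cc=lambda_adh_cs / alpha
            )
            heights.append(mean_steady_cell_height(run_simulation(p)))
        means.append(float(np.mean(heights)))
    return {
        "alpha_low": alphas[0],
        "alpha_high": alphas[1],
        "height_low_alpha": means[0],
        "height_high_alpha": means[1],
        "ratio": means[0] / means[1],
        "n_seeds": len(seeds),
    }


# -- deterministic unit-test fixtures ---------------------------------------

FIXTURE_NAMES = (
    "single-cell",
    "domino",
    "two-layer-6-cell",
    "L-shaped-cell",
    "pre-confluent-monolayer",
)


def generate_fixture(name: str) -> LatticeState:
    """Small hand-constructed lattices with exactly known metrics.

    single-cell: the standard initial condition on a 60x40 lattice.
    domino: one 2-pixel horizontal cell on the substrate.
    two-layer-6-cell: 4 basal cells in a row plus 2 suprabasal cells stacked
        on top of the middle ones.
    L-shaped-cell: an L of 7-tall stem (2 wide) plus a 4x2 foot; hand counts:
        area 22, boundary links 26, n_s 6.
    pre-confluent-monolayer: five 10x20 cells covering 50 of 56 substrate
        columns.
    """
    if name == "single-cell":
        return _frame(60, 40, substrate_width=56, cells=[_rect(1, 15, 15, 15)],
                      A0=225)
    if name == "domino":
        return _frame(20, 12, substrate_width=16, cells=[_rect(1, 9, 2, 1)], A0=2)
    if name == "two-layer-6-cell":
        cells = [_rect(i + 1, 4 + 6 * i, 6, 6) for i in range(4)]  # basal row
        cells += [_rect(5, 10, 6, 6, z0_extra=6), _rect(6, 16, 6, 6, z0_extra=6)]
        return _frame(32, 24, substrate_width=28, cells=cells, A0=36)
    if name == "L-shaped-cell":
        # stem: 2 wide x 7 tall at x=6..7; foot: extra 4 x 2 at x=8..11, bottom
        cells = [_rect(1, 6, 2, 7), _rect(1, 8, 4, 2)]
        return _frame(24, 16, substrate_width=20, cells=cells, A0=22)
    if name == "pre-confluent-monolayer":
        cells = [_rect(i + 1, 3 + 10 * i, 10, 20) for i in range(5)]
        return _frame(60, 32, substrate_width=56, cells=cells, A0=200)
    raise ValueError(f"unknown fixture {name!r}; catalogue: {FIXTURE_NAMES}")


def _rect(cid: int, x0: int, w: int, h: int, z0_extra: int = 0) -> tuple[int, int, int, int, int]:
    return (cid, x0, w, h, z0_extra)


def _frame(
    W: int,
    H: int,
    substrate_width: int,
    cells: list[tuple[int, int, int, int, int]],
    A0: int,
    substrate_thickness: int = 3,
) -> LatticeState:
    """Wall ring + centered substrate + axis-aligned rectangles resting on it."""
    params = SimulationParameters(
        lattice_width=W, lattice_height=H,
        substrate_width=substrate_width,
        substrate_thickness=substrate_thickness,
        A0=A0, division_mode="disabled", max_mcs=0,
    )
    labels = np.full((H, W), MEDIUM, dtype=np.int32)
    labels[0, :] = WALL
    labels[-1, :] = WALL
    labels[:, 0] = WALL
    labels[:, -1] = WALL
    sx0 = (W - substrate_width) // 2
    z0 = 1 + substrate_thickness
    labels[1:z0, sx0 : sx0 + substrate_width] = SUBSTRATE
    for cid, x0, w, h, z_extra in cells:
        labels[z0 + z_extra : z0 + z_extra + h, x0 : x0 + w] = cid
    return LatticeState(labels, params)
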