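"""Metropolis elementary steps, the Monte Carlo step loop, and full runs.

One Monte Carlo step (MCS) — the model time unit — is n elementary copy
attempts, n being the number of lattice sites.  An elementary step picks a
uniformly random site and a uniformly random face neighbor; if the labels
differ and neither compartment is frozen, the source label is copied onto
the target with the Metropolis probability (1 for dE <= 0, e^(-dE/T) else).
Attempts that pick equal labels or frozen compartments still count toward
the n attempts of the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import neighborhood, offsets_as_arrays
from ._kernel import run_mcs_kernel
from .energy import apply_copy, delta_energy, metropolis_accept, total_energy
from .params import SimulationParameters
from .proliferation import DivisionEvent, proliferation_sweep
from .state import LatticeState, initialize_simulation

_FROZEN = (-1, -2)  # SUBSTRATE, WALL


@dataclass(frozen=True)
class StepStatistics:
    """Bookkeeping for one MCS."""

    mcs: int
    attempted: int
    rejected_same_label: int
    rejected_frozen: int
    accepted: int
    energy_total: float

    @property
    def acceptance_ratio(self) -> float:
        return self.accepted / self.attempted if self.attempted else 0.0


def attempt_copy(
    state: LatticeState,
    rng: np.random.Generator,
    params: SimulationParameters | None = None,
) -> bool:
    """One elementary step in pure Python (reference path; the MCS loop uses
    the compiled kernel).  Returns True iff a copy was accepted and applied."""
    if params is None:
        params = state.params
    H, W = state.labels.shape
    zi = int(rng.integers(H))
    xi = int(rng.integers(W))
    dz, dx = neighborhood(1)[int(rng.integers(4))]
    zj, xj = zi + dz, xi + dx
    if not (0 <= zj < H and 0 <= xj < W):
        return False
    s = int(state.labels[zi, xi])
    t = int(state.labels[zj, xj])
    if s == t or s in _FROZEN or t in _FROZEN:
        return False
    dE = delta_energy(state, (zi, xi), (zj, xj), params)
    if metropolis_accept(dE, params.T, rng):
        apply_copy(state, (zi, xi), (zj, xj))
        return True
    return False


def run_mcs(
    state: LatticeState,
    rng: np.random.Generator,
    params: SimulationParameters | None = None,
    energy_before: float | None = None,
) -> StepStatistics:
    """Execute one MCS (n = width * height attempts) via the compiled kernel.

    The kernel consumes one 31-bit seed drawn from ``rng``, so the whole
    trajectory remains a deterministic function of the run seed.
    """
    if params is None:
        params = state.params
    perim_dz, perim_dx = offsets_as_arrays(neighborhood(params.perimeter_neighborhood_order))
    cont_dz, cont_dx = offsets_as_arrays(neighborhood(params.contact_neighborhood_order))
    seed = int(rng.integers(2**31))
    attempted, same, frozen, accepted, e_delta = run_mcs_kernel(
        state.labels,
        state.substrate_adjacent,
        state.area, state.perimeter, state.n_s, state.sum_x, state.sum_z,
        float(params.lambda_area), float(params.lambda_cont),
        float(params.lambda_adh_cc), float(params.lambda_adh_cs),
        float(params.A0), float(params.T),
        perim_dz, perim_dx, cont_dz, cont_dx,
        params.n_sites, seed,
    )
    state.mcs_clock += 1
    if energy_before is None:
        energy = total_energy(state, params).total
    else:
        energy = energy_before + e_delta
    return StepStatistics(
        mcs=state.mcs_clock,
        attempted=int(attempted),
        rejected_same_label=int(same),
        rejected_frozen=int(frozen),
        accepted=int(accepted),
        energy_total=float(energy),
    )


@dataclass
class Trajectory:
    """Output of a full run: periodic label snapshots plus per-MCS statistics."""

    params: SimulationParameters
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)
    stats: list[StepStatistics] = field(default_factory=list)
    divisions: list[DivisionEvent] = field(default_factory=list)
    final_state: LatticeState | None = None
    reached_steady: bool = False

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mcs": [s.mcs for s in self.stats],
                "attempted": [s.attempted for s in self.stats],
                "accepted": [s.accepted for s in self.stats],
                "rejected_same_label": [s.rejected_same_label for s in self.stats],
                "rejected_frozen": [s.rejected_frozen for s in self.stats],
                "acceptance_ratio": [s.acceptance_ratio for s in self.stats],
                "energy_total": [s.energy_total for s in self.stats],
            }
        )

    def divisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mcs": [d.mcs for d in self.divisions],
                "mother_id": [d.mother_id for d in self.divisions],
                "daughter_a": [d.daughter_ids[0] for d in self.divisions],
                "daughter_b": [d.daughter_ids[1] for d in self.divisions],
                "n_x": [d.normal[0] for d in self.divisions],
                "n_z": [d.normal[1] for d in self.divisions],
                "mother_area": [d.mother_area for d in self.divisions],
                "area_a": [d.daughter_areas[0] for d in self.divisions],
                "area_b": [d.daughter_areas[1] for d in self.divisions],
                "mother_n_s": [d.mother_n_s for d in self.divisions],
            }
        )

    def snapshot_states(self):
        """Yield (mcs, LatticeState) with freshly recounted caches."""
        for mcs, labels in self.snapshots:
            yield mcs, LatticeState(labels, self.params, mcs_clock=mcs)


def _is_steady(
    energies: list[float],
    last_division_mcs: int,
    mcs: int,
    params: SimulationParameters,
) -> bool:
    """Operational steady state: no divisions over the sliding window and the
    mean total energy of the window's two halves agreeing to a relative
    tolerance (drift test rather than range test, to be insensitive to the
    T-driven fluctuation floor)."""
    w = params.steady_window
    if mcs < w or mcs - last_division_mcs < w:
        return False
    window = np.asarray(energies[-w:])
    half = w // 2
    m1 = window[:half].mean()
    m2 = window[half:].mean()
    scale = max(abs(m1), abs(m2), 1.0)
    return abs(m2 - m1) / scale < params.steady_energy_rtol


def run_simulation(params: SimulationParameters) -> Trajectory:
    """Initialize, then alternate MCS and (unless disabled) a division sweep.

    Stops at ``max_mcs`` or, when ``stop_at_steady``, at the first MCS where
    the steady-state criterion fires.  Snapshots (label-grid copies) are
    recorded every ``snapshot_every`` MCS and always at the final MCS.
    """
    state = initialize_simulation(params)
    rng = np.random.default_rng(params.seed)
    traj = Trajectory(params=params)
    traj.snapshots.append((0, state.labels.copy()))

    energy = total_energy(state, params).total
    energies: list[float] = []
    last_division_mcs = 0

    for mcs in range(1, params.max_mcs + 1):
        step = run_mcs(state, rng, params, energy_before=energy)
        energy = step.energy_total
        if params.division_mode != "disabled":
            events = proliferation_sweep(state, rng, params)
            if events:
                traj.divisions.extend(events)
                last_division_mcs = mcs
                energy = total_energy(state, params).total
                step = StepStatistics(
                    mcs=step.mcs,
                    attempted=step.attempted,
                    rejected_same_label=step.rejected_same_label,
                    rejected_frozen=step.rejected_frozen,
                    accepted=step.accepted,
                    energy_total=energy,
                )
        traj.stats.append(step)
        energies.append(energy)

        at_cadence = params.snapshot_every > 0 and mcs % params.snapshot_every == 0
        steady = params.stop_at_steady and _is_steady(energies, last_division_mcs, mcs, params)
        if at_cadence or steady or mcs == params.max_mcs:
            traj.snapshots.append((mcs, state.labels.copy()))
        if steady:
            traj.reached_steady = True
            break

    traj.final_state = state
    return traj
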