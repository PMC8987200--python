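"""Simulation parameters for the epithelial Potts model.

All energies are in model units; lengths and areas are in lattice pixels.
The Monte Carlo temperature ``T`` sets the scale of accepted fluctuations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

DIVISION_MODES = ("vertical", "horizontal", "random", "major_axis", "disabled")


@dataclass
class SimulationParameters:
    """Full parameter set: Potts energies, Hill proliferation, geometry, run control.

    Attributes
    ----------
    lambda_area:
        Compressibility penalty on ``(A_sigma - A0)**2``; >= 0.
    lambda_cont:
        Cortical contractility penalty on the squared boundary-link count
        ``L_sigma**2`` (a cortex spring with zero rest length); >= 0.
    lambda_adh_cc, lambda_adh_cs:
        Cell-cell and cell-substrate boundary energy per neighbor link;
        both <= 0 so that cells favor expanding shared boundaries.
    A0:
        Target cell area in pixels.
    T:
        Potts temperature (Metropolis scaling factor).
    gamma, k, P_max:
        Hill proliferation law ``P_div = P_max * n_s^k / (n_s^k + (gamma*sqrt(A0))^k)``.
    division_mode:
        Orientation policy for the mitotic plane normal: ``vertical`` (normal
        (1,0), daughters side by side), ``horizontal`` (normal (0,1), daughters
        stacked), ``random``, ``major_axis`` (long-axis placement of daughters),
        or ``disabled``.
    contact_neighborhood_order:
        Neighborhood order for the adhesion J-sum (2 = 8-neighborhood default).
    perimeter_neighborhood_order:
        Neighborhood order for the boundary-link count L_sigma (1 = face links,
        making a w x h rectangle's perimeter exactly 2(w+h)).
    """

    lambda_area: float = 1.0
    lambda_cont: float = 3.0
    lambda_adh_cc: float = -150.0
    lambda_adh_cs: float = -300.0
    A0: int = 225
    T: float = 50.0
    gamma: float = 2.0
    k: float = 10.0
    P_max: float = 0.1
    lattice_width: int = 480
    lattice_height: int = 195
    substrate_width: int = 450
    substrate_thickness: int = 3
    division_mode: str = "vertical"
    contact_neighborhood_order: int = 2
    perimeter_neighborhood_order: int = 1
    max_mcs: int = 50_000
    seed: int = 0
    snapshot_every: int = 100
    steady_window: int = 500
    steady_energy_rtol: float = 1e-3
    stop_at_steady: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.lambda_area < 0 or self.lambda_cont < 0:
            raise ValueError("lambda_area and lambda_cont must be >= 0")
        if self.lambda_adh_cc > 0 or self.lambda_adh_cs > 0:
            raise ValueError("adhesion energies lambda_adh_cc/cs must be <= 0")
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not 0.0 <= self.P_max <= 1.0:
            raise ValueError("P_max must lie in [0, 1]")
        if self.division_mode not in DIVISION_MODES:
            raise ValueError(
                f"division_mode {self.division_mode!r} not in {DIVISION_MODES}"
            )
        if self.substrate_width > self.lattice_width:
            raise ValueError("substrate cannot be wider than the lattice")
        if self.contact_neighborhood_order not in (1, 2, 3, 4):
            raise ValueError("contact_neighborhood_order must be in 1..4")
        if self.perimeter_neighborhood_order not in (1, 2, 3, 4):
            raise ValueError("perimeter_neighborhood_order must be in 1..4")
        if self.substrate_thickness < 1:
            raise ValueError("substrate_thickness must be >= 1")
        if self.max_mcs < 0 or self.steady_window < 1:
            raise ValueError("max_mcs must be >= 0 and steady_window >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def alpha(self) -> float:
        """Adhesion ratio alpha = lambda_adh_cs / lambda_adh_cc."""
        if self.lambda_adh_cc == 0:
            return math.inf
        return self.lambda_adh_cs / self.lambda_adh_cc

    @property
    def n_sites(self) -> int:
        """Elementary copy attempts per Monte Carlo step (= lattice sites)."""
        return self.lattice_width * self.lattice_height

    @property
    def hill_halfsat(self) -> float:
        """Half-saturation adhesion-site count gamma * sqrt(A0)."""
        return self.gamma * math.sqrt(self.A0)

    def replace(self, **changes: Any) -> "SimulationParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationParameters":
        """Read parameters from JSON or from a flat ``key = value`` text file."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(parse_flat_config(text))


def parse_flat_config(text: str) -> dict[str, Any]:
    """Parse a flat ``key = value`` config (one field per line, ``#`` comments)."""
    out: dict[str, Any] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        out[key] = _coerce(val)
    return out


def _coerce(val: str) -> Any:
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def reduced_preset(**overrides: Any) -> SimulationParameters:
    """Desk-scale preset: 240x100 lattice, 220-pixel substrate, 10k MCS budget.

    Shape metrics are local, so a narrower domain reproduces the same cell
    morphologies as the production 480x195 lattice at a fraction of the cost.
    """
    base = dict(
        lattice_width=240,
        lattice_height=100,
        substrate_width=220,
        max_mcs=10_000,
        snapshot_every=50,
    )
    base.update(overrides)
    return SimulationParameters(**base)
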