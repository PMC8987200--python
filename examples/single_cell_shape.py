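"""Single-cell morphology: contractility rounds a cell, substrate adhesion
flattens it.

Runs the Potts dynamics with division disabled for two mechanical regimes on
a small lattice and prints the steady cell extents, next to the analytic
rectangular-cell prediction for the same parameters.  The aspect ratio h/w
(< 1 squamous, ~1 cuboidal, > 1 columnar) is the quantity the single-cell
phase diagram is built from.
"""

from epipotts import SimulationParameters, rect_equilibrium, run_simulation

REGIMES = {
    "high contractility, weak adhesion": dict(lambda_cont=7.0, lambda_adh_cs=-100.0),
    "low contractility, strong adhesion": dict(lambda_cont=1.0, lambda_adh_cs=-700.0),
}

for name, lam in REGIMES.items():
    params = SimulationParameters(
        lattice_width=120, lattice_height=60, substrate_width=100,
        division_mode="disabled", max_mcs=2000, stop_at_steady=False,
        lambda_adh_cc=lam["lambda_adh_cs"] / 2, seed=4, **lam,
    )
    cell = next(iter(run_simulation(params).final_state.cells.values()))
    eq = rect_equilibrium(params)
    print(f"{name}:")
    print(f"  simulated  w x h = {cell.width} x {cell.height}  "
          f"(aspect {cell.height / cell.width:.2f}, area {cell.area})")
    print(f"  analytic   l* x h* = {eq.l_star:.1f} x {eq.h_star:.1f}  "
          f"(aspect {eq.aspect_ratio:.2f})")
print("A flat (squamous) cell has aspect < 1; contractility pushes it toward 1.")
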