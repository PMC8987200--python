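"""Analytic rectangular-cell phase surface.

Minimizes the closed-form single-cell energy E(l, h) over a grid of
contractility and cell-substrate adhesion values and prints the equilibrium
aspect ratio h*/l* and area l*h* per grid point.  Aspect ratio decreases
monotonically as substrate adhesion strengthens (cells spread out), and
increases with contractility at fixed adhesion.
"""

from epipotts import analytic_phase_surface

table = analytic_phase_surface(
    lambda_cont_values=[1.0, 3.0, 5.0, 7.0],
    lambda_adh_cs_values=[-100.0, -300.0, -500.0, -700.0],
    lambda_area_values=[1.0],
)
print(table[["lambda_cont", "lambda_adh_cs", "l_star", "h_star",
             "aspect_ratio", "area"]].round(2).to_string(index=False))
print("\nEach row is one mechanical parameter set; aspect_ratio < 1 means a "
      "flat (squamous) equilibrium cell.")
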