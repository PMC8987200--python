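# epipotts

A 2D Cellular Potts Model (CPM) of epithelial cells proliferating on a
substrate, for studying how cellular mechanics and the orientation of cell
division shape epithelial layers: single-cell squamous/cuboidal/columnar
shapes, self-arresting confluent monolayers, and the monolayer-to-multilayer
transition by cell extrusion.  It is aimed at computational tissue
mechanics: everything is a seeded, scriptable Python API with a thin CLI on
top.

## Model

Cells are sets of lattice sites sharing a positive label on an `x`–`z`
cross-section (`z` perpendicular to the substrate).  Configurations evolve
by Metropolis pixel copies under the energy

```
E = λ_area Σ_σ (A_σ − A0)²  +  λ_cont Σ_σ L_σ²  +  Σ_⟨i,j⟩ J(σ_i, σ_j) (1 − δ_{σ_i σ_j})
```

with `A_σ` the cell area, `L_σ` its boundary-link count (face links by
default), and `J = λ_adh^cc < 0` for cell–cell contacts, `λ_adh^cs < 0` for
cell–substrate contacts, and `0` against medium or the frozen wall ring.
A proposed copy of a random site's label onto a random neighbor is accepted
with probability `1` if `ΔE ≤ 0` and `e^(−ΔE/T)` otherwise; one Monte Carlo
step (MCS) is one attempt per lattice site.

Each MCS, a cell that has reached its target area (`A_σ ≥ A0`) divides with
the Hill probability of its substrate-adhesion pixel count `n_s`:

```
P_div = P_max · n_s^k / (n_s^k + (γ√A0)^k),      P_div = 0 when n_s = 0,
```

splitting along a plane through its centroid whose normal is vertical
`(1,0)`, horizontal `(0,1)`, random, or aligned with the cell's major axis.
The package also ships the closed-form single-rectangular-cell energy
`E(l,h) = λ_area(lh−A0)² + λ_cont(2l+2h)² + λ_adh^cs l` with its
stationarity conditions and certified global minimizer, plus snapshot
morphometrics (basal/suprabasal partition, coverage, per-cell extents) and
a categorical classifier of collective structures.

## Worked example

`examples/division_orientation.py` — with columnar-cell mechanics, switching
the division plane from vertical to major-axis extrudes daughters out of the
basal layer:

```
  vertical: (basal, suprabasal) per seed = [(23, 0), (24, 0), (23, 0)]
major_axis: (basal, suprabasal) per seed = [(22, 1), (19, 3), (12, 3)]
Suprabasal cells (no substrate contact) appear only under major-axis division.
```

Basal cells touch the substrate and may divide; suprabasal cells do not and
cannot.  Vertical division keeps every daughter on the substrate (a
self-arresting monolayer); major-axis division of tall cells stacks
daughters, seeding a multilayer.  The other scripts in `examples/` cover
single-cell shape versus mechanics, the analytic rectangle phase surface,
monolayer growth and self-arrest, a miniature phase-diagram sweep, and the
effect of the adhesion ratio α = λ_adh^cs / λ_adh^cc on monolayer cell
height.

A minimal API session:

```python
from epipotts import reduced_preset, run_simulation, measure_snapshot

params = reduced_preset(seed=1, lambda_cont=7.0, lambda_adh_cs=-700.0,
                        lambda_adh_cc=-350.0)
traj = run_simulation(params)
print(measure_snapshot(traj.final_state))
```

The CLI mirrors the library: `epipotts simulate|sweep|analyze|rect|fixtures`.

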