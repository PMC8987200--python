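"""A miniature collective-morphology phase diagram.

Sweeps contractility x substrate adhesion at desk scale (one replicate per
point) and prints the structure label per grid point: non-confluent groups
at high contractility / weak adhesion, self-arresting monolayers and
multilayers as adhesion strengthens.
"""

from epipotts import SweepSpec, reduced_preset, run_sweep

spec = SweepSpec(
    axes={
        "lambda_cont": [1.0, 7.0],
        "lambda_adh_cs": [-100.0, -700.0],
        "alpha": [2],
    },
    replicates=1,
    base_seed=0,
    base_params=reduced_preset(),
)
table = run_sweep(spec)
print(table[["lambda_cont", "lambda_adh_cs", "seed", "label", "n_cells",
             "coverage"]].to_string(index=False))
print("\nEach row is one seeded simulation; 'label' is the categorical "
      "structure classification of its trajectory.")
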