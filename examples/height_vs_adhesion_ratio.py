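"""Lateral cell-cell adhesion sets monolayer cell height.

Compares steady monolayer basal-cell heights between adhesion ratios
alpha = 2 (strong cell-cell adhesion) and alpha = 20 (weak), at fixed
cell-substrate adhesion.  Strong lateral adhesion stabilizes tall lateral
interfaces, so the alpha = 2 layer is taller; the printed ratio quantifies
the flattening caused by weakening cell-cell adhesion.
"""

from epipotts.experiments import adhesion_ratio_height_experiment

out = adhesion_ratio_height_experiment(
    lambda_cont=3.0, lambda_adh_cs=-300.0, seeds=(1, 2, 3),
)
print(f"mean interior basal-cell height, alpha=2 : {out['height_low_alpha']:.2f} px")
print(f"mean interior basal-cell height, alpha=20: {out['height_high_alpha']:.2f} px")
print(f"height ratio (alpha=2 / alpha=20)        : {out['ratio']:.3f}")
print("A ratio above 1 means weakening lateral adhesion flattens the cells.")
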