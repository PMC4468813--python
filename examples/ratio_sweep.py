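"""Reproduce the box-size sweep experiment at desk scale.

Twenty synthetic complexes are docked with the mock backend into cubic
boxes of edge 2-36 A.  Accuracy, binned by the Rg-to-edge ratio, is
U-shaped: tight boxes cause sampling failures, generous boxes cause
scoring failures, and the best mean RMSD sits at an interior ratio.
(The mock backend is non-physical, so the *location* of its optimum is
not meaningful — only the shape of the curve is.)
"""

from dockbox import run_ratio_sweep, synth_complex

complexes = [synth_complex(n_heavy=12, seed=100 + i) for i in range(20)]
curve = run_ratio_sweep(complexes, seed=42)

print("ratio   RMSD  resid  contact    n")
for p in curve.points:
    print(
        f"{p.ratio:5.2f}  {p.mean_rmsd:5.2f}  {p.mean_frac_binding_residues:5.2f}"
        f"  {p.mean_frac_specific_contacts:7.2f}  {p.n:3d}"
    )
print(f"sampling failures: {len(curve.failures)} (complex, edge) points")
print(f"interior optimum: {curve.has_interior_optimum()}, "
      f"best ratio {curve.optimum_ratio():.2f}")
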