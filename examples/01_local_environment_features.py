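"""Local-environment features of a toy structure.

Builds a 10-residue helical toy peptide, computes per-residue
solvent-accessible surface area, and prints the radial class-wise
neighbour counts and SASA totals around one serine.
"""

import oglcsite as og

structure = og.make_toy_structure(
    og.ToyStructureSpec(sequence="GAVKSDSTLR", geometry="helix")
)
sasa = og.residue_sasa(structure, og.compute_sasa(structure))
center = 4  # the first serine (0-based)

vec = og.local_environment_vector(structure, center, radii=(0.0, 5.0, 10.0))
print(f"centre residue: {structure.sequence[center]} at position {center + 1}")
print(f"own SASA: {vec.values['self_sasa']:.1f} A^2")
for r in (5, 10):
    count = vec.values[f"positively_charged_r{r}_count"]
    total = vec.values[f"positively_charged_r{r}_total_sasa"]
    print(f"r={r:>2} A: {count:.0f} positively charged neighbours, "
          f"their SASA {total:.1f} A^2")

# Counts and SASA totals can only grow with the radius, and the full
# feature table has one fixed-order column per (class, radius, statistic).
table = og.featurize_sites(structure, [4, 6], radii=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0))
print(f"feature table: {table.shape[0]} sites x {table.shape[1]} features")
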