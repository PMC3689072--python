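"""Rotation-translation-block coarse-graining versus full diagonalization.

Partitions a 30-residue ideal helix into 3-residue rigid blocks and
compares the RTB spectrum with the exact one: RTB eigenvalues bound the full
ones from above (internal block stiffening), while the soft-mode shapes are
preserved.
"""

import numpy as np

from modekit import (FixtureSpec, SpringModel, build_hessian,
                     build_spring_network, diagonalize_full, diagonalize_rtb,
                     make_blocks, make_structure, overlap)

structure = make_structure(FixtureSpec("helix_like", 30, seed=7))
hessian = build_hessian(build_spring_network(structure, SpringModel()),
                        structure)

full = diagonalize_full(hessian)
partition = make_blocks(structure, "n_residues", n_residues=3)
rtb = diagonalize_rtb(hessian, structure, partition)

print(f"full problem size: {hessian.dim}, RTB problem size: {rtb.n_modes}")
print("mode   full λ    RTB λ    ratio   |overlap|")
for k in range(6, 11):
    ov = abs(overlap(rtb.eigenvectors[:, k], full.eigenvectors[:, k]))
    print(f"{k + 1:4d}  {full.eigenvalues[k]:7.4f}  {rtb.eigenvalues[k]:7.4f}"
          f"  {rtb.eigenvalues[k] / full.eigenvalues[k]:6.3f}   {ov:.3f}")
# ratios slightly above 1 (stiffening) with overlaps near 1: the block
# approximation keeps the low-frequency physics at a fraction of the cost
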