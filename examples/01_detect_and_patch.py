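"""Detect a cavity on a synthetic pocket protein and build its patch.

Generates a 420-atom toy protein with one mixed-chemistry pocket, runs
alpha-sphere cavity detection, picks the cavity that covers the planted
pseudo-ligand and converts it into a pharmacophore-typed binding-site patch.
"""

import numpy as np

from pocketmap import (
    PocketSpec,
    detect_cavities,
    make_pocket_protein,
    match_cavity_to_ligand,
    patch_from_cavity,
    surface_atoms,
)

spec = PocketSpec(
    center=np.array([6.0, 0.0, 0.0]),
    mouth_direction=np.array([1.0, 0.0, 0.0]),
    depth=9.0,
    width=7.0,
    lining_types=("donor", "acceptor", "anion", "cation", "hydrophobe"),
)
structure, truths = make_pocket_protein(
    n_atoms=420, shell_radius=14.0, pockets=[spec], seed=7
)
print(f"structure: {len(structure.atoms)} atoms "
      f"({len(structure.protein_heavy_indices())} protein heavy)")

cavities = detect_cavities(structure)
print(f"detected {len(cavities)} cavities: sizes {[len(c) for c in cavities]}")

ligand = structure.coords(
    [i for i, a in enumerate(structure.atoms) if a.record == "ligand"]
)
cavity = match_cavity_to_ligand(cavities, ligand)
offset = np.linalg.norm(cavity.sphere_centers().mean(axis=0) - truths[0].center)
print(f"ligand-matched cavity {cavity.id}: {len(cavity)} alpha spheres, "
      f"centroid {offset:.1f} A from the planted pocket centre")

patch = patch_from_cavity(structure, cavity, surface=surface_atoms(structure))
print(f"patch: {len(patch.shape_points)} shape points, "
      f"pharmacophores {patch.type_counts()}")
# The cavity's alpha spheres sit inside the carved pocket, so the patch is the
# solvent-accessible pocket wall with the chemistry that was planted there.
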