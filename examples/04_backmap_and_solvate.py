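"""Rebuild an atomistic system from a coarse-grained complex.

Fits an atomistic reference helix onto CG backbone beads (Kabsch on
Cα ↔ bead pairs), aligns a membrane patch on the CG phosphates, prunes
lipids within 0.6 Å of the protein, solvates on a lattice, ionizes to
~0.1 mol/L, and emits the water-exclusion slab for the protein-membrane
gap.
"""

import numpy as np

from memscale import fixtures as fx
from memscale.mapping import map_protein
from memscale.backmap import (fit_protein_to_cg, fit_membrane_to_cg,
                              prune_lipids, solvate_and_ionize,
                              water_exclusion_region)
from memscale.structure_io import Structure

aa_ref = fx.build_amphipathic_anchor()
cg = map_protein(aa_ref)
# pretend the CG complex drifted: rotate + translate the beads
from scipy.spatial.transform import Rotation
rot = Rotation.from_euler("xyz", [10, 25, -40], degrees=True).as_matrix()
cg.beads.xyz = cg.beads.xyz @ rot.T + [20.0, 15.0, 30.0]

fitted = fit_protein_to_cg(aa_ref, cg)
ca = np.flatnonzero(fitted.names == "CA")
rmsd = np.sqrt(np.mean(np.sum(
    (fitted.xyz[ca] - cg.beads.xyz[cg.backbone_indices]) ** 2, axis=1)))
print(f"protein fit: Cα-to-bead RMSD = {rmsd:.2f} Å "
      "(sub-Å: the atomistic fold is placed on the CG complex)")

# a tiny atomistic membrane patch with P atoms at ±12 Å
names, resn, rid, xyz = [], [], [], []
k = 1
for zsign in (1, -1):
    for ix in range(4):
        for iy in range(4):
            for nm, dz in (("P", 0.0), ("C1", -zsign * 4.0)):
                names.append(nm); resn.append("POPC"); rid.append(k)
                xyz.append([8.0 * ix, 8.0 * iy, zsign * 12.0 + dz])
            k += 1
patch = Structure(names, resn, rid, ["M"] * len(names), np.array(xyz))

cg_phos = patch.xyz[patch.names == "P"] + [2.0, 1.0, 6.0]
aligned = fit_membrane_to_cg(patch, cg_phos)
print(f"membrane aligned: phosphate centroid moved to "
      f"{aligned.xyz[aligned.names == 'P'].mean(0).round(1)}")

aligned.xyz[0] = fitted.xyz[0] + [0.3, 0.0, 0.0]   # manufacture one clash
system = Structure.concat([fitted, aligned])
pruned, removed = prune_lipids(system, fitted, cutoff=0.6)
print(f"pruning: removed {removed} lipid(s) within 0.6 Å of the protein")

solute = fitted.copy()
solute.box = np.array([40.0, 40.0, 40.0, 90, 90, 90])
solvated, info = solvate_and_ionize(solute, target_conc=0.1, seed=0)
print(f"solvation: {info['n_waters']} waters, {info['n_pos']} Na+ and "
      f"{info['n_neg']} Cl- for {info['v_solvent']:.0f} Å³ of solvent "
      "(≈0.1 mol/L)")

membrane = patch.copy()
protein_up = fitted.copy()
protein_up.xyz += [0, 0, 30.0 - protein_up.xyz[:, 2].min()]
region = water_exclusion_region(protein_up, membrane)
print(f"water-exclusion slab: z in [{region.z_lo:.1f}, {region.z_hi:.1f}] Å "
      f"(height {region.height:.1f} Å) over the protein footprint")
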