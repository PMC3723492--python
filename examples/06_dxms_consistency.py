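"""Score a structural model against deuterium-exchange protection data.

Builds the synthetic DXMS fragment table that emulates the iPLA2
pattern (one strongly protected anchor fragment 708-730, three weakly
protected cavity fragments), derives per-residue burial from scripted
membrane-bound and solution poses, and scores fragment-level agreement.
"""

import numpy as np

from memscale import fixtures as fx
from memscale.analysis import membrane_frame
from memscale.dxms import (burial_profile, consistency_score,
                           read_fragments)
from memscale.structure_io import Structure, Trajectory

tsv = fx.synth_dxms(fx.dxms_preset_ipla2())
print("synthetic DXMS table:")
print(tsv)
frags = read_fragments(tsv)

protein = fx.build_helix(fx.HelixSpec("A" * 166), resid_start=625)
protein.xyz[:, 2] = 0.0
bil = fx.build_bilayer(fx.BilayerSpec(nx=4, ny=4, head_offset=12.0))
top = Structure.concat([protein, bil.beads])
n_prot = protein.n_atoms
lip = np.arange(n_prot, top.n_atoms)
phos = np.asarray(bil.phosphate_indices) + n_prot


def pose(z_base, dips):
    traj = Trajectory(top)
    for f in range(3):
        c = top.xyz.copy()
        c[:n_prot, 2] = z_base
        for (lo, hi), zs in dips.items():
            sel = (top.res_ids[:n_prot] >= lo) & (top.res_ids[:n_prot] <= hi)
            c[:n_prot][sel, 2] = zs[f]
        traj.append(c, box=top.box, time=float(f))
    mfs = [membrane_frame(fr.coords, lip, phos, top.masses)
           for fr in traj.frames]
    return traj, mfs


bound, mfs_b = pose(18.0, {(708, 730): [6.0] * 3,
                           (631, 655): [8.0, 25.0, 25.0],
                           (658, 664): [8.0, 25.0, 25.0],
                           (773, 778): [8.0, 25.0, 25.0]})
solution, mfs_s = pose(25.0, {})

for name, (traj, mfs) in (("membrane-bound", (bound, mfs_b)),
                          ("solution", (solution, mfs_s))):
    bp = burial_profile(traj, mfs)
    table, score = consistency_score(bp, frags)
    print(f"{name} model:")
    print(table.to_string(index=False))
    print(f"  overall consistency score = {score:.2f}\n")

print("the membrane-bound pose matches the protection pattern (anchor "
      "buried, cavity fragments transiently buried), the solution pose "
      "does not - scoring separates them")
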