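"""Quantify a protein-membrane complex: depths, angles, densities.

Computes the per-residue depth table and its hydrophobic/basic/polar
class summaries from the packaged published anchor-region values,
verifies the insertion-angle estimator on constructed tilts, and builds
a z-density profile of a toy bilayer.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from memscale import fixtures as fx
from memscale.analysis import (MembraneFrame, density_profile,
                               group_depth_summary, insertion_angle,
                               membrane_frame)
from memscale.reference import load_anchor_depth_table
from memscale.structure_io import Trajectory

table = load_anchor_depth_table()
print("published per-residue side-chain depths (Å from bilayer centre):")
print(table.to_string(index=False))
summary = group_depth_summary(table)
print("\nclass summaries (mean of row means ± mean of row sds):")
print(summary.to_string())
gap = (table[table.res_class != "hydrophobic"].mean_depth.mean()
       - table[table.res_class == "hydrophobic"].mean_depth.mean())
print(f"\nhydrophobic anchors sit {gap:.1f} Å (≈{round(gap)} Å) deeper "
      "than the basic/polar surface residues")

ca = fx.build_helix(fx.HelixSpec("A" * 36))
pts = ca.xyz[ca.names == "CA"]
mf = MembraneFrame(0.0, 14.0, -14.0)
errs = []
for tilt in (0, 30, 60, 90):
    rot = Rotation.from_euler("y", 90 - tilt, degrees=True).as_matrix()
    got = insertion_angle(pts @ rot.T, np.arange(len(pts)), mf)
    errs.append(abs(got - tilt))
    print(f"constructed tilt {tilt:2d}° -> measured {got:5.1f}°")
print(f"max tilt-recovery error: {max(errs):.2f}°")

bil = fx.build_bilayer(fx.BilayerSpec(nx=4, ny=4, head_offset=14.0))
traj = Trajectory(bil.beads)
traj.append(bil.beads.xyz, box=bil.beads.box, time=0.0)
lip = np.arange(bil.n_beads)
mfs = [membrane_frame(bil.beads.xyz, lip, bil.phosphate_indices)]
heads = np.asarray(bil.phosphate_indices)
tails = np.flatnonzero(bil.bead_classes == "C")
centers, profs = density_profile(traj, {"heads": heads, "tails": tails},
                                 mfs, bin_width=1.0)
head_peaks = centers[profs["heads"] > 0.9 * profs["heads"].max()]
print(f"\ndensity profile: headgroup peaks at {head_peaks.round(1)} Å "
      "(± the construction offset), tails filling the interior")
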