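"""Harmonic elastic network over backbone beads.

During coarse-grained simulation the protein's secondary and tertiary
structure is preserved by harmonic distance restraints between all
backbone beads within a cutoff (default 7 Å) of each other in the
reference structure, with force constant 10 kJ mol⁻¹ Å⁻²; the energy
convention is E = ½ k (r − r₀)².  Sequence-adjacent backbone pairs are
already joined by backbone bonds and are excluded by default
(``include_bonded=True`` restores them).  Side-chain beads never
participate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mapping import CGModel

__all__ = ["ElasticBond", "build_elastic_network", "elastic_energy_forces"]

DEFAULT_CUTOFF = 7.0   # Å
DEFAULT_K = 10.0       # kJ mol⁻¹ Å⁻²


@dataclass(frozen=True)
class ElasticBond:
    """Harmonic restraint between backbone beads i < j."""

    i: int
    j: int
    r0: float
    k: float

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("require i < j")
        if self.r0 <= 0 or self.k < 0:
            raise ValueError("require r0 > 0 and k ≥ 0")


def build_elastic_network(cg: CGModel, cutoff: float = DEFAULT_CUTOFF,
                          k: float = DEFAULT_K, *,
                          include_bonded: bool = False) -> list[ElasticBond]:
    """Restraints between all backbone-bead pairs within ``cutoff``.

    ``r0`` is set to the reference distance of each pair in ``cg.beads``;
    pairs already joined by a backbone bond are excluded unless
    ``include_bonded``.  The list is ordered by (i, j) and stored on
    ``cg.elastic_bonds`` as well as returned.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bb = np.asarray(cg.backbone_indices, int)
    if bb.size == 0:
        raise ValueError("model has no backbone beads")
    coords = cg.beads.xyz[bb]
    bonded = {(min(i, j), max(i, j)) for (i, j, *_r) in cg.bonds}
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(cutoff))
    out = []
    for a, b in pairs:
        gi, gj = int(bb[a]), int(bb[b])
        if gi > gj:
            gi, gj = gj, gi
        if not include_bonded and (gi, gj) in bonded:
            continue
        r0 = float(np.linalg.norm(cg.beads.xyz[gj] - cg.beads.xyz[gi]))
        out.append(ElasticBond(gi, gj, r0, k))
    out.sort(key=lambda e: (e.i, e.j))
    cg.elastic_bonds = out
    return out


def elastic_energy_forces(bonds: list[ElasticBond], coords: np.ndarray):
    """Energy (kJ mol⁻¹) and per-bead forces of the network.

    E = Σ ½ k (r − r₀)²; forces are the exact analytic gradients, so at
    the reference geometry both vanish and for any configuration the
    forces sum to zero.
    """
    coords = np.asarray(coords, float)
    forces = np.zeros_like(coords)
    if not bonds:
        return 0.0, forces
    i = np.array([b.i for b in bonds])
    j = np.array([b.j for b in bonds])
    r0 = np.array([b.r0 for b in bonds])
    k = np.array([b.k for b in bonds])
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    energy = float(np.sum(0.5 * k * (r - r0) ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        fmag = np.where(r > 0, -k * (r - r0) / r, 0.0)
    fvec = fmag[:, None] * d          # force on j
    np.add.at(forces, j, fvec)
    np.add.at(forces, i, -fvec)
    return energy, forces
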