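"""CG → atomistic back-mapping by rigid-body reconstruction.

An equilibrated atomistic reference protein is placed onto the CG
complex by a least-squares (Kabsch) fit of its Cα atoms onto the CG
backbone beads; an equilibrated membrane patch is aligned onto the CG
phosphate positions (plane + centroid matching — there is no 1:1
correspondence for lipids); lipids clashing with the protein (any atom
within 0.6 Å) are removed; the system is solvated on a lattice and
ionized to a target concentration (≈0.1 mol/L) with neutralizing
counter-ions; and a declarative repulsive region keeps water out of the
gap between protein and membrane.  Atomistic dynamics itself is left to
external engines — this module only constructs their input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure
from .mapping import CGModel, MappingError
from .units import N_AVOGADRO

__all__ = [
    "RigidTransform", "kabsch_fit", "fit_protein_to_cg",
    "fit_membrane_to_cg", "prune_lipids", "ion_count",
    "solvate_and_ionize", "ExclusionRegion", "water_exclusion_region",
    "LIPID_RESNAMES",
]

LIPID_RESNAMES = ("POPC", "TOY4", "TOY3", "POPE", "DPPC")
PHOSPHATE_NAMES = ("P", "PO4", "HD")


@dataclass
class RigidTransform:
    """Proper rotation + translation with the post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Optimal least-squares superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (det = +1; reflections are corrected by
    the usual sign flip of the smallest singular vector) and translation
    minimizing the RMSD between the transformed mobile points and the
    target.
    """
    mob = np.asarray(mobile, float)
    tgt = np.asarray(target, float)
    if mob.shape != tgt.shape:
        raise ValueError(f"point count mismatch: {mob.shape} vs {tgt.shape}")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    cm, ct = mob.mean(axis=0), tgt.mean(axis=0)
    h = (mob - cm).T @ (tgt - ct)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return RigidTransform(rot, trans, rmsd)


def fit_protein_to_cg(aa_ref: Structure, cg: CGModel) -> Structure:
    """Rigidly move an atomistic reference onto CG backbone beads.

    Correspondence is Cα atom ↔ backbone bead, matched by residue id.
    The whole structure moves as a rigid body, so all internal distances
    are preserved to round-off.
    """
    bb = np.asarray(cg.backbone_indices, int)
    bead_by_res = {int(cg.beads.res_ids[i]): i for i in bb}
    ca_mask = np.array([n == "CA" for n in aa_ref.names])
    ca_idx = np.flatnonzero(ca_mask)
    ca_res = [int(r) for r in aa_ref.res_ids[ca_idx]]
    missing = sorted(set(bead_by_res) ^ set(ca_res))
    if missing:
        raise MappingError("residue mismatch between atomistic reference and "
                           f"CG model; unmatched res_ids: {missing}")
    target = np.array([cg.beads.xyz[bead_by_res[r]] for r in ca_res])
    tf = kabsch_fit(aa_ref.xyz[ca_idx], target)
    out = aa_ref.copy()
    out.xyz = tf.apply(aa_ref.xyz)
    return out


def _phosphate_indices(patch: Structure):
    idx = np.flatnonzero(np.array([str(n) in PHOSPHATE_NAMES
                                   for n in patch.names]))
    if idx.size == 0:
        raise ValueError("patch has no recognizable phosphate atoms "
                         f"(looked for {PHOSPHATE_NAMES})")
    return idx


def _two_means_z(z: np.ndarray, min_gap: float = 5.0):
    """Split z values into two leaflets; error if not bilayer-like."""
    z = np.asarray(z, float)
    lo, hi = z.min(), z.max()
    if hi - lo < min_gap:
        raise ValueError("phosphate z values are unimodal: not a bilayer")
    c = np.array([lo, hi])
    for _ in range(50):
        lab = np.abs(z[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([z[lab == g].mean() if np.any(lab == g) else c[g]
                        for g in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    if abs(c[1] - c[0]) < min_gap or not (np.any(lab == 0) and np.any(lab == 1)):
        raise ValueError("phosphate z values do not separate into two leaflets")
    return (c.min(), c.max()), lab


def fit_membrane_to_cg(patch: Structure, cg_phosphates: np.ndarray,
                       *, rotate_about_normal: float = 0.0) -> Structure:
    """Align an atomistic membrane patch onto CG phosphate positions.

    The patch is translated so that its phosphate centroid (and hence
    its bilayer midplane) and lateral centre match those of the CG
    phosphates; an optional rotation about the bilayer normal (z) may be
    applied.  Leaflet spacing and all internal geometry are preserved.
    """
    cg_p = np.asarray(cg_phosphates, float)
    if cg_p.size == 0:
        raise ValueError("no CG phosphate positions given")
    pidx = _phosphate_indices(patch)
    _two_means_z(patch.xyz[pidx, 2])   # bilayer sanity check
    out = patch.copy()
    if rotate_about_normal:
        th = np.radians(rotate_about_normal)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        cen = out.xyz[pidx].mean(axis=0)
        out.xyz = (out.xyz - cen) @ rot.T + cen
    out.xyz += cg_p.mean(axis=0) - out.xyz[pidx].mean(axis=0)
    return out


def prune_lipids(system: Structure, protein: Structure,
                 cutoff: float = 0.6,
                 lipid_resnames=LIPID_RESNAMES):
    """Remove every lipid with ANY atom strictly within ``cutoff`` of the protein.

    Lipids are identified by residue name; removal is whole-lipid and
    deterministic.  Returns ``(pruned system, removed lipid count)``.
    """
    is_lipid = np.array([str(r) in lipid_resnames for r in system.res_names])
    tree = cKDTree(protein.xyz)
    d, _ = tree.query(system.xyz, k=1)
    clash = is_lipid & (d < cutoff)
    removed_keys = {(c, int(r)) for c, r in
                    zip(system.chains[clash], system.res_ids[clash])}
    keep = np.array([not (is_lipid[i]
                          and (system.chains[i], int(system.res_ids[i]))
                          in removed_keys)
                     for i in range(system.n_atoms)])
    return system.subset(np.flatnonzero(keep)), len(removed_keys)


def ion_count(target_conc: float, v_solvent: float) -> int:
    """Ions per species for a solvent volume (Å³) at ``target_conc`` mol/L."""
    return int(round(target_conc * N_AVOGADRO / 1.0e27 * v_solvent))


def solvate_and_ionize(system: Structure, *, target_conc: float = 0.1,
                       exclusion: float = 3.0, spacing: float = 3.1,
                       seed: int = 0, box=None):
    """Lattice solvation plus ionization to ``target_conc`` mol/L.

    Single-site waters (residue HOH, atom OW — a reduced water
    representation sufficient for geometry/occupancy work) are placed on
    a cubic lattice of the given ``spacing`` wherever they are farther
    than ``exclusion`` from every solute atom.  The ion count per
    species is ``round(conc · N_A · V_solvent)`` with
    V_solvent = n_waters · spacing³, plus counter-ions neutralizing the
    net solute charge; ions replace random waters (seeded).
    """
    box6 = system.box if box is None else np.asarray(box, float)
    if box6 is None:
        raise ValueError("solvation requires a defined box")
    lx, ly, lz = box6[:3]
    grid = [np.arange(spacing / 2, L, spacing) for L in (lx, ly, lz)]
    pts = np.stack(np.meshgrid(*grid, indexing="ij"), axis=-1).reshape(-1, 3)
    if system.n_atoms:
        tree = cKDTree(system.xyz)
        d, _ = tree.query(pts, k=1)
        pts = pts[d > exclusion]
    n_w = len(pts)
    v_solvent = n_w * spacing ** 3
    n_ion = ion_count(target_conc, v_solvent)
    net_q = float(np.round(system.charges.sum()))
    n_pos = n_ion + int(max(0.0, -net_q))
    n_neg = n_ion + int(max(0.0, net_q))
    if n_pos + n_neg > n_w:
        raise ValueError(f"no space for {n_pos + n_neg} ions among "
                         f"{n_w} waters")
    rng = np.random.default_rng(seed)
    ion_sites = rng.choice(n_w, size=n_pos + n_neg, replace=False)
    kind = np.full(n_w, "W")
    kind[ion_sites[:n_pos]] = "+"
    kind[ion_sites[n_pos:]] = "-"
    names = np.where(kind == "W", "OW", np.where(kind == "+", "NA", "CL"))
    resn = np.where(kind == "W", "HOH", np.where(kind == "+", "NA", "CL"))
    charges = np.where(kind == "+", 1.0, np.where(kind == "-", -1.0, 0.0))
    solvent = Structure(names, resn, np.arange(1, n_w + 1), ["S"] * n_w, pts,
                        elements=np.where(kind == "W", "O", names).tolist(),
                        charges=charges, box=box6, title="solvent")
    out = Structure.concat([system, solvent], box=box6,
                           title=(system.title + " solvated").strip())
    return out, {"n_waters": int(n_w - n_pos - n_neg), "n_pos": n_pos,
                 "n_neg": n_neg, "v_solvent": v_solvent}


@dataclass
class ExclusionRegion:
    """Declarative water-exclusion slab with a half-harmonic wall.

    The slab spans ``z_lo`` (membrane phosphate plane) to ``z_hi``
    (protein lower envelope), laterally clipped to the protein
    footprint.  ``k_wall`` (kJ mol⁻¹ Å⁻²) is the half-harmonic constant
    pushing waters out: E = ½ k d² for penetration depth d.
    """

    z_lo: float
    z_hi: float
    x_range: tuple
    y_range: tuple
    k_wall: float = 10.0

    @property
    def empty(self) -> bool:
        return self.z_hi <= self.z_lo

    @property
    def height(self) -> float:
        return max(0.0, self.z_hi - self.z_lo)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float).reshape(-1, 3)
        return ((p[:, 2] > self.z_lo) & (p[:, 2] < self.z_hi)
                & (p[:, 0] > self.x_range[0]) & (p[:, 0] < self.x_range[1])
                & (p[:, 1] > self.y_range[0]) & (p[:, 1] < self.y_range[1]))

    def to_toml(self) -> str:
        return ("[water_exclusion]\n"
                f"z_lo = {self.z_lo:.3f}\n"
                f"z_hi = {self.z_hi:.3f}\n"
                f"x_range = [{self.x_range[0]:.3f}, {self.x_range[1]:.3f}]\n"
                f"y_range = [{self.y_range[0]:.3f}, {self.y_range[1]:.3f}]\n"
                f"k_wall = {self.k_wall:.3f}\n")


def water_exclusion_region(protein: Structure, membrane: Structure,
                           k_wall: float = 10.0) -> ExclusionRegion:
    """Slab keeping water out of the protein–membrane gap.

    Bounded below by the proximal phosphate plane of the membrane and
    above by the protein's lower envelope, clipped laterally to the
    protein footprint.  A protein touching (or inside) the membrane
    yields an empty region with a warning.
    """
    pidx = _phosphate_indices(membrane)
    (z_low_leaf, z_up_leaf), _lab = _two_means_z(membrane.xyz[pidx, 2])
    z_lo = z_up_leaf if protein.xyz[:, 2].mean() > membrane.xyz[:, 2].mean() \
        else z_low_leaf
    z_hi = float(protein.xyz[:, 2].min())
    region = ExclusionRegion(float(z_lo), z_hi,
                             (float(protein.xyz[:, 0].min()),
                              float(protein.xyz[:, 0].max())),
                             (float(protein.xyz[:, 1].min()),
                              float(protein.xyz[:, 1].max())), k_wall)
    if region.empty:
        warnings.warn("protein touches or penetrates the membrane: "
                      "empty water-exclusion region")
    return region
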