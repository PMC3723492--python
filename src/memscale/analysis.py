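"""Quantitative analysis of protein–membrane complexes.

Implements the geometric observables used to characterize interfacial
anchoring: the membrane frame (bilayer centre of mass and per-leaflet
phosphate planes along the normal), the insertion angle of a designated
helix (angle between the helix axis and its projection on the membrane
plane, in [0°, 90°]), insertion depth (|z-c.o.m. − bilayer centre|),
per-residue depth tables with hydrophobic/basic/polar class summaries,
hydrogen-bond counts, RMSD/RMSF, mass-weighted z-density profiles, an
implicit-probe (single-site Lennard-Jones, methane-like) free-energy
map, and a bilayer self-assembly detector for coarse-grained runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Trajectory
from .mapping import CGModel
from .backmap import kabsch_fit, _two_means_z
from .units import KB

__all__ = [
    "MembraneFrame", "membrane_frame", "membrane_frames",
    "insertion_angle", "insertion_depth",
    "residue_depth_table", "group_depth_summary", "classify_residue",
    "hbond_count", "rmsd_series", "rmsf", "density_profile", "ils_map",
    "BilayerReport", "bilayer_check",
]

HYDROPHOBIC_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO",
                   "CYS"}
BASIC_RES = {"ARG", "LYS", "HIS"}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "BB"}


def classify_residue(res_name: str) -> str:
    """hydrophobic / basic / polar class of a residue name."""
    rn = str(res_name).upper()
    if rn in HYDROPHOBIC_RES:
        return "hydrophobic"
    if rn in BASIC_RES:
        return "basic"
    return "polar"


@dataclass
class MembraneFrame:
    """Bilayer geometry in one frame (normal fixed to +z by convention)."""

    center_z: float
    phosphate_z_upper: float
    phosphate_z_lower: float
    normal: np.ndarray = None

    def __post_init__(self):
        if self.normal is None:
            self.normal = np.array([0.0, 0.0, 1.0])
        if not (self.phosphate_z_upper > self.center_z > self.phosphate_z_lower):
            raise ValueError("leaflet planes must bracket the bilayer centre")


def membrane_frame(coords: np.ndarray, lipid_indices, phosphate_indices,
                   masses=None) -> MembraneFrame:
    """Bilayer centre (lipid z-c.o.m.) and per-leaflet phosphate means.

    Leaflets are separated by a two-means split of phosphate z values;
    an inseparable (non-bilayer) distribution raises ``ValueError``.
    """
    coords = np.asarray(coords, float)
    lip = np.asarray(lipid_indices, int)
    phos = np.asarray(phosphate_indices, int)
    w = (np.ones(len(lip)) if masses is None
         else np.asarray(masses, float)[lip])
    center = float(np.average(coords[lip, 2], weights=w))
    (z_lo, z_hi), _ = _two_means_z(coords[phos, 2])
    return MembraneFrame(center, float(z_hi), float(z_lo))


def membrane_frames(traj: Trajectory, lipid_indices, phosphate_indices):
    """One :class:`MembraneFrame` per trajectory frame."""
    m = traj.topology.masses
    return [membrane_frame(fr.coords, lipid_indices, phosphate_indices, m)
            for fr in traj.frames]


def insertion_angle(coords: np.ndarray, helix_indices, mf: MembraneFrame
                    ) -> float:
    """Angle (deg) between a helix and its projection on the membrane plane.

    The helix axis is the principal direction (largest singular vector)
    of the centred CA/backbone coordinates; the angle is folded into
    [0°, 90°] (an insertion angle is orientationless): 0° = lying in the
    membrane plane, 90° = along the normal.
    """
    idx = np.asarray(helix_indices, int)
    if idx.size < 4:
        raise ValueError("need at least 4 helix positions")
    pts = np.asarray(coords, float)[idx]
    pts = pts - pts.mean(axis=0)
    if np.allclose(pts, 0):
        raise ValueError("degenerate helix: all positions coincide")
    _u, _s, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    cos_from_normal = abs(float(np.dot(axis, mf.normal)))
    return float(90.0 - np.degrees(np.arccos(np.clip(cos_from_normal, 0, 1))))


def insertion_depth(coords: np.ndarray, indices, mf: MembraneFrame,
                    masses=None) -> float:
    """|z-centre-of-mass of the selected atoms − bilayer centre| (Å)."""
    idx = np.asarray(indices, int)
    if idx.size == 0:
        raise ValueError("empty index set")
    w = np.ones(idx.size) if masses is None else np.asarray(masses, float)[idx]
    z = float(np.average(np.asarray(coords, float)[idx, 2], weights=w))
    return abs(z - mf.center_z)


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

def residue_depth_table(traj: Trajectory, residues, mfs, *,
                        classes=None, window=None,
                        mode: str = "sidechain") -> pd.DataFrame:
    """Per-residue membrane-depth statistics over an analysis window.

    For each residue id, the depth in each frame is the distance along
    the normal between the residue's side-chain centre of mass
    (``mode='sidechain'``; ``'residue'`` uses all atoms) and the bilayer
    centre; rows carry mean ± sd (population convention, ÷N) over the
    frames of ``window`` (a slice or iterable of frame indices; default
    all).  A residue with no side-chain atoms falls back to the
    whole-residue centre of mass with a warning.
    """
    top = traj.topology
    frames = (range(traj.n_frames) if window is None
              else range(*window.indices(traj.n_frames))
              if isinstance(window, slice) else list(window))
    rows = []
    for k, rid in enumerate(residues):
        sel = np.flatnonzero(top.res_ids == rid)
        if sel.size == 0:
            raise ValueError(f"residue {rid} not in topology")
        if mode == "sidechain":
            sc = sel[[str(top.names[i]) not in BACKBONE_NAMES for i in sel]]
            if sc.size == 0:
                warnings.warn(f"residue {rid}: no side-chain atoms, using "
                              "whole residue")
                sc = sel
        else:
            sc = sel
        w = top.masses[sc]
        if w.sum() <= 0:
            w = np.ones(sc.size)
        depths = np.array(
            [abs(np.average(traj.frames[f].coords[sc, 2], weights=w)
                 - mfs[f].center_z) for f in frames])
        cls = (classes[k] if classes is not None
               else classify_residue(top.res_names[sel[0]]))
        rows.append({"res_id": int(rid), "res_class": cls,
                     "mean_depth": float(depths.mean()),
                     "sd_depth": float(depths.std())})
    return pd.DataFrame(rows)


def group_depth_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class (mean of row means, mean of row sds), to one decimal.

    ``table`` rows need ``res_class``, ``mean_depth``, ``sd_depth`` — the
    layout :func:`residue_depth_table` produces (or any table of
    published per-residue values cast into it).
    """
    if table.empty:
        warnings.warn("empty depth table: no class summaries")
        return pd.DataFrame(columns=["mean_depth", "sd_depth"])
    g = table.groupby("res_class", sort=False)[["mean_depth", "sd_depth"]]
    return g.mean().round(1)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_count(coords: np.ndarray, donors, acceptors, *,
                dist_cutoff: float = 3.5, angle_min: float = 150.0) -> int:
    """Geometric hydrogen-bond count.

    ``donors`` is a list of ``(donor_heavy_idx, hydrogen_idx)`` pairs
    (``hydrogen_idx=None`` switches that donor to the heavy-atom-only
    distance criterion, allowed only when ``angle_min`` is disabled by
    passing ``None``); ``acceptors`` is a list of acceptor indices.
    A bond is counted when donor–acceptor distance ≤ ``dist_cutoff`` Å
    and the donor–H···acceptor angle ≥ ``angle_min``°.
    """
    coords = np.asarray(coords, float)
    acceptors = np.asarray(acceptors, int)
    count = 0
    for entry in donors:
        d_idx, h_idx = entry if isinstance(entry, (tuple, list)) else (entry, None)
        if h_idx is None and angle_min is not None:
            raise ValueError(
                "donor without attached hydrogen: pass angle_min=None to use "
                "the heavy-atom-only (distance) criterion")
        dvec = coords[acceptors] - coords[d_idx]
        dist = np.linalg.norm(dvec, axis=1)
        ok = dist <= dist_cutoff
        ok &= dist > 1e-6          # the donor itself may be in the acceptor set
        if angle_min is not None:
            # D-H···A angle measured at H, between H→D and H→A (180° = linear)
            h = coords[h_idx]
            u_hd = coords[d_idx] - h
            v = coords[acceptors] - h
            nv = np.linalg.norm(v, axis=1)
            cosang = (v @ u_hd) / np.maximum(np.linalg.norm(u_hd) * nv, 1e-12)
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            ok &= ang >= angle_min
        count += int(np.sum(ok))
    return count


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, ref_coords: np.ndarray, indices,
                fit: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) of the selected atoms against a reference."""
    idx = np.asarray(indices, int)
    ref = np.asarray(ref_coords, float)[idx]
    out = np.empty(traj.n_frames)
    for f, fr in enumerate(traj.frames):
        mob = fr.coords[idx]
        if fit:
            out[f] = kabsch_fit(mob, ref).rmsd_after
        else:
            out[f] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsf(traj: Trajectory, indices, fit: bool = True) -> np.ndarray:
    """Per-atom RMSF (Å) about the time-mean structure after per-frame fit."""
    idx = np.asarray(indices, int)
    ref = traj.frames[0].coords[idx]
    aligned = np.empty((traj.n_frames, idx.size, 3))
    for f, fr in enumerate(traj.frames):
        mob = fr.coords[idx]
        aligned[f] = kabsch_fit(mob, ref).apply(mob) if fit else mob
    mean = aligned.mean(axis=0)
    if fit:
        for f in range(traj.n_frames):
            aligned[f] = kabsch_fit(aligned[f], mean).apply(aligned[f])
        mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

def density_profile(traj: Trajectory, groups: dict, mfs, *,
                    bin_width: float = 1.0):
    """Mass-weighted z-density per group, centred on the bilayer centre.

    Returns ``(bin_centers, {group: profile})`` with each profile
    normalized to integrate to 1 (∑ profile · bin_width = 1).  Distances
    are wrapped into (−Lz/2, Lz/2] when the frame has a box.
    """
    top = traj.topology
    lz = max((fr.box[2] if fr.box is not None else
              np.ptp(fr.coords[:, 2]) + 2 * bin_width)
             for fr in traj.frames)
    half = lz / 2
    edges = np.arange(-half, half + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for name, idx in groups.items():
        idx = np.asarray(idx, int)
        if idx.size == 0:
            warnings.warn(f"group {name!r} is empty: flat zero profile")
            out[name] = np.zeros(centers.size)
            continue
        w = top.masses[idx]
        if w.sum() <= 0:
            w = np.ones(idx.size)
        hist = np.zeros(centers.size)
        for f, fr in enumerate(traj.frames):
            dz = fr.coords[idx, 2] - mfs[f].center_z
            if fr.box is not None:
                dz -= fr.box[2] * np.round(dz / fr.box[2])
            h, _ = np.histogram(dz, bins=edges, weights=w)
            hist += h
        total = hist.sum() * bin_width
        out[name] = hist / total if total > 0 else hist
    return centers, out


# ---------------------------------------------------------------------------
# implicit-probe free energy map
# ---------------------------------------------------------------------------

def ils_map(traj: Trajectory, atom_eps, atom_sigma, *,
            probe_eps: float = 1.23, probe_sigma: float = 3.73,
            spacing: float = 1.0, temperature: float = 323.0,
            cutoff: float = 12.0, origin=None, shape=None):
    """Implicit-probe free-energy grid from an unperturbed trajectory.

    For each voxel x,  F(x) = −k_B T ln ⟨exp(−ΔE(x)/k_B T)⟩ over frames,
    where ΔE is the Lennard-Jones interaction energy of a single-site
    probe (methane-like defaults) with all atoms within ``cutoff``;
    probe–atom parameters combine by Lorentz–Berthelot.  Voxels whose
    Boltzmann average underflows are +inf (never visited).  Returns
    ``(origin, spacing, F)`` with F of shape ``shape``.
    """
    if spacing < 0.1:
        raise ValueError("grid spacing < 0.1 Å: resource guard")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    box0 = traj.frames[0].box
    for fr in traj.frames:
        if (fr.box is None) != (box0 is None) or \
                (box0 is not None and not np.allclose(fr.box, box0)):
            raise ValueError("implicit-probe map requires a constant box")
    if origin is None or shape is None:
        if box0 is not None:
            origin = np.zeros(3)
            extent = np.asarray(box0[:3], float)
        else:
            lo = traj.frames[0].coords.min(axis=0) - 3.0
            hi = traj.frames[0].coords.max(axis=0) + 3.0
            origin, extent = lo, hi - lo
        shape = tuple(int(max(1, np.floor(e / spacing))) for e in extent)
    origin = np.asarray(origin, float)
    axes = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing
            for d in range(3)]
    vox = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    eps_c = np.sqrt(np.asarray(atom_eps, float) * probe_eps)
    sig_c = 0.5 * (np.asarray(atom_sigma, float) + probe_sigma)
    beta = 1.0 / (KB * temperature)
    acc = np.zeros(len(vox))
    for fr in traj.frames:
        tree = cKDTree(fr.coords)
        boltz = np.empty(len(vox))
        neigh = tree.query_ball_point(vox, r=cutoff)
        for vi, atoms in enumerate(neigh):
            if not atoms:
                boltz[vi] = 1.0
                continue
            a = np.asarray(atoms, int)
            d = np.linalg.norm(fr.coords[a] - vox[vi], axis=1)
            d = np.maximum(d, 1e-6)
            sr6 = (sig_c[a] / d) ** 6
            e = float(np.sum(4 * eps_c[a] * (sr6 * sr6 - sr6)))
            boltz[vi] = np.exp(-beta * min(e, 500.0 / beta))
        acc += boltz
    mean = acc / traj.n_frames
    with np.errstate(divide="ignore"):
        f = np.where(mean > 0, -KB * temperature * np.log(
            np.maximum(mean, 1e-300)), np.inf)
    f[mean <= 1e-290] = np.inf
    return origin, spacing, f.reshape(shape)


# ---------------------------------------------------------------------------
# bilayer self-assembly detection
# ---------------------------------------------------------------------------

@dataclass
class BilayerReport:
    """Outcome of the single-bilayer check on a CG configuration."""

    ok: bool
    axis: int
    cluster_fraction: float
    leaflet_counts: tuple
    head_offset_mean: float
    tail_offset_mean: float


def _circular_center(x, period):
    ang = 2 * np.pi * x / period
    c = np.mean(np.cos(ang))
    s = np.mean(np.sin(ang))
    r = np.hypot(c, s)
    return period * np.arctan2(s, c) / (2 * np.pi), r


def bilayer_check(model: CGModel, coords=None, box=None, *,
                  contact: float = 6.5, min_cluster_frac: float = 0.8,
                  min_leaflet_frac: float = 0.2,
                  min_head_offset: float = 3.0) -> BilayerReport:
    """Has a single bilayer slab formed (two leaflets, tails interior)?

    Lipids are clustered by apolar-bead contacts under periodic
    boundaries; the slab normal is the box axis along which the tail
    beads are most concentrated (circular statistics).  The check passes
    when one cluster holds ≥ ``min_cluster_frac`` of the lipids, head
    beads split into two sufficiently populated leaflets on opposite
    sides of the tail slab, and heads lie farther from the slab centre
    than tails.
    """
    beads = model.beads
    coords = beads.xyz if coords is None else np.asarray(coords, float)
    if box is None:
        box = None if beads.box is None else beads.box[:3]
    phos = np.asarray(model.phosphate_indices, int)
    lipid_resn = {str(r) for r in beads.res_names[phos]}
    lip_mask = np.array([str(r) in lipid_resn for r in beads.res_names])
    tail = np.flatnonzero(lip_mask & (model.bead_classes == "C"))
    head = phos
    # group beads into lipid molecules
    keys = {}
    for i in np.flatnonzero(lip_mask):
        keys.setdefault((beads.chains[i], int(beads.res_ids[i])),
                        []).append(i)
    lipid_ids = {i: li for li, (_k, idx) in enumerate(keys.items())
                 for i in idx}
    n_lip = len(keys)

    wrapped = np.mod(coords[tail], box) if box is not None else coords[tail]
    tree = cKDTree(wrapped, boxsize=box)
    parent = list(range(n_lip))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in tree.query_pairs(contact):
        a, b = find(lipid_ids[tail[i]]), find(lipid_ids[tail[j]])
        if a != b:
            parent[a] = b
    roots = [find(i) for i in range(n_lip)]
    counts = np.bincount(roots, minlength=n_lip)
    cluster_frac = counts.max() / n_lip if n_lip else 0.0

    best_axis, best_r = 2, -1.0
    for ax in range(3):
        period = box[ax] if box is not None else \
            np.ptp(coords[tail, ax]) * 2 + 1
        _c, r = _circular_center(coords[tail, ax], period)
        if r > best_r:
            best_axis, best_r = ax, r
    period = box[best_axis] if box is not None else \
        np.ptp(coords[:, best_axis]) * 2 + 1
    center, _ = _circular_center(coords[tail, best_axis], period)

    def offset(idx):
        d = coords[idx, best_axis] - center
        return d - period * np.round(d / period)

    d_head, d_tail = offset(head), offset(tail)
    n_up = int(np.sum(d_head > 0))
    n_dn = int(np.sum(d_head < 0))
    leaf_ok = min(n_up, n_dn) >= min_leaflet_frac * max(len(head), 1)
    head_off = float(np.mean(np.abs(d_head))) if len(head) else 0.0
    tail_off = float(np.mean(np.abs(d_tail))) if len(tail) else 0.0
    ok = (cluster_frac >= min_cluster_frac and leaf_ok
          and head_off > tail_off and head_off >= min_head_offset)
    return BilayerReport(bool(ok), best_axis, float(cluster_frac),
                         (n_up, n_dn), head_off, tail_off)
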