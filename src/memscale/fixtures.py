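"""Synthetic fixtures: helices, toy lipids, bilayers, random boxes, DXMS tables.

Everything downstream is testable without external downloads: this
module builds ideal α-helices (textbook 1.5 Å rise / 100° twist) with a
reduced backbone (N, CA, C, O plus a pseudo side-chain atom CB), an
amphipathic interfacial-anchor helix with the hydrophobic cluster of the
iPLA2 anchor region (residues 710–724) on one face, a 41-residue
helix-loop-helix mini protein numbered 710–750 in full-protein
coordinates, pre-assembled toy bilayers, random lipid/water
self-assembly boxes, and synthetic deuterium-exchange fragment tables.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Structure
from .mapping import (CGModel, LipidTemplate, load_lipid_templates,
                      map_water)

__all__ = [
    "HelixSpec", "BilayerSpec", "AA3", "ANCHOR_SEQUENCE",
    "build_helix", "build_amphipathic_anchor", "build_mini_protein",
    "build_bilayer", "random_box", "synth_dxms", "dxms_preset_ipla2",
]

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: anchor-region sequence, residues 710–724: basic/polar face
#: (Arg710, Ser712, Asn713, Glu716, Lys719, Thr720, Gly723) opposite a
#: hydrophobic face (Pro711, Pro714, Trp715, Leu717, Val721, Phe722)
ANCHOR_SEQUENCE = "RPSNPWELAKTVFGA"

HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"}
BASIC = {"ARG", "LYS", "HIS"}


@dataclass
class HelixSpec:
    """Ideal α-helix geometry."""

    sequence: str
    rise: float = 1.5      # Å per residue
    twist: float = 100.0   # degrees per residue
    radius: float = 2.3    # Å (CA helix radius)

    def __post_init__(self):
        if self.rise <= 0 or not 0 < self.twist < 360:
            raise ValueError("require rise > 0 and 0 < twist < 360")
        bad = [c for c in self.sequence.upper() if c not in AA3]
        if bad:
            raise ValueError(f"unknown residue letter(s): {''.join(bad)}")


@dataclass
class BilayerSpec:
    """Pre-assembled toy bilayer layout."""

    nx: int = 6
    ny: int = 6
    apl: float = 40.0          # area per lipid, Å²
    head_offset: float = 13.0  # phosphate plane |z| from midplane, Å
    lipid: str = "TOY4"

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.apl <= 0 or self.head_offset <= 0:
            raise ValueError("invalid bilayer spec")


def build_helix(spec: HelixSpec, resid_start: int = 1, chain: str = "A",
                title: str = "ideal helix") -> Structure:
    """Build an ideal helix: N, CA, C, O and a pseudo side-chain CB.

    CA *i* sits at azimuth i·twist and z = i·rise on a cylinder of the
    given radius; the pseudo CB points radially outward, so residue
    side-chain azimuths follow the helical wheel.  Residue ids start at
    ``resid_start`` (full-protein numbering such as 710–724 is therefore
    reproducible).  Glycine gets no CB.
    """
    seq = spec.sequence.upper()
    names, resn, rid, xyz = [], [], [], []
    for i, letter in enumerate(seq):
        res = AA3[letter]
        theta = np.radians(i * spec.twist)
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        e_t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        ca = spec.radius * e_r + np.array([0, 0, i * spec.rise])
        local = {
            "N": ca - 0.4 * e_r - 1.1 * e_t - 0.8 * e_z,
            "CA": ca,
            "C": ca - 0.3 * e_r + 1.2 * e_t + 0.5 * e_z,
            "O": ca + 0.3 * e_r + 1.6 * e_t + 1.2 * e_z,
        }
        if res != "GLY":
            local["CB"] = ca + 1.5 * e_r + 0.3 * e_z
        for nm, pos in local.items():
            names.append(nm)
            resn.append(res)
            rid.append(resid_start + i)
            xyz.append(pos)
    elements = [("N" if n == "N" else "O" if n == "O" else "C") for n in names]
    return Structure(names, resn, rid, [chain] * len(names),
                     np.array(xyz), elements=elements, title=title)


def build_amphipathic_anchor(resid_start: int = 710,
                             spec: HelixSpec | None = None) -> Structure:
    """The 15-residue interfacial anchor helix (residues 710–724).

    With the packaged sequence and 100°/residue twist, the hydrophobic
    side chains (711, 714, 715, 717, 721, 722) cluster on one face of
    the helical wheel — the amphipathic motif that drives interfacial
    anchoring.
    """
    spec = spec or HelixSpec(ANCHOR_SEQUENCE)
    return build_helix(spec, resid_start=resid_start,
                       title="amphipathic anchor helix")


def build_mini_protein() -> Structure:
    """A 41-residue helix-loop-helix mini protein, residues 710–750.

    The anchor helix (710–724) lies along x (membrane-parallel when the
    membrane normal is z) and the "long" helix (725–750) rises away from
    it — a desk-scale stand-in for the catalytic domain's
    membrane-facing surface, numbered in full-protein coordinates.
    """
    anchor = build_helix(HelixSpec(ANCHOR_SEQUENCE), resid_start=710)
    # lay the anchor helix axis along x
    rot = Rotation.from_euler("y", 90, degrees=True).as_matrix()
    anchor.xyz = anchor.xyz @ rot.T
    long_seq = "GAELKASTVNDQLIRAGELSAKTVNA"  # 26 residues: 725–750
    helix2 = build_helix(HelixSpec(long_seq), resid_start=725)
    tilt = Rotation.from_euler("y", 25, degrees=True).as_matrix()
    helix2.xyz = helix2.xyz @ tilt.T
    helix2.xyz += (anchor.xyz[-1] - helix2.xyz[0]) + np.array([3.0, 0.0, 4.0])
    out = Structure.concat([anchor, helix2], title="mini protein 710-750")
    out.chains[:] = "A"
    return out


# ---------------------------------------------------------------------------
# lipids and bilayers
# ---------------------------------------------------------------------------

def _cg_lipid(template: LipidTemplate, res_id: int, head_pos, direction,
              spacing: float = 4.2) -> Structure:
    """One CG lipid as a straight bead chain from head along ``direction``."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    n = len(template.beads)
    xyz = np.asarray(head_pos, float) + np.outer(np.arange(n) * spacing, d)
    return Structure([b.bead_name for b in template.beads],
                     [template.res_name] * n, [res_id] * n, ["L"] * n, xyz,
                     elements=["X"] * n,
                     masses=[b.mass for b in template.beads],
                     charges=[b.charge for b in template.beads],
                     is_bead=[True] * n)


def _lipid_model(parts, template, box, title) -> CGModel:
    beads = Structure.concat(parts, box=box, title=title)
    nb = len(template.beads)
    names = [b.bead_name for b in template.beads]
    ph_local = names.index(template.phosphate_bead)
    bonds, angles, ph = [], [], []
    for li in range(len(parts)):
        off = li * nb
        bonds += [(off + i, off + j, r0, k) for (i, j, r0, k) in template.bonds]
        angles += [(off + i, off + j, off + k, t, kt)
                   for (i, j, k, t, kt) in template.angles]
        ph.append(off + ph_local)
    classes = np.array([b.bead_class for b in template.beads] * len(parts),
                       object)
    return CGModel(beads, bonds, angles, np.empty(0, int),
                   np.array(ph, int), [], classes)


def build_bilayer(spec: BilayerSpec | None = None, *, z_pad: float = 12.0,
                  templates=None) -> CGModel:
    """Pre-assembled toy bilayer: two leaflet grids, tails pointing inward.

    Phosphate (head) beads sit at ±``head_offset``; the box is
    nx·√apl × ny·√apl laterally and 2·(head_offset + z_pad) high,
    centred so the midplane is z = box_z/2 when wrapped (coordinates are
    emitted centred on z = 0).
    """
    spec = spec or BilayerSpec()
    tmpl = (templates or load_lipid_templates())[spec.lipid]
    a = np.sqrt(spec.apl)
    parts = []
    rid = 1
    for leaf, zsign in ((0, 1.0), (1, -1.0)):
        shift = 0.5 * a if leaf else 0.0
        for ix in range(spec.nx):
            for iy in range(spec.ny):
                head = np.array([ix * a + shift, iy * a + shift,
                                 zsign * spec.head_offset])
                parts.append(_cg_lipid(tmpl, rid, head, [0, 0, -zsign]))
                rid += 1
    box = np.array([spec.nx * a, spec.ny * a,
                    2 * (spec.head_offset + z_pad), 90, 90, 90])
    return _lipid_model(parts, tmpl, box,
                        f"toy bilayer {spec.nx}x{spec.ny}x2")


def random_box(n_lipids: int, n_waters: int, solute: CGModel | None = None,
               box: float | tuple = 38.0, seed: int = 0, *,
               lipid: str = "TOY4", min_dist: float = 3.2,
               templates=None) -> CGModel:
    """Random self-assembly box: lipids + CG water (+ optional solute).

    Lipids are straight-chain conformers at uniformly random positions
    and orientations; waters are random points.  Placement rejects
    candidates within ``min_dist`` of already-placed beads (residual
    overlaps are resolved by the minimizer's force capping).  Fully
    deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    box3 = np.array([box, box, box], float) if np.isscalar(box) \
        else np.asarray(box, float)
    tmpl = (templates or load_lipid_templates())[lipid]
    placed = []
    if solute is not None:
        solute = CGModel.merge([solute])   # detached copy; caller untouched
        solute.beads.xyz += box3 / 2 - solute.beads.xyz.mean(axis=0)
        placed.append(solute.beads.xyz)

    def far_enough(xyz):
        for arr in placed:
            d = xyz[:, None, :] - arr[None, :, :]
            d -= box3 * np.round(d / box3)
            if np.min(np.einsum("ijk,ijk->ij", d, d)) < min_dist ** 2:
                return False
        return True

    parts = []
    for li in range(n_lipids):
        for _try in range(400):
            head = rng.uniform(0, box3)
            direction = Rotation.random(random_state=rng).apply([0, 0, 1.0])
            lip = _cg_lipid(tmpl, li + 1, head, direction)
            lip.xyz -= box3 * np.floor(lip.xyz / box3)  # wrap into box
            if far_enough(lip.xyz):
                break
        else:
            raise RuntimeError("random box too dense: cannot place lipid")
        parts.append(lip)
        placed.append(lip.xyz)
    lipids = _lipid_model(parts, tmpl, np.array([*box3, 90, 90, 90]),
                          f"random box {n_lipids} lipids")

    water = map_water(4 * n_waters)
    wxyz = np.empty((n_waters, 3))
    for wi in range(n_waters):
        for _try in range(400):
            p = rng.uniform(0, box3)[None, :]
            if far_enough(p):
                break
        else:
            raise RuntimeError("random box too dense: cannot place water")
        wxyz[wi] = p[0]
        placed.append(p)
    water.beads.xyz = wxyz

    models = ([solute] if solute is not None else []) + [lipids, water]
    return CGModel.merge(models, box=np.array([*box3, 90, 90, 90]),
                         title=f"random box seed {seed}")


def interfacial_system(seed: int = 0, *, spec: BilayerSpec | None = None,
                       helix_height: float = 8.0, tilt: float = 0.0,
                       water_spacing: float = 4.7, templates=None):
    """An amphipathic anchor helix in water above a pre-formed toy bilayer.

    The CG helix (mapped from :func:`build_amphipathic_anchor`, elastic
    network applied) is laid with its axis in the membrane plane (x),
    rolled about its axis by a seed-dependent random azimuth (so the
    hydrophobic face starts in a random orientation), optionally tilted
    by ``tilt`` degrees about y, and its centre placed ``helix_height``
    Å above the upper phosphate plane (negative = inserted).  CG water
    beads fill the remaining volume on a lattice.  Returns
    ``(model, info)`` where ``info`` maps index groups (helix backbone,
    hydrophobic/polar side-chain beads, lipids, water).
    """
    from .elastic import build_elastic_network
    from .mapping import map_protein

    rng = np.random.default_rng(seed)
    spec = spec or BilayerSpec()
    bil = build_bilayer(spec, templates=templates)
    box3 = bil.beads.box[:3]

    helix = map_protein(build_amphipathic_anchor())
    build_elastic_network(helix)
    xyz = helix.beads.xyz
    xyz -= xyz[helix.backbone_indices].mean(axis=0)
    # helix axis z → x, then a random roll about the axis, then tilt about y
    lay = Rotation.from_euler("y", 90, degrees=True)
    roll = Rotation.from_euler("x", rng.uniform(0, 360), degrees=True)
    tilt_r = Rotation.from_euler("y", tilt, degrees=True)
    helix.beads.xyz = xyz @ (tilt_r * roll * lay).as_matrix().T
    helix.beads.xyz += np.array([box3[0] / 2, box3[1] / 2,
                                 spec.head_offset + helix_height])

    merged = CGModel.merge([helix, bil], box=bil.beads.box,
                           title=f"interfacial system seed {seed}")
    # lattice water outside the membrane slab and away from solute
    grid = [np.arange(water_spacing / 2, L, water_spacing) for L in box3]
    pts = np.stack(np.meshgrid(
        grid[0], grid[1], grid[2] - box3[2] / 2, indexing="ij"),
        axis=-1).reshape(-1, 3)
    pts = pts[np.abs(pts[:, 2]) > spec.head_offset + 1.0]
    from scipy.spatial import cKDTree
    d, _ = cKDTree(merged.beads.xyz).query(pts, k=1)
    pts = pts[d > 4.0]
    water = map_water(4 * len(pts))
    water.beads.xyz = pts
    model = CGModel.merge([merged, water], box=bil.beads.box,
                          title=merged.beads.title)

    nh = helix.n_beads
    cls = model.bead_classes
    prot = np.arange(nh)
    sc = np.setdiff1d(prot, np.asarray(model.backbone_indices, int))
    info = {
        "helix_backbone": np.asarray(model.backbone_indices, int),
        "hydrophobic_sc": sc[cls[sc] == "C"],
        "polar_sc": sc[(cls[sc] == "P") | (cls[sc] == "Q")],
        "protein": prot,
        "lipids": np.arange(nh, nh + bil.n_beads),
        "water": np.arange(nh + bil.n_beads, model.n_beads),
        "head_offset": spec.head_offset,
    }
    return model, info


# ---------------------------------------------------------------------------
# synthetic DXMS tables
# ---------------------------------------------------------------------------

def dxms_preset_ipla2():
    """Fragment pattern of the iPLA2 catalytic domain on membrane binding.

    One strongly protected anchor fragment (708–730, ≈70 % decrement
    after 5 min incubation) and three weakly protected cavity fragments
    (631–655, 658–664, 773–778, <40 %).
    """
    return [(708, 730, 72.0, 300.0), (631, 655, 30.0, 300.0),
            (658, 664, 32.0, 300.0), (773, 778, 35.0, 300.0)]


def synth_dxms(regions, path=None) -> str:
    """Serialize (start, end, decrement %, incubation s) fragments as TSV.

    Ranges must be non-overlapping.  Returns the TSV text and optionally
    writes it to ``path``.
    """
    rows = sorted(regions, key=lambda r: r[0])
    for (a, b) in zip(rows, rows[1:]):
        if a[1] >= b[0]:
            raise ValueError(f"overlapping fragments {a[:2]} and {b[:2]}")
    lines = ["res_start\tres_end\tdecrement_pct\tincubation_s"]
    for (s, e, d, t) in rows:
        if s > e:
            raise ValueError(f"fragment start {s} > end {e}")
        lines.append(f"{int(s)}\t{int(e)}\t{float(d):g}\t{float(t):g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
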