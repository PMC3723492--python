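"""Atomistic → coarse-grained mapping at ≈4:1 resolution.

Proteins are mapped to one backbone bead per residue (centre of mass of
the N, CA, C, O atoms) plus 0–2 side-chain beads placed at the centre
of mass of template-defined parent atoms; lipids are mapped bead-by-bead
from a lipid template; water is mapped 4 atomistic waters → 1 CG bead.
Bead polarity classes (P polar / N intermediate / C apolar / Q charged,
plus W for CG water) and charges come from packaged, editable template
tables (``memscale/data/``), not from code.

Bead masses are the sums of their matched parent-atom masses, so total
CG mass equals the total atomistic mass of the mapped atoms, and every
bead sits at the exact centre of mass of its parents.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure_io import Structure

__all__ = [
    "BeadTemplate", "LipidTemplate", "CGModel", "MappingError",
    "load_protein_templates", "load_lipid_templates",
    "map_protein", "map_lipid", "map_water",
    "BACKBONE_BOND_K", "DEFAULT_WATER_MASS",
]

#: harmonic bond force constant between consecutive backbone beads and
#: backbone–side-chain pairs (kJ mol⁻¹ Å⁻²)
BACKBONE_BOND_K = 12.5

#: CG water bead mass: 4 atomistic waters (amu)
DEFAULT_WATER_MASS = 72.0


class MappingError(ValueError):
    """A residue or atom pattern could not be mapped."""


@dataclass
class BeadTemplate:
    """One bead of a mapping template."""

    bead_name: str
    bead_class: str          # P, N, C, Q or W
    charge: float = 0.0
    parent_atoms: tuple = ()  # fnmatch patterns over atom names
    mass: float = 0.0         # default mass when built without parents

    def __post_init__(self):
        if self.bead_class not in ("P", "N", "C", "Q", "W"):
            raise ValueError(f"unknown bead class {self.bead_class!r}")
        if self.charge != 0 and self.bead_class != "Q":
            raise ValueError("nonzero charge requires class Q")
        if not self.parent_atoms and self.mass <= 0:
            raise ValueError("bead needs parent atoms or a default mass")


@dataclass
class LipidTemplate:
    """Ordered beads + intramolecular topology of one lipid species."""

    res_name: str
    beads: list[BeadTemplate]
    bonds: list[tuple[int, int, float, float]]          # (i, j, r0, k)
    angles: list[tuple[int, int, int, float, float]]    # (i, j, k, θ0°, kθ)
    phosphate_bead: str = ""

    @property
    def net_charge(self) -> float:
        return sum(b.charge for b in self.beads)


@dataclass
class CGModel:
    """A coarse-grained model: beads plus bonded topology.

    ``beads`` is a :class:`~memscale.structure_io.Structure` with
    ``is_bead`` true throughout.  ``bonds`` are harmonic
    ``(i, j, r0 Å, k kJ mol⁻¹ Å⁻²)``; ``angles`` are harmonic
    ``(i, j, k, θ0 deg, kθ kJ mol⁻¹ rad⁻²)``.  ``elastic_bonds`` is
    filled by :mod:`memscale.elastic`.
    """

    beads: Structure
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    backbone_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    phosphate_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    elastic_bonds: list = field(default_factory=list)
    bead_classes: np.ndarray = field(default_factory=lambda: np.empty(0, object))

    def __post_init__(self):
        n = self.beads.n_atoms
        for (i, j, *_rest) in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index ({i},{j}) out of range")
        for (i, j, k, *_rest) in self.angles:
            if not all(0 <= x < n for x in (i, j, k)):
                raise ValueError(f"angle index ({i},{j},{k}) out of range")

    @property
    def n_beads(self) -> int:
        return self.beads.n_atoms

    @staticmethod
    def merge(models: list["CGModel"], box=None, title="") -> "CGModel":
        """Concatenate models, shifting all topology indices."""
        parts, bonds, angles, bb, ph, ela, cls = [], [], [], [], [], [], []
        off = 0
        for m in models:
            parts.append(m.beads)
            bonds += [(i + off, j + off, r0, k) for (i, j, r0, k) in m.bonds]
            angles += [(i + off, j + off, k + off, t, kt)
                       for (i, j, k, t, kt) in m.angles]
            bb.append(np.asarray(m.backbone_indices, int) + off)
            ph.append(np.asarray(m.phosphate_indices, int) + off)
            for e in m.elastic_bonds:
                ela.append(type(e)(e.i + off, e.j + off, e.r0, e.k))
            cls.append(m.bead_classes)
            off += m.n_beads
        return CGModel(Structure.concat(parts, box=box, title=title),
                       bonds, angles, np.concatenate(bb), np.concatenate(ph),
                       ela, np.concatenate(cls))


# ---------------------------------------------------------------------------
# template loading
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("memscale.data").joinpath(name).read_text()


def load_protein_templates(text: str | None = None):
    """Load the residue → side-chain-bead table (packaged default).

    Returns ``(backbone_template, {resname: [BeadTemplate, ...]})``.
    """
    text = text if text is not None else _data_text("protein_beads.txt")
    backbone = None
    table: dict[str, list[BeadTemplate]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "BACKBONE":
            cls, q, parents = parts[1], float(parts[2]), parts[3].split(",")
            backbone = BeadTemplate("BB", cls, q, tuple(parents))
        else:
            res, bead, cls, q, parents = (parts[0], parts[1], parts[2],
                                          float(parts[3]), parts[4].split(","))
            table.setdefault(res, []).append(
                BeadTemplate(bead, cls, q, tuple(parents)))
    if backbone is None:
        raise MappingError("protein template defines no BACKBONE bead")
    # residues with no side-chain beads are legal (GLY, ALA)
    for res in ("GLY", "ALA"):
        table.setdefault(res, [])
    return backbone, table


def load_lipid_templates(text: str | None = None) -> dict[str, LipidTemplate]:
    """Load lipid templates (packaged default covers POPC, TOY4, TOY3)."""
    text = text if text is not None else _data_text("lipids.txt")
    out: dict[str, LipidTemplate] = {}
    cur = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "LIPID":
            cur = LipidTemplate(parts[1], [], [], [])
            out[parts[1]] = cur
        elif cur is None:
            raise MappingError(f"directive before LIPID: {line!r}")
        elif parts[0] == "BEAD":
            cur.beads.append(BeadTemplate(parts[1], parts[2], float(parts[3]),
                                          tuple(parts[5].split(",")),
                                          mass=float(parts[4])))
        elif parts[0] == "BOND":
            names = [b.bead_name for b in cur.beads]
            cur.bonds.append((names.index(parts[1]), names.index(parts[2]),
                              float(parts[3]), float(parts[4])))
        elif parts[0] == "ANGLE":
            names = [b.bead_name for b in cur.beads]
            cur.angles.append((names.index(parts[1]), names.index(parts[2]),
                               names.index(parts[3]),
                               float(parts[4]), float(parts[5])))
        elif parts[0] == "PHOSPHATE":
            cur.phosphate_bead = parts[1]
        else:
            raise MappingError(f"unknown lipid-template directive {parts[0]!r}")
    return out


def _match_parents(names: np.ndarray, patterns) -> np.ndarray:
    mask = np.zeros(len(names), dtype=bool)
    for pat in patterns:
        mask |= np.array([fnmatch.fnmatchcase(str(n), pat) for n in names])
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# mapping operations
# ---------------------------------------------------------------------------

def _residue_groups(s: Structure):
    """Yield (chain, res_id, res_name, atom indices) in file order."""
    keys = list(zip(s.chains, s.res_ids))
    seen, order = {}, []
    for i, key in enumerate(keys):
        if key not in seen:
            seen[key] = len(order)
            order.append([key, []])
        order[seen[key]][1].append(i)
    for (chain, rid), idx in order:
        idx = np.array(idx, int)
        yield chain, int(rid), str(s.res_names[idx[0]]), idx


def map_protein(s: Structure, templates=None) -> CGModel:
    """Map an atomistic (or reduced-fixture) protein to CG beads.

    One backbone bead (BB) per residue at the centre of mass of the
    backbone atoms present (N, CA, C, O), 0–2 side-chain beads per the
    template, consecutive backbone beads bonded, BB–SC1–SC2 chain bonds
    within each residue.  Raises :class:`MappingError` listing any
    residue type missing from the template table.
    """
    backbone, table = (templates if templates is not None
                       else load_protein_templates())
    missing = sorted({str(r) for r in np.unique(s.res_names)} - set(table))
    if missing:
        raise MappingError(f"no bead template for residue(s): {', '.join(missing)}")

    names, resn, rid, chain, xyz, mass, charge, cls = ([] for _ in range(8))
    bonds, bb_idx = [], []
    prev_bb, nb = None, 0
    for ch, r, rn, idx in _residue_groups(s):
        sub_names = s.names[idx]
        bbi = idx[_match_parents(sub_names, backbone.parent_atoms)]
        if len(bbi) == 0:
            raise MappingError(f"residue {rn} {r}: no backbone atoms "
                               f"({','.join(backbone.parent_atoms)}) found")
        beads_here = [(backbone, bbi)]
        for bt in table[rn]:
            pi = idx[_match_parents(sub_names, bt.parent_atoms)]
            if len(pi):
                beads_here.append((bt, pi))
        first_of_res = nb
        for bt, pi in beads_here:
            m = s.masses[pi]
            w = m if m.sum() > 0 else np.ones(len(pi))
            names.append(bt.bead_name)
            resn.append(rn); rid.append(r); chain.append(ch)
            xyz.append((s.xyz[pi] * w[:, None]).sum(axis=0) / w.sum())
            mass.append(float(m.sum()) if m.sum() > 0 else 72.0)
            charge.append(bt.charge); cls.append(bt.bead_class)
            nb += 1
        bb_idx.append(first_of_res)
        # intra-residue chain: BB–SC1, SC1–SC2
        for k in range(first_of_res, nb - 1):
            r0 = float(np.linalg.norm(np.asarray(xyz[k + 1]) - np.asarray(xyz[k])))
            bonds.append((k, k + 1, r0, BACKBONE_BOND_K))
        if prev_bb is not None:
            r0 = float(np.linalg.norm(np.asarray(xyz[first_of_res])
                                      - np.asarray(xyz[prev_bb])))
            bonds.append((prev_bb, first_of_res, r0, BACKBONE_BOND_K))
        prev_bb = first_of_res

    beads = Structure(names, resn, rid, chain, np.array(xyz),
                      elements=["X"] * nb, masses=mass, charges=charge,
                      is_bead=[True] * nb,
                      box=None if s.box is None else s.box.copy(),
                      title=f"CG {s.title}".strip())
    return CGModel(beads, bonds, [], np.array(bb_idx, int),
                   np.empty(0, int), [], np.array(cls, object))


def map_lipid(s: Structure, template: LipidTemplate) -> CGModel:
    """Map atomistic lipids (all residues of the template species) to CG."""
    names, resn, rid, chain, xyz, mass, charge, cls = ([] for _ in range(8))
    bonds, angles, ph_idx = [], [], []
    nb = 0
    nlip = 0
    for ch, r, rn, idx in _residue_groups(s):
        if rn != template.res_name:
            raise MappingError(f"residue {rn} {r} does not match lipid "
                               f"template {template.res_name!r}")
        nlip += 1
        base = nb
        for bt in template.beads:
            pi = idx[_match_parents(s.names[idx], bt.parent_atoms)]
            if len(pi) == 0:
                raise MappingError(f"lipid {rn} {r}: no atoms match bead "
                                   f"{bt.bead_name} patterns "
                                   f"{','.join(bt.parent_atoms)}")
            m = s.masses[pi]
            w = m if m.sum() > 0 else np.ones(len(pi))
            names.append(bt.bead_name)
            resn.append(rn); rid.append(r); chain.append(ch)
            xyz.append((s.xyz[pi] * w[:, None]).sum(axis=0) / w.sum())
            mass.append(float(m.sum()) if m.sum() > 0 else bt.mass)
            charge.append(bt.charge); cls.append(bt.bead_class)
            if bt.bead_name == template.phosphate_bead:
                ph_idx.append(nb)
            nb += 1
        bonds += [(base + i, base + j, r0, k) for (i, j, r0, k) in template.bonds]
        angles += [(base + i, base + j, base + k, t, kt)
                   for (i, j, k, t, kt) in template.angles]

    beads = Structure(names, resn, rid, chain, np.array(xyz).reshape(nb, 3),
                      elements=["X"] * nb, masses=mass, charges=charge,
                      is_bead=[True] * nb,
                      box=None if s.box is None else s.box.copy(),
                      title=f"CG {template.res_name} x{nlip}")
    return CGModel(beads, bonds, angles, np.empty(0, int),
                   np.array(ph_idx, int), [], np.array(cls, object))


def map_water(n_aa_waters: int, *, spacing: float = 4.7,
              origin=(0.0, 0.0, 0.0)) -> CGModel:
    """Map ``n_aa_waters`` atomistic waters to ``n // 4`` neutral CG beads.

    Bead positions are a simple cubic lattice (``spacing`` Å) from
    ``origin`` — the count, class and mass are the mapping content;
    positions are placeholders for system building.
    """
    if n_aa_waters < 0:
        raise ValueError("water count must be ≥ 0")
    n = int(n_aa_waters) // 4
    side = max(1, int(np.ceil(n ** (1 / 3))))
    k = np.arange(n)
    xyz = (np.stack([k % side, (k // side) % side, k // side ** 2], axis=1)
           * spacing + np.asarray(origin, float))
    beads = Structure(["W"] * n, ["W"] * n, np.arange(1, n + 1),
                      ["W"] * n, xyz.reshape(n, 3), elements=["X"] * n,
                      masses=[DEFAULT_WATER_MASS] * n, charges=[0.0] * n,
                      is_bead=[True] * n, title=f"CG water x{n}")
    return CGModel(beads, [], [], np.empty(0, int), np.empty(0, int), [],
                   np.array(["W"] * n, object))
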