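"""Molecular structures, trajectories and selections.

This module is the common currency of the package: every other module
consumes and produces :class:`Structure` objects (ordered atoms or
coarse-grained beads with coordinates in Å and an optional periodic
box) and :class:`Trajectory` objects (a topology plus time-ordered
coordinate frames).

File formats
------------
* **PDB** — ``ATOM``/``HETATM``/``MODEL``/``CRYST1`` records; multi-MODEL
  files are read as trajectories.
* **GRO** — fixed-column GROMACS format; coordinates are stored in nm on
  disk and converted to Å on read (and back on write).
* **native trajectory** — a documented plain-text frame format
  (``MEMTRAJ`` header, per-frame time/box/xyz lines) used as the default
  trajectory write format; see :func:`write_trajectory`.

Parsing and writing of PDB and GRO delegate to :mod:`biotite`; this
module only adapts between biotite's ``AtomArray`` and the package's
:class:`Structure`.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .units import element_mass

__all__ = [
    "Atom", "Structure", "Frame", "Trajectory",
    "read_structure", "write_structure",
    "read_trajectory", "write_trajectory",
    "select", "ParseError", "SelectionError",
]


class ParseError(ValueError):
    """A structure/trajectory file did not parse under its format."""


class SelectionError(ValueError):
    """A selection expression is syntactically invalid."""


@dataclass
class Atom:
    """A single atom or coarse-grained bead (coordinates in Å)."""

    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    xyz: np.ndarray
    mass: float = 0.0
    charge: float = 0.0
    is_bead: bool = False


class Structure:
    """An ordered collection of atoms with an optional periodic box.

    Internally a struct-of-arrays: ``names``, ``elements``, ``res_names``,
    ``res_ids``, ``chains`` (object/int arrays of length ``n_atoms``),
    ``xyz`` (``(n_atoms, 3)`` float, Å), ``masses`` (amu), ``charges``
    (e), ``is_bead`` (bool).  ``box`` is ``(lx, ly, lz, alpha, beta,
    gamma)`` in Å / degrees, or ``None``.  Atom order is stable: a
    read → write round trip preserves it exactly.
    """

    def __init__(self, names, res_names, res_ids, chains, xyz, *,
                 elements=None, masses=None, charges=None, is_bead=None,
                 box=None, title=""):
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.res_names = np.asarray(res_names, dtype=object)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.xyz = np.array(xyz, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        self.elements = (np.asarray(elements, dtype=object) if elements is not None
                         else np.array([_guess_element(nm) for nm in self.names],
                                       dtype=object))
        self.masses = (np.array(masses, dtype=float) if masses is not None
                       else np.array([element_mass(e) for e in self.elements]))
        if np.any(self.masses < 0):
            raise ValueError("negative mass")
        self.charges = (np.array(charges, dtype=float) if charges is not None
                        else np.zeros(n))
        self.is_bead = (np.array(is_bead, dtype=bool) if is_bead is not None
                        else np.zeros(n, dtype=bool))
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None:
            if self.box.shape != (6,):
                raise ValueError("box must be (lx, ly, lz, alpha, beta, gamma)")
            if np.any(self.box[:3] <= 0):
                raise ValueError("box lengths must be positive")
        self.title = title

    # -- container protocol -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    def __getitem__(self, i: int) -> Atom:
        return Atom(self.names[i], self.elements[i], self.res_names[i],
                    int(self.res_ids[i]), self.chains[i], self.xyz[i].copy(),
                    float(self.masses[i]), float(self.charges[i]),
                    bool(self.is_bead[i]))

    @property
    def atoms(self):
        """List of :class:`Atom` views (copy; edit arrays for bulk changes)."""
        return [self[i] for i in range(self.n_atoms)]

    def __repr__(self):
        return (f"<Structure {self.n_atoms} atoms, "
                f"{len(np.unique(self.res_ids))} residue ids"
                + (", box" if self.box is not None else "") + ">")

    # -- manipulation -------------------------------------------------------
    def copy(self) -> "Structure":
        return Structure(self.names.copy(), self.res_names.copy(),
                         self.res_ids.copy(), self.chains.copy(),
                         self.xyz.copy(), elements=self.elements.copy(),
                         masses=self.masses.copy(), charges=self.charges.copy(),
                         is_bead=self.is_bead.copy(),
                         box=None if self.box is None else self.box.copy(),
                         title=self.title)

    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(self.names[idx], self.res_names[idx],
                         self.res_ids[idx], self.chains[idx], self.xyz[idx],
                         elements=self.elements[idx], masses=self.masses[idx],
                         charges=self.charges[idx], is_bead=self.is_bead[idx],
                         box=None if self.box is None else self.box.copy(),
                         title=self.title)

    @staticmethod
    def concat(parts: list["Structure"], box=None, title="") -> "Structure":
        """Concatenate structures (atom order: parts in the given order)."""
        if box is None:
            for p in parts:
                if p.box is not None:
                    box = p.box.copy()
                    break
        cat = lambda attr: np.concatenate([getattr(p, attr) for p in parts])
        return Structure(cat("names"), cat("res_names"), cat("res_ids"),
                         cat("chains"),
                         np.concatenate([p.xyz for p in parts], axis=0),
                         elements=cat("elements"), masses=cat("masses"),
                         charges=cat("charges"), is_bead=cat("is_bead"),
                         box=box, title=title)

    @staticmethod
    def from_atoms(atoms: list[Atom], box=None, title="") -> "Structure":
        return Structure([a.name for a in atoms], [a.res_name for a in atoms],
                         [a.res_id for a in atoms], [a.chain for a in atoms],
                         np.array([a.xyz for a in atoms], dtype=float),
                         elements=[a.element for a in atoms],
                         masses=[a.mass for a in atoms],
                         charges=[a.charge for a in atoms],
                         is_bead=[a.is_bead for a in atoms],
                         box=box, title=title)

    def center_of_mass(self, indices=None) -> np.ndarray:
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        m = self.masses[idx]
        if m.sum() <= 0:
            return self.xyz[idx].mean(axis=0)
        return (self.xyz[idx] * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class Frame:
    """One trajectory frame: coordinates (Å), box, time (fs)."""

    coords: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0


@dataclass
class Trajectory:
    """A topology plus time-ordered frames (same atom count each frame)."""

    topology: Structure
    frames: list[Frame] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def append(self, coords, box=None, time=0.0):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame has {coords.shape[0]} atoms, topology has "
                f"{self.topology.n_atoms}")
        if self.frames and time < self.frames[-1].time:
            raise ValueError("frame times must be non-decreasing")
        self.frames.append(Frame(coords.copy(),
                                 None if box is None else np.asarray(box, float),
                                 float(time)))

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_FORMATS = ("pdb", "gro")


def _infer_format(path, format=None):
    if format is not None:
        fmt = format.lower()
        if fmt not in _FORMATS + ("memtraj",):
            raise ValueError(f"unknown format {format!r}; expected PDB or GRO")
        return fmt
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext in _FORMATS:
        return ext
    if ext in ("mtrj", "memtraj", "traj"):
        return "memtraj"
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def _guess_element(name: str) -> str:
    stripped = re.sub(r"[^A-Za-z]", "", str(name))
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ("CL", "NA", "MG", "ZN", "FE", "BR"):
        return two
    return stripped[0].upper()


def _locate_bad_line(path, fmt):
    """Best-effort scan for the first malformed record, for error messages."""
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if fmt == "pdb" and line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                        int(line[22:26])
                    except (ValueError, IndexError):
                        return ln
                if fmt == "gro" and ln == 2:
                    try:
                        int(line.split()[0])
                    except (ValueError, IndexError):
                        return ln
    except OSError:
        return None
    return None


def _structure_from_atom_array(arr, title="", is_bead=False) -> Structure:
    box = None
    if arr.box is not None:
        a, b, c, al, be, ga = struc.unitcell_from_vectors(arr.box)
        box = np.array([a, b, c, np.degrees(al), np.degrees(be), np.degrees(ga)])
    elements = [e if e else _guess_element(n)
                for e, n in zip(arr.element, arr.atom_name)]
    return Structure(arr.atom_name, arr.res_name, arr.res_id, arr.chain_id,
                     arr.coord, elements=elements, box=box, title=title,
                     is_bead=np.full(arr.array_length(), is_bead, dtype=bool))


def read_structure(path, format: str | None = None, *,
                   model: int = 1, is_bead: bool = False) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure` (coordinates in Å).

    GRO coordinates (nm on disk) are converted to Å; the box, when
    present, is captured as lengths (Å) and angles (degrees).  ``model``
    picks one MODEL of a multi-model PDB (1-based).  ``is_bead`` marks
    every atom as a coarse-grained bead (formats carry no such flag).
    """
    fmt = _infer_format(path, format)
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"{fmt!r} is a trajectory format; use read_trajectory")
    try:
        if fmt == "pdb":
            f = PDBFile.read(str(path))
            arr = f.get_structure(model=model)
        else:
            f = GROFile.read(str(path))
            arr = f.get_structure(model=model)
    except Exception as exc:
        ln = _locate_bad_line(path, fmt)
        where = f" at line {ln}" if ln else ""
        raise ParseError(f"malformed {fmt.upper()} record in {path}{where}: {exc}") from exc
    return _structure_from_atom_array(arr, title=os.path.basename(str(path)),
                                      is_bead=is_bead)


def _atom_array_from_structure(s: Structure):
    arr = struc.AtomArray(s.n_atoms)
    arr.atom_name = np.array([str(n) for n in s.names], dtype="U6")
    arr.res_name = np.array([str(n) for n in s.res_names], dtype="U5")
    arr.res_id = s.res_ids.astype(int)
    arr.chain_id = np.array([str(c) if c else "A" for c in s.chains], dtype="U4")
    arr.element = np.array([str(e) for e in s.elements], dtype="U2")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.coord = s.xyz.astype(np.float32)
    if s.box is not None:
        lx, ly, lz, al, be, ga = s.box
        arr.box = struc.vectors_from_unitcell(
            lx, ly, lz, np.radians(al), np.radians(be), np.radians(ga))
    return arr


def write_structure(s: Structure, path, format: str | None = None) -> None:
    """Write a :class:`Structure` as PDB or GRO (GRO converts Å → nm)."""
    fmt = _infer_format(path, format)
    arr = _atom_array_from_structure(s)
    if fmt == "pdb":
        f = PDBFile()
        f.set_structure(arr)
    elif fmt == "gro":
        f = GROFile()
        f.set_structure(arr)
    else:
        raise ValueError("use write_trajectory for trajectory formats")
    f.write(str(path))


# -- native plain-text trajectory format ------------------------------------
#
#   MEMTRAJ 1
#   FRAME <time_fs> <natoms>
#   BOX <lx> <ly> <lz> <alpha> <beta> <gamma>     (or: BOX none)
#   <x> <y> <z>                                    (natoms lines, Å)
#   FRAME ...

def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory: native text (default) or multi-MODEL PDB."""
    fmt = _infer_format(path, format) if format or "." in str(path) else "memtraj"
    if fmt == "pdb":
        arrs = []
        for fr in traj.frames:
            s = traj.topology.copy()
            s.xyz = fr.coords
            s.box = fr.box
            arrs.append(_atom_array_from_structure(s))
        stack = struc.stack(arrs)
        f = PDBFile()
        f.set_structure(stack)
        f.write(str(path))
        return
    with open(path, "w") as fh:
        fh.write("MEMTRAJ 1\n")
        for fr in traj.frames:
            fh.write(f"FRAME {fr.time:.6g} {fr.coords.shape[0]}\n")
            if fr.box is None:
                fh.write("BOX none\n")
            else:
                fh.write("BOX " + " ".join(f"{v:.6f}" for v in fr.box) + "\n")
            np.savetxt(fh, fr.coords, fmt="%.6f")


def read_trajectory(path, topology: Structure | None = None,
                    format: str | None = None) -> Trajectory:
    """Read a native-format or multi-MODEL PDB trajectory."""
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        f = PDBFile.read(str(path))
        stack = f.get_structure()
        top = _structure_from_atom_array(stack[0] if stack.stack_depth() > 0
                                         else stack, title=os.path.basename(str(path)))
        traj = Trajectory(top)
        for i in range(stack.stack_depth()):
            traj.append(stack.coord[i], box=top.box, time=float(i))
        return traj
    if fmt == "gro":
        raise ValueError("GRO trajectories are not supported; use PDB or native")
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "MEMTRAJ":
            raise ParseError(f"{path}: not a MEMTRAJ file (line 1)")
        frames = []
        ln = 1
        for line in fh:
            ln += 1
            parts = line.split()
            if not parts:
                continue
            if parts[0] != "FRAME":
                raise ParseError(f"{path}: expected FRAME at line {ln}")
            time, natoms = float(parts[1]), int(parts[2])
            boxparts = fh.readline().split()
            ln += 1
            if boxparts[0] != "BOX":
                raise ParseError(f"{path}: expected BOX at line {ln}")
            box = (None if boxparts[1] == "none"
                   else np.array([float(v) for v in boxparts[1:7]]))
            coords = np.empty((natoms, 3))
            for i in range(natoms):
                ln += 1
                try:
                    coords[i] = [float(v) for v in fh.readline().split()[:3]]
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: bad coordinate line {ln}") from exc
            frames.append(Frame(coords, box, time))
    if topology is None:
        raise ValueError("native trajectory format requires a topology Structure")
    traj = Trajectory(topology)
    for fr in frames:
        traj.append(fr.coords, fr.box, fr.time)
    return traj


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def select(s: Structure, expr: str) -> np.ndarray:
    """Evaluate a selection expression, returning ascending atom indices.

    Grammar (case-insensitive keywords)::

        expr     := term ("or" term)*
        term     := factor ("and" factor)*
        factor   := "not" factor | "(" expr ")" | predicate
        predicate:= "resid" range+ | "name" pattern+ | "chain" id+
                  | "resname" pattern+ | "all" | "none"
        range    := N | N-M          (inclusive)
        pattern  := glob (fnmatch: CA, C*, SC?)

    Selection is purely predicate-based — coordinates never enter — so
    it is idempotent and monotone under subsetting.
    """
    tokens = _TOKEN_RE.findall(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask, pos = _parse_or(s, tokens, 0)
    if pos != len(tokens):
        raise SelectionError(f"trailing tokens in selection: {' '.join(tokens[pos:])}")
    return np.flatnonzero(mask)


_KEYWORDS = {"and", "or", "not", "resid", "name", "chain", "resname",
             "all", "none", "(", ")"}


def _parse_or(s, toks, pos):
    mask, pos = _parse_and(s, toks, pos)
    while pos < len(toks) and toks[pos].lower() == "or":
        rhs, pos = _parse_and(s, toks, pos + 1)
        mask = mask | rhs
    return mask, pos


def _parse_and(s, toks, pos):
    mask, pos = _parse_factor(s, toks, pos)
    while pos < len(toks) and toks[pos].lower() == "and":
        rhs, pos = _parse_factor(s, toks, pos + 1)
        mask = mask & rhs
    return mask, pos


def _parse_factor(s, toks, pos):
    if pos >= len(toks):
        raise SelectionError("unexpected end of selection expression")
    tok = toks[pos].lower()
    if tok == "not":
        mask, pos = _parse_factor(s, toks, pos + 1)
        return ~mask, pos
    if tok == "(":
        mask, pos = _parse_or(s, toks, pos + 1)
        if pos >= len(toks) or toks[pos] != ")":
            raise SelectionError("unbalanced parenthesis in selection")
        return mask, pos + 1
    if tok == "all":
        return np.ones(s.n_atoms, dtype=bool), pos + 1
    if tok == "none":
        return np.zeros(s.n_atoms, dtype=bool), pos + 1
    if tok in ("resid", "name", "chain", "resname"):
        args, end = [], pos + 1
        while end < len(toks) and toks[end].lower() not in _KEYWORDS:
            args.append(toks[end])
            end += 1
        if not args:
            raise SelectionError(f"'{tok}' needs at least one argument")
        return _predicate(s, tok, args), end
    raise SelectionError(f"unexpected token {toks[pos]!r} in selection")


def _predicate(s, kind, args):
    import fnmatch
    if kind == "resid":
        mask = np.zeros(s.n_atoms, dtype=bool)
        for a in args:
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", a)
            if not m:
                raise SelectionError(f"bad resid range {a!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            mask |= (s.res_ids >= lo) & (s.res_ids <= hi)
        return mask
    attr = {"name": s.names, "chain": s.chains, "resname": s.res_names}[kind]
    vals = np.array([str(v) for v in attr])
    mask = np.zeros(s.n_atoms, dtype=bool)
    for pat in args:
        mask |= np.array([fnmatch.fnmatchcase(v, pat) for v in vals])
    return mask
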