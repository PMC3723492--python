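"""Consistency scoring between structural models and H/D-exchange data.

Deuterium-exchange mass spectrometry (DXMS) reports, per proteolytic
fragment, the percent decrement in deuteration when the protein binds a
membrane: a large decrement means the fragment became protected
(buried at the interface), a small one partial protection, none that it
stayed solvent-exposed.  This module derives a per-residue burial
fraction from a trajectory (depth below the proximal phosphate plane,
or a SASA criterion for atomistic models) and scores fragment-level
agreement: strongly protected fragments should be predicted buried,
unprotected ones exposed, and weak/intermediate fragments partially
buried (half-weight).  The fragment-matching score itself is this
package's construction — exchange data are qualitative — and every
threshold is exposed as a parameter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Trajectory
from .analysis import BACKBONE_NAMES

__all__ = [
    "DxmsFragment", "BurialProfile", "read_fragments", "classify_fragments",
    "burial_profile", "consistency_score",
    "STRONG_THRESHOLD", "WEAK_THRESHOLD",
]

STRONG_THRESHOLD = 70.0   # % decrement: ≥ → strong protection
WEAK_THRESHOLD = 40.0     # % decrement: (0, 40) → weak protection


@dataclass
class DxmsFragment:
    """One exchange fragment: residue range + decrement + incubation."""

    res_start: int
    res_end: int
    decrement_pct: float
    incubation: float = 300.0
    frag_class: str = ""

    def __post_init__(self):
        if self.res_start > self.res_end:
            raise ValueError("res_start must be ≤ res_end")
        if not 0 <= self.decrement_pct <= 100:
            raise ValueError("decrement must be within [0, 100] %")

    @property
    def residues(self):
        return range(self.res_start, self.res_end + 1)


def read_fragments(source) -> list[DxmsFragment]:
    """Parse the TSV fragment format (res_start, res_end, decrement_pct,
    incubation_s); ``source`` may be a path or TSV text."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    return [DxmsFragment(int(r.res_start), int(r.res_end),
                         float(r.decrement_pct), float(r.incubation_s))
            for r in df.itertuples()]


def classify_fragments(fragments) -> list[DxmsFragment]:
    """Assign protection classes from the decrement thresholds.

    ≥ 70 % → ``strong``; 0 % → ``none``; (0, 40) % → ``weak``;
    [40, 70) % → ``intermediate``.  Returns the same fragments with
    ``frag_class`` filled.
    """
    for f in fragments:
        d = f.decrement_pct
        if d >= STRONG_THRESHOLD:
            f.frag_class = "strong"
        elif d == 0:
            f.frag_class = "none"
        elif d < WEAK_THRESHOLD:
            f.frag_class = "weak"
        else:
            f.frag_class = "intermediate"
    return list(fragments)


@dataclass
class BurialProfile:
    """Per-residue fraction of frames buried, plus the burial rule used."""

    fractions: dict            # res_id -> fraction in [0, 1]
    rule: str = "depth"

    def __post_init__(self):
        for rid, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"burial fraction of residue {rid} "
                                 "outside [0, 1]")

    def mean_over(self, residues):
        vals = [self.fractions[r] for r in residues if r in self.fractions]
        return float(np.mean(vals)) if vals else None


def burial_profile(traj: Trajectory, mfs=None, mode: str = "depth", *,
                   protein_indices=None, sasa_threshold: float = 15.0
                   ) -> BurialProfile:
    """Fraction of frames in which each protein residue is buried.

    ``depth`` mode: a residue is buried in a frame when its side-chain
    centre of mass lies below the proximal leaflet's mean phosphate
    plane (the leaflet on the protein's side of the bilayer centre);
    requires one :class:`~memscale.analysis.MembraneFrame` per frame.
    ``sasa`` mode: buried when the residue's solvent-accessible surface
    area (1.4 Å probe) falls below ``sasa_threshold`` Å²; needs an
    atomistic topology (raises for bead models, suggesting depth mode).
    """
    top = traj.topology
    if protein_indices is None:
        lipidish = {"W", "HOH", "NA", "CL", "POPC", "TOY4", "TOY3"}
        protein_indices = np.flatnonzero(
            np.array([str(r) not in lipidish for r in top.res_names]))
    protein_indices = np.asarray(protein_indices, int)
    res_ids = sorted({int(top.res_ids[i]) for i in protein_indices})

    if mode == "sasa":
        if np.any(top.is_bead[protein_indices]):
            raise ValueError("SASA burial needs an atomistic model; use "
                             "mode='depth' for bead models")
        return _burial_sasa(traj, protein_indices, res_ids, sasa_threshold)
    if mode != "depth":
        raise ValueError(f"unknown burial mode {mode!r}")
    if mfs is None:
        raise ValueError("depth mode requires membrane frames")

    sc_by_res = {}
    for rid in res_ids:
        sel = protein_indices[top.res_ids[protein_indices] == rid]
        sc = sel[[str(top.names[i]) not in BACKBONE_NAMES for i in sel]]
        sc_by_res[rid] = sc if sc.size else sel
    buried = {rid: 0 for rid in res_ids}
    for f, fr in enumerate(traj.frames):
        mf = mfs[f]
        prot_z = float(np.mean(fr.coords[protein_indices, 2]))
        side = 1.0 if prot_z >= mf.center_z else -1.0
        plane = mf.phosphate_z_upper if side > 0 else mf.phosphate_z_lower
        for rid, sc in sc_by_res.items():
            w = top.masses[sc]
            if w.sum() <= 0:
                w = np.ones(sc.size)
            z = float(np.average(fr.coords[sc, 2], weights=w))
            if side * (z - plane) < 0:        # deeper than the phosphate plane
                buried[rid] += 1
    n = max(traj.n_frames, 1)
    return BurialProfile({r: c / n for r, c in buried.items()},
                         rule="depth: side-chain c.o.m. below proximal "
                              "phosphate plane")


def _burial_sasa(traj, protein_indices, res_ids, threshold):
    import biotite.structure as struc
    from .structure_io import _atom_array_from_structure

    top = traj.topology.subset(protein_indices)
    counts = {rid: 0 for rid in res_ids}
    for fr in traj.frames:
        s = top.copy()
        s.xyz = fr.coords[protein_indices]
        arr = _atom_array_from_structure(s)
        sasa = struc.sasa(arr, vdw_radii="Single", point_number=100)
        for rid in res_ids:
            val = float(np.nansum(sasa[arr.res_id == rid]))
            if val < threshold:
                counts[rid] += 1
    n = max(traj.n_frames, 1)
    return BurialProfile({r: c / n for r, c in counts.items()},
                         rule=f"sasa < {threshold} Å² (1.4 Å probe)")


def consistency_score(bp: BurialProfile, fragments, *,
                      burial_threshold: float = 0.5):
    """Fragment-level agreement between burial and exchange protection.

    A fragment is predicted *protected* when the mean burial fraction
    over its residues is ≥ ``burial_threshold``.  Matching: strong ↔
    predicted-protected and none ↔ predicted-exposed count with weight
    1; weak/intermediate fragments count with weight ½ and match when
    partially buried (0 < mean < threshold).  Fragments with no residue
    covered by the profile are listed unscored.  Returns
    ``(match_table, overall_score)`` with score = Σ matched weight /
    Σ weight.
    """
    fragments = classify_fragments(fragments)
    rows = []
    got, tot = 0.0, 0.0
    for fr in fragments:
        mean = bp.mean_over(fr.residues)
        if mean is None:
            rows.append({"res_start": fr.res_start, "res_end": fr.res_end,
                         "frag_class": fr.frag_class, "mean_burial": np.nan,
                         "weight": 0.0, "matched": np.nan})
            continue
        if fr.frag_class == "strong":
            weight, matched = 1.0, mean >= burial_threshold
        elif fr.frag_class == "none":
            weight, matched = 1.0, mean < burial_threshold
        else:   # weak / intermediate: partial burial expected
            weight, matched = 0.5, 0.0 < mean < burial_threshold
        rows.append({"res_start": fr.res_start, "res_end": fr.res_end,
                     "frag_class": fr.frag_class, "mean_burial": mean,
                     "weight": weight, "matched": bool(matched)})
        tot += weight
        got += weight if matched else 0.0
    table = pd.DataFrame(rows)
    score = got / tot if tot > 0 else float("nan")
    return table, float(score)
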