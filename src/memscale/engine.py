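"""Minimal coarse-grained molecular-dynamics engine.

Implements the desk-scale CG simulation protocol: shift-function
Lennard-Jones and screened Coulomb nonbonded interactions (force and
energy smoothly zero at 12 Å; LJ shifted over 9–12 Å, Coulomb over
0–12 Å, relative dielectric 15), harmonic bonds/angles plus the elastic
network, leapfrog integration at 25 fs, the stochastic velocity-rescaling
(Bussi) thermostat, a Berendsen anisotropic barostat, steepest-descent
minimization, and minimum-image periodic boundaries in orthorhombic
boxes.

Shift function
--------------
For an inverse-power term 1/r^α the shifted kernel is the standard
cubic/quartic force-shift polynomial: for r₁ ≤ r ≤ r_c

    F(r) = α/r^(α+1) + A (r−r₁)² + B (r−r₁)³
    V(r) = 1/r^α − (A/3)(r−r₁)³ − (B/4)(r−r₁)⁴ − C

with A, B solved from F(r_c) = F'(r_c) = 0 and C from V(r_c) = 0, so
energy and force are continuous everywhere and vanish at the cutoff.
The coefficients are solved numerically at construction from those
boundary conditions.

Units: Å, fs, amu, kJ mol⁻¹ (see :mod:`memscale.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Trajectory
from .mapping import CGModel
from .units import KB, COULOMB_K, ACCEL, KE2KJ, P2BAR

__all__ = [
    "ForceField", "IntegratorConfig", "SimulationState", "ShiftKernel",
    "load_forcefield", "lj_shifted", "coulomb_shifted",
    "compute_forces", "ForceCalculator", "steepest_descent", "run_md",
    "initialize_velocities", "detect_anchoring", "AnchoringEvent",
    "IntegrationError", "MinimizationError",
]


class IntegrationError(RuntimeError):
    """The integrator left the physically meaningful regime."""


class MinimizationError(RuntimeError):
    """Steepest descent could not obtain a finite energy."""


# ---------------------------------------------------------------------------
# shifted nonbonded kernels
# ---------------------------------------------------------------------------

class ShiftKernel:
    """Force-shifted 1/r^α kernel over the window (r1, rc)."""

    def __init__(self, alpha: int, r1: float, rc: float):
        if not 0 <= r1 < rc:
            raise ValueError("window requires 0 <= r1 < rc")
        self.alpha, self.r1, self.rc = alpha, float(r1), float(rc)
        d = rc - r1
        # F(rc) = 0 and F'(rc) = 0
        m = np.array([[d ** 2, d ** 3], [2 * d, 3 * d ** 2]])
        rhs = np.array([-alpha / rc ** (alpha + 1),
                        alpha * (alpha + 1) / rc ** (alpha + 2)])
        self.A, self.B = np.linalg.solve(m, rhs)
        self.C = (1.0 / rc ** alpha
                  - self.A / 3 * d ** 3 - self.B / 4 * d ** 4)

    def __call__(self, r):
        """Return (phi, dphi) with V = phi and scalar force F = dphi = −dV/dr."""
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("r must be positive")
        inside = r < self.rc
        rr = np.where(inside, r, 1.0)      # dummy beyond cutoff
        t = np.clip(rr - self.r1, 0.0, None)
        phi = (rr ** -self.alpha
               - self.A / 3 * t ** 3 - self.B / 4 * t ** 4 - self.C)
        dphi = (self.alpha * rr ** -(self.alpha + 1)
                + self.A * t ** 2 + self.B * t ** 3)
        return np.where(inside, phi, 0.0), np.where(inside, dphi, 0.0)


_CLASSES = ("P", "N", "C", "Q", "W")


@dataclass
class ForceField:
    """Nonbonded class table + shift windows + dielectric.

    ``eps``/``sigma`` are symmetric matrices over the bead classes
    ``classes``; ``eps_r`` is the uniform relative dielectric (default
    15); LJ is shifted over ``lj_window`` = (9, 12) Å and Coulomb over
    ``coul_window`` = (0, 12) Å.
    """

    classes: tuple = _CLASSES
    eps: np.ndarray = None
    sigma: np.ndarray = None
    eps_r: float = 15.0
    lj_window: tuple = (9.0, 12.0)
    coul_window: tuple = (0.0, 12.0)
    class_mass: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eps_r <= 0:
            raise ValueError("eps_r must be positive")
        for lo, hi in (self.lj_window, self.coul_window):
            if not lo < hi:
                raise ValueError("shift window lower bound must be < upper")
        if self.eps is not None and (np.any(self.eps < 0)
                                     or np.any(self.sigma <= 0)):
            raise ValueError("require ε ≥ 0 and σ > 0")
        self._k12 = ShiftKernel(12, *self.lj_window)
        self._k6 = ShiftKernel(6, *self.lj_window)
        self._k1 = ShiftKernel(1, *self.coul_window)

    @property
    def cutoff(self) -> float:
        return max(self.lj_window[1], self.coul_window[1])

    def class_index(self, labels) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([lut[str(c)] for c in labels], int)
        except KeyError as exc:
            raise ValueError(f"bead class {exc} not in force field") from exc

    def lj_shifted(self, r, eps, sigma):
        """Shifted 12-6 LJ: (energy kJ mol⁻¹, scalar force kJ mol⁻¹ Å⁻¹)."""
        p12, f12 = self._k12(r)
        p6, f6 = self._k6(r)
        s6 = np.asarray(sigma, float) ** 6
        e = 4.0 * np.asarray(eps, float)
        return e * (s6 * s6 * p12 - s6 * p6), e * (s6 * s6 * f12 - s6 * f6)

    def coulomb_shifted(self, r, q_i, q_j):
        """Shifted screened Coulomb: (energy, scalar force)."""
        p1, f1 = self._k1(r)
        pref = COULOMB_K / self.eps_r * np.asarray(q_i, float) * np.asarray(q_j, float)
        return pref * p1, pref * f1


def load_forcefield(text: str | None = None, **overrides) -> ForceField:
    """Load the packaged toy force field (or a table in the same format)."""
    if text is None:
        text = resources.files("memscale.data").joinpath(
            "toy_forcefield.txt").read_text()
    lut = {c: i for i, c in enumerate(_CLASSES)}
    n = len(_CLASSES)
    eps = np.full((n, n), np.nan)
    sig = np.full((n, n), np.nan)
    masses = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "PAIR":
            i, j = lut[parts[1]], lut[parts[2]]
            eps[i, j] = eps[j, i] = float(parts[3])
            sig[i, j] = sig[j, i] = float(parts[4])
        elif parts[0] == "MASS":
            masses[parts[1]] = float(parts[2])
    # Lorentz-Berthelot fallback for unlisted pairs
    for i in range(n):
        for j in range(n):
            if np.isnan(eps[i, j]):
                eps[i, j] = np.sqrt(eps[i, i] * eps[j, j])
                sig[i, j] = 0.5 * (sig[i, i] + sig[j, j])
    return ForceField(_CLASSES, eps, sig, class_mass=masses, **overrides)


def lj_shifted(r, eps, sigma, window=(9.0, 12.0)):
    """Module-level shifted LJ with the default 9–12 Å window."""
    ff = ForceField(lj_window=window)
    return ff.lj_shifted(r, eps, sigma)


def coulomb_shifted(r, q_i, q_j, eps_r=15.0, window=(0.0, 12.0)):
    """Module-level shifted Coulomb with the default 0–12 Å window."""
    ff = ForceField(eps_r=eps_r, coul_window=window)
    return ff.coulomb_shifted(r, q_i, q_j)


# ---------------------------------------------------------------------------
# state / configuration
# ---------------------------------------------------------------------------

@dataclass
class IntegratorConfig:
    """Integrator, thermostat and barostat settings."""

    dt: float = 25.0                 # fs
    temperature: float = 323.0       # K
    thermostat: bool = True
    thermostat_tau: float = 1000.0   # fs
    barostat: str = "off"            # off | berendsen
    p_ref: float = 1.0               # bar
    barostat_tau: float = 10.0       # ps
    compressibility: float = 3.0e-5  # bar⁻¹
    anisotropic: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.temperature <= 0 or self.barostat_tau <= 0:
            raise ValueError("dt, temperature and barostat_tau must be positive")
        if self.barostat not in ("off", "berendsen"):
            raise ValueError("barostat must be 'off' or 'berendsen'")


@dataclass
class SimulationState:
    """Coordinates (Å), velocities (Å fs⁻¹), box lengths (Å), time (fs)."""

    coords: np.ndarray
    velocities: np.ndarray = None
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.array(self.coords, float)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.coords)
        else:
            self.velocities = np.array(self.velocities, float)
        if self.box is not None:
            self.box = np.array(self.box, float).reshape(3)

    def copy(self):
        return SimulationState(self.coords.copy(), self.velocities.copy(),
                               None if self.box is None else self.box.copy(),
                               self.time)


def initialize_velocities(state: SimulationState, masses, temperature: float,
                          seed: int) -> None:
    """Maxwell–Boltzmann velocities at ``temperature``, COM motion removed."""
    rng = np.random.default_rng(seed)
    m = np.asarray(masses, float)
    sigma = np.sqrt(KB * temperature / (m * KE2KJ))
    v = rng.standard_normal(state.coords.shape) * sigma[:, None]
    v -= (v * m[:, None]).sum(axis=0) / m.sum()
    state.velocities = v


# ---------------------------------------------------------------------------
# force evaluation
# ---------------------------------------------------------------------------

def _min_image(d, box):
    if box is not None:
        d -= box * np.round(d / box)
    return d


class ForceCalculator:
    """Cached topology + neighbor list for repeated force evaluations.

    The neighbor list is built with a KD-tree over the periodically
    wrapped coordinates using cutoff + ``skin`` (2 Å) and rebuilt when
    any bead has moved more than skin/2 since the last build (or the
    box changed by > 0.5 %).  Nonbonded interactions are excluded for
    directly bonded pairs and angle 1–3 pairs.
    """

    SKIN = 2.0

    def __init__(self, cg: CGModel, ff: ForceField):
        self.cg, self.ff = cg, ff
        self.masses = cg.beads.masses.copy()
        self.charges = cg.beads.charges.copy()
        self.cls = ff.class_index(cg.bead_classes)
        excl = {self._key(i, j) for (i, j, *_r) in cg.bonds}
        excl |= {self._key(i, k) for (i, _j, k, *_r) in cg.angles}
        n = cg.n_beads
        self.excl = excl
        self._excl_codes = np.array(sorted(i * n + j for i, j in excl),
                                    dtype=np.int64)
        b = cg.bonds
        self.b_i = np.array([x[0] for x in b], int)
        self.b_j = np.array([x[1] for x in b], int)
        self.b_r0 = np.array([x[2] for x in b], float)
        self.b_k = np.array([x[3] for x in b], float)
        a = cg.angles
        self.a_i = np.array([x[0] for x in a], int)
        self.a_j = np.array([x[1] for x in a], int)
        self.a_k = np.array([x[2] for x in a], int)
        self.a_t0 = np.radians([x[3] for x in a])
        self.a_kt = np.array([x[4] for x in a], float)
        e = cg.elastic_bonds
        self.e_i = np.array([x.i for x in e], int)
        self.e_j = np.array([x.j for x in e], int)
        self.e_r0 = np.array([x.r0 for x in e], float)
        self.e_k = np.array([x.k for x in e], float)
        self._pairs = None
        self._ref = None
        self._ref_box = None

    @property
    def n(self):
        return self.cg.n_beads

    @staticmethod
    def _key(i, j):
        return (i, j) if i < j else (j, i)

    # -- neighbor list ------------------------------------------------------
    def _build_pairs(self, coords, box):
        rc = self.ff.cutoff + self.SKIN
        if box is not None:
            if np.any(box < 2 * self.ff.cutoff):
                raise ValueError("box must exceed twice the cutoff in "
                                 "every dimension")
            wrapped = np.mod(coords, box)
            wrapped[wrapped >= box] = 0.0
            tree = cKDTree(wrapped, boxsize=box)
        else:
            tree = cKDTree(coords)
        pairs = tree.query_pairs(rc, output_type="ndarray")
        if len(pairs) and len(self._excl_codes):
            lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
            hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
            codes = lo * self.n + hi
            pairs = pairs[~np.isin(codes, self._excl_codes,
                                   assume_unique=False)]
        self._pairs = pairs.astype(int).reshape(-1, 2)
        pi, pj = self._pairs[:, 0], self._pairs[:, 1]
        self._p_eps = self.ff.eps[self.cls[pi], self.cls[pj]]
        self._p_sig = self.ff.sigma[self.cls[pi], self.cls[pj]]
        self._p_eps4 = 4.0 * self._p_eps
        self._p_sig2 = self._p_sig ** 2
        self._p_sig6 = self._p_sig ** 6
        self._p_qq = self.charges[pi] * self.charges[pj]
        self._p_hasq = np.any(self._p_qq != 0)
        self._ref = coords.copy()
        self._ref_box = None if box is None else box.copy()

    def _needs_rebuild(self, coords, box):
        if self._pairs is None:
            return True
        if (box is None) != (self._ref_box is None):
            return True
        if box is not None and np.any(np.abs(box / self._ref_box - 1) > 0.005):
            return True
        disp = coords - self._ref
        return bool(np.any(np.abs(disp) > self.SKIN / 2))

    # -- evaluation ---------------------------------------------------------
    def __call__(self, coords, box):
        """Return (total energy, forces (N,3), virial diagonal (3,), parts)."""
        n = self.n
        coords = np.asarray(coords, float)
        forces = np.zeros((n, 3))
        virial = np.zeros(3)
        parts = {}

        if self._needs_rebuild(coords, box):
            self._build_pairs(coords, box)
        pi, pj = self._pairs[:, 0], self._pairs[:, 1]
        d = _min_image(coords[pj] - coords[pi], box)
        r2 = np.einsum("ij,ij->i", d, d)
        rc2 = self.ff.cutoff ** 2
        m = r2 < rc2
        if np.any(m):
            # fused shifted-LJ (+ Coulomb) evaluation; algebra identical to
            # ForceField.lj_shifted / coulomb_shifted, vectorized per pair
            dm, rim, rjm = d[m], pi[m], pj[m]
            r2m = r2[m]
            r = np.sqrt(r2m)
            inv2 = 1.0 / r2m
            s2 = self._p_sig2[m] * inv2
            sr6 = s2 * s2 * s2
            sr12 = sr6 * sr6
            eps4 = self._p_eps4[m]
            sig6 = self._p_sig6[m]
            sig12 = sig6 * sig6
            k12, k6 = self.ff._k12, self.ff._k6
            t = np.clip(r - k12.r1, 0.0, None)
            t2 = t * t
            t3 = t2 * t
            t4 = t3 * t
            e_lj = eps4 * (sr12 - sr6
                           - sig12 * (k12.A / 3 * t3 + k12.B / 4 * t4 + k12.C)
                           + sig6 * (k6.A / 3 * t3 + k6.B / 4 * t4 + k6.C))
            fmag = eps4 * ((12 * sr12 - 6 * sr6) / r
                           + sig12 * (k12.A * t2 + k12.B * t3)
                           - sig6 * (k6.A * t2 + k6.B * t3))
            e_nb = e_lj.sum()
            if self._p_hasq:
                k1 = self.ff._k1
                tc = np.clip(r - k1.r1, 0.0, None)
                pref = (COULOMB_K / self.ff.eps_r) * self._p_qq[m]
                e_nb += np.sum(pref * (1.0 / r - k1.A / 3 * tc ** 3
                                       - k1.B / 4 * tc ** 4 - k1.C))
                fmag = fmag + pref * (1.0 / r2m + k1.A * tc ** 2
                                      + k1.B * tc ** 3)
            fvec = (fmag / r)[:, None] * dm
            self._scatter(forces, rjm, rim, fvec)
            virial += np.einsum("ij,ij->j", dm, fvec)
            parts["nonbonded"] = float(e_nb)
        else:
            parts["nonbonded"] = 0.0

        for label, (bi, bj, r0, k) in (
                ("bond", (self.b_i, self.b_j, self.b_r0, self.b_k)),
                ("elastic", (self.e_i, self.e_j, self.e_r0, self.e_k))):
            if len(bi) == 0:
                parts[label] = 0.0
                continue
            d = _min_image(coords[bj] - coords[bi], box)
            r = np.linalg.norm(d, axis=1)
            parts[label] = float(np.sum(0.5 * k * (r - r0) ** 2))
            fvec = (-k * (r - r0) / r)[:, None] * d
            self._scatter(forces, bj, bi, fvec)
            virial += np.einsum("ij,ij->j", d, fvec)

        parts["angle"] = self._angles(coords, box, forces, virial)
        energy = float(sum(parts.values()))
        return energy, forces, virial, parts

    @staticmethod
    def _scatter(forces, idx_plus, idx_minus, fvec):
        n = forces.shape[0]
        for a in range(3):
            forces[:, a] += (np.bincount(idx_plus, fvec[:, a], minlength=n)
                             - np.bincount(idx_minus, fvec[:, a], minlength=n))

    def _angles(self, coords, box, forces, virial):
        if len(self.a_i) == 0:
            return 0.0
        u = _min_image(coords[self.a_i] - coords[self.a_j], box)
        v = _min_image(coords[self.a_k] - coords[self.a_j], box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.clip(1 - cos ** 2, 1e-12, None))
        dtheta = theta - self.a_t0
        c = self.a_kt * dtheta / sin
        fi = c[:, None] * (v / (nu * nv)[:, None] - (cos / nu ** 2)[:, None] * u)
        fk = c[:, None] * (u / (nu * nv)[:, None] - (cos / nv ** 2)[:, None] * v)
        n = forces.shape[0]
        for a in range(3):
            forces[:, a] += (np.bincount(self.a_i, fi[:, a], minlength=n)
                             + np.bincount(self.a_k, fk[:, a], minlength=n)
                             - np.bincount(self.a_j, fi[:, a] + fk[:, a],
                                           minlength=n))
        virial += np.einsum("ij,ij->j", u, fi) + np.einsum("ij,ij->j", v, fk)
        return float(np.sum(0.5 * self.a_kt * dtheta ** 2))


def compute_forces(state: SimulationState, cg: CGModel, ff: ForceField):
    """One-shot force evaluation: (total energy, forces, virial diagonal)."""
    calc = ForceCalculator(cg, ff)
    e, f, w, _ = calc(state.coords, state.box)
    return e, f, w


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def steepest_descent(state: SimulationState, cg: CGModel, ff: ForceField,
                     max_steps: int = 5000, initial_step: float = 0.2,
                     force_cap: float = 1.0e4, tol: float = 1.0e-8):
    """Steepest-descent energy minimization (adaptive step, 5000 steps).

    Moves along the (cap-limited) force direction; an accepted step
    grows the trial step ×1.2, a rejected one shrinks it ×0.2, so the
    energy is monotone non-increasing across accepted steps.  Force
    capping resolves the hard-core clashes of randomly built boxes.
    Returns the minimized state.
    """
    st = state.copy()
    calc = ForceCalculator(cg, ff)

    def capped(f):
        norm = np.linalg.norm(f, axis=1)
        scale = np.where(norm > force_cap, force_cap / np.maximum(norm, 1e-30), 1.0)
        return f * scale[:, None]

    e, f, _, _ = calc(st.coords, st.box)
    if not np.isfinite(e):
        # push overlapping beads apart by a tiny jitter, then retry
        st.coords += 1e-3 * np.random.default_rng(0).standard_normal(
            st.coords.shape)
        e, f, _, _ = calc(st.coords, st.box)
        if not np.isfinite(e):
            raise MinimizationError("initial energy non-finite even after "
                                    "clash capping")
    h = float(initial_step)
    for _step in range(max_steps):
        f = capped(f)
        fmax = np.abs(f).max()
        if fmax == 0 or h < tol:
            break
        trial = st.coords + f / fmax * h
        e_t, f_t, _, _ = calc(trial, st.box)
        if np.isfinite(e_t) and e_t < e:
            st.coords, e, f = trial, e_t, f_t
            h *= 1.2
        else:
            h *= 0.2
    st.velocities = np.zeros_like(st.coords)
    return st


# ---------------------------------------------------------------------------
# molecular dynamics
# ---------------------------------------------------------------------------

def _kinetic(v, m):
    return 0.5 * KE2KJ * float(np.sum(m[:, None] * v ** 2))


def run_md(state: SimulationState, cg: CGModel, ff: ForceField,
           config: IntegratorConfig, n_steps: int, *,
           stride: int = 0, log_stride: int = 0):
    """Leapfrog MD; returns ``(final_state, Trajectory, log)``.

    Thermostat: stochastic velocity rescaling toward the target kinetic
    energy (canonical sampling); barostat: first-order Berendsen scaling
    of each box axis from the instantaneous pressure-tensor diagonal
    (μ_a = 1 at P_a = p_ref exactly).  Frames are recorded every
    ``stride`` steps (0 = final frame only); the log records energy
    components, temperature, pressure and box every ``log_stride``
    steps.  Fully reproducible given ``config.seed``.
    """
    st = state.copy()
    rng = np.random.default_rng(config.seed)
    calc = ForceCalculator(cg, ff)
    m = calc.masses
    ndf = max(3 * calc.n - 3, 1)
    k_target = 0.5 * ndf * KB * config.temperature
    dt = config.dt
    tau_p_fs = config.barostat_tau * 1000.0

    traj = Trajectory(cg.beads.copy())
    log = []
    e, f, w, parts = calc(st.coords, st.box)
    for step in range(1, n_steps + 1):
        a = ACCEL * f / m[:, None]
        v_full = st.velocities + 0.5 * dt * a      # on-step velocity estimate
        st.velocities += dt * a
        # -- Bussi stochastic velocity rescaling (half-step velocities)
        if config.thermostat:
            kin = _kinetic(st.velocities, m)
            if kin > 0:
                c = np.exp(-dt / config.thermostat_tau)
                r1 = rng.standard_normal()
                s = rng.chisquare(ndf - 1) if ndf > 1 else 0.0
                ratio = k_target / (ndf * kin)
                alpha2 = ((np.sqrt(c) + np.sqrt((1 - c) * ratio) * r1) ** 2
                          + (1 - c) * ratio * s)
                st.velocities *= np.sqrt(alpha2)
        st.coords += dt * st.velocities
        st.time += dt

        # -- Berendsen anisotropic barostat
        if config.barostat == "berendsen" and st.box is not None:
            vol = float(np.prod(st.box))
            kin_diag = KE2KJ * np.sum(m[:, None] * v_full ** 2, axis=0)
            p_diag = (kin_diag + w) / vol * P2BAR
            if not config.anisotropic:
                p_diag = np.full(3, p_diag.mean())
            mu = 1.0 - (config.compressibility * dt / (3.0 * tau_p_fs)
                        * (config.p_ref - p_diag))
            mu = np.clip(mu, 0.98, 1.02)
            st.box *= mu
            st.coords *= mu

        e, f, w, parts = calc(st.coords, st.box)

        # on-step velocity: v(t+dt) = v(t+dt/2) + (dt/2)·a(t+dt)
        v_on = st.velocities + 0.5 * dt * ACCEL * f / m[:, None]
        kin_full = _kinetic(v_on, m)
        t_inst = 2 * kin_full / (ndf * KB)
        if t_inst > 10 * config.temperature:
            raise IntegrationError(
                f"temperature explosion at step {step}: {t_inst:.0f} K "
                f"(target {config.temperature} K); reduce dt or minimize first")
        if stride and step % stride == 0:
            traj.append(st.coords, _box6(st.box), st.time)
        if log_stride and step % log_stride == 0:
            vol = float(np.prod(st.box)) if st.box is not None else np.nan
            pressure = (((2 * kin_full + w.sum()) / (3 * vol) * P2BAR)
                        if st.box is not None else np.nan)
            log.append({"step": step, "time_fs": st.time, "potential": e,
                        "kinetic": kin_full, "total": e + kin_full,
                        "temperature": t_inst, "pressure": pressure,
                        "box": None if st.box is None else st.box.copy(),
                        **{f"e_{k}": v for k, v in parts.items()}})
    if not stride or n_steps % stride != 0:
        traj.append(st.coords, _box6(st.box), st.time)
    return st, traj, log


def _box6(box):
    if box is None:
        return None
    return np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0])


# ---------------------------------------------------------------------------
# anchoring detection
# ---------------------------------------------------------------------------

@dataclass
class AnchoringEvent:
    """One protein–membrane collision: frame span + productive label."""

    start_frame: int
    end_frame: int
    start_time: float
    productive: bool


def detect_anchoring(traj: Trajectory, anchor_beads, phosphate_indices,
                     contact_cutoff: float = 6.0, *,
                     protein_indices=None, lipid_indices=None,
                     dwell_frames: int = 3):
    """Find membrane-collision events and the first productive anchoring.

    A collision event is a maximal run of frames in which any protein
    bead lies within ``contact_cutoff`` of any lipid bead.  An event is
    *productive* when the anchor beads stay within ``contact_cutoff`` of
    the phosphate (headgroup) beads for at least ``dwell_frames``
    consecutive frames; the anchoring time is the start of the first
    productive event.  Returns ``(anchoring_time_or_None, events)``.
    """
    top = traj.topology
    anchor = np.asarray(anchor_beads, int)
    phos = np.asarray(phosphate_indices, int)
    if phos.size == 0:
        raise ValueError("no phosphate beads: no bilayer to anchor to")
    lipid_resn = set(str(r) for r in top.res_names[phos])
    if lipid_indices is None:
        lipid_indices = np.flatnonzero(
            np.array([str(r) in lipid_resn for r in top.res_names]))
    lipid_indices = np.asarray(lipid_indices, int)
    if protein_indices is None:
        protein_indices = np.flatnonzero(
            np.array([str(r) not in lipid_resn and str(r) != "W"
                      for r in top.res_names]))
    protein_indices = np.asarray(protein_indices, int)

    contact = np.zeros(traj.n_frames, bool)
    anchored = np.zeros(traj.n_frames, bool)
    for fi, fr in enumerate(traj.frames):
        box = None if fr.box is None else fr.box[:3]
        lip = fr.coords[lipid_indices]
        tree = cKDTree(np.mod(lip, box) if box is not None else lip,
                       boxsize=box)
        prot = fr.coords[protein_indices]
        d, _ = tree.query(np.mod(prot, box) if box is not None else prot, k=1)
        contact[fi] = bool(np.min(d) <= contact_cutoff)
        ph = fr.coords[phos]
        ptree = cKDTree(np.mod(ph, box) if box is not None else ph,
                        boxsize=box)
        anc = fr.coords[anchor]
        da, _ = ptree.query(np.mod(anc, box) if box is not None else anc, k=1)
        anchored[fi] = bool(np.max(da) <= contact_cutoff)

    events = []
    anchoring_time = None
    fi = 0
    while fi < traj.n_frames:
        if not contact[fi]:
            fi += 1
            continue
        start = fi
        while fi < traj.n_frames and contact[fi]:
            fi += 1
        end = fi - 1
        run, best = 0, 0
        for g in range(start, end + 1):
            run = run + 1 if anchored[g] else 0
            best = max(best, run)
        productive = best >= dwell_frames
        ev = AnchoringEvent(start, end, traj.frames[start].time, productive)
        events.append(ev)
        if productive and anchoring_time is None:
            anchoring_time = ev.start_time
    return anchoring_time, events
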