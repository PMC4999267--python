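"""Bond-angle-torsion (BAT) internal coordinates and Hessians.

The configuration-integral machinery works in internal coordinates: each
mobile atom is placed by a bond length to a reference atom, a bend angle and
a dihedral (a z-matrix).  For a fully mobile molecule the first three placed
atoms carry the external degrees of freedom (position of the root plus three
rotations), leaving 3N-6 internal coordinates; when a frozen shell is present
every mobile atom is placed relative to already-fixed references and all its
coordinates are internal.

The BAT Hessian of U+W is obtained from the Cartesian Hessian through the
chain rule,

    H_q[a,b] = J_a^T H_x J_b + g_x . d2x/(dq_a dq_b),

with the Jacobian J = dx/dq and the curvature of the reconstruction map
evaluated by central differences of the exact rebuild (exact to O(h^2),
h = 1e-4).  The torsional mode analysis diagonalizes the sub-block of H_q
obtained by removing all bond and angle rows and columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .toy_systems import (
    ToyMolecularSystem, SolvationModel, bend_angle, dihedral_angle,
    gradient, cartesian_hessian, potential_energy,
)


class DegenerateGeometryError(ValueError):
    """Collinear references or angles at the domain boundary."""


# ---------------------------------------------------------------------------
# z-matrix construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZEntry:
    atom: int
    bond_ref: int = -1     # -1: no reference (root of a free molecule)
    angle_ref: int = -1
    torsion_ref: int = -1


def _collinear(a, b, c, tol=1e-6) -> bool:
    u = np.asarray(b) - np.asarray(a)
    v = np.asarray(c) - np.asarray(a)
    cr = np.cross(u, v)
    return np.linalg.norm(cr) < tol * max(np.linalg.norm(u) * np.linalg.norm(v), 1e-30)


def reference_zmatrix(system: ToyMolecularSystem) -> list:
    """The system's canonical z-matrix, built once from its stored coordinates.

    Torsion vectors of different conformers are only comparable when they are
    expressed in the same z-matrix, so everything downstream of the search
    uses this shared definition.
    """
    zm = getattr(system, "_ref_zmatrix", None)
    if zm is None:
        zm = build_zmatrix(system)
        system._ref_zmatrix = zm
    return zm


def build_zmatrix(system: ToyMolecularSystem, coords: np.ndarray = None,
                  root: int = None) -> list:
    """Placement order (list of ZEntry) for the mobile atoms of ``system``.

    Atoms are placed breadth-first over the bond graph; disconnected mobile
    fragments (e.g. a guest inside a frozen host) are attached through
    pseudo-references to the nearest already-placed atoms, which turns the
    fragment's rigid-body placement into ordinary internal coordinates.
    """
    x = system.coords if coords is None else np.asarray(coords, float)
    g = system.bond_graph()
    frozen = list(np.flatnonzero(system.frozen))
    free = [int(a) for a in np.flatnonzero(~system.frozen)]
    if len(frozen) in (1, 2):
        raise DegenerateGeometryError(
            "frozen shells must contain at least 3 atoms to serve as references")
    placed: list = list(frozen)
    entries: list = []

    def _pick_refs(k, parent):
        """angle and torsion references for atom k bonded/anchored to parent."""
        # prefer the parent's own references, then bonded neighbors, then nearest
        cand = [e for e in entries if e.atom == parent]
        pref = []
        if cand:
            pref = [cand[0].bond_ref, cand[0].angle_ref]
        pref += [a for a in g[parent] if a in placed]
        pref += sorted((a for a in placed if a not in (k, parent)),
                       key=lambda a: np.linalg.norm(x[a] - x[k]))
        a_ref = None
        for a in pref:
            if a is None or a < 0 or a in (k, parent):
                continue
            if not _collinear(x[k], x[parent], x[a]):
                a_ref = a
                break
        if a_ref is None:
            raise DegenerateGeometryError(
                f"no non-collinear angle reference for atom {k} (parent {parent})")
        t_ref = None
        pref_t = []
        cand_a = [e for e in entries if e.atom == a_ref]
        if cand_a:
            pref_t = [cand_a[0].bond_ref]
        pref_t += [a for a in g[a_ref] if a in placed]
        pref_t += sorted((a for a in placed if a not in (k, parent, a_ref)),
                         key=lambda a: np.linalg.norm(x[a] - x[a_ref]))
        for a in pref_t:
            if a is None or a < 0 or a in (k, parent, a_ref):
                continue
            if not _collinear(x[parent], x[a_ref], x[a]):
                t_ref = a
                break
        if t_ref is None:
            raise DegenerateGeometryError(
                f"no non-collinear torsion reference for atom {k} "
                f"(parent {parent}, angle ref {a_ref})")
        return a_ref, t_ref

    remaining = set(free)
    if not frozen:
        # free molecule: seed the placement with a root chain of three atoms
        r0 = root if root is not None else free[0]
        nb = sorted(g[r0]) or [a for a in free if a != r0]
        r1 = nb[0]
        r2 = None
        for c in sorted(g[r1]) + sorted(g[r0]) + free:
            if c in (r0, r1):
                continue
            if not _collinear(x[r0], x[r1], x[c]):
                r2 = c
                break
        if r2 is None:
            raise DegenerateGeometryError(
                f"cannot seed z-matrix: atoms collinear around root {r0}")
        entries.append(ZEntry(r0))
        entries.append(ZEntry(r1, bond_ref=r0))
        parent2 = r1 if r1 in g[r2] else r0
        other2 = r0 if parent2 == r1 else r1
        entries.append(ZEntry(r2, bond_ref=parent2, angle_ref=other2))
        placed += [r0, r1, r2]
        remaining -= {r0, r1, r2}
    # BFS over the rest
    while remaining:
        k = None
        parent = None
        # prefer atoms bonded to a placed atom, in index order
        for a in sorted(remaining):
            bonded_placed = [p for p in sorted(g[a]) if p in placed]
            if bonded_placed:
                k, parent = a, bonded_placed[0]
                break
        if k is None:
            # disconnected fragment: anchor its lowest-index atom to the
            # nearest placed atom via a pseudo-bond
            k = sorted(remaining)[0]
            parent = min(placed, key=lambda a: np.linalg.norm(x[a] - x[k]))
        a_ref, t_ref = _pick_refs(k, parent)
        entries.append(ZEntry(k, bond_ref=parent, angle_ref=a_ref, torsion_ref=t_ref))
        placed.append(k)
        remaining.discard(k)
    return entries


# ---------------------------------------------------------------------------
# BAT state
# ---------------------------------------------------------------------------

@dataclass
class BATState:
    """Internal coordinates plus the information needed for exact rebuild."""

    zmatrix: list                      # list of ZEntry, placement order
    bonds: np.ndarray                  # per entry with bond_ref, A
    angles: np.ndarray                 # per entry with angle_ref, rad (0, pi)
    torsions: np.ndarray               # per entry with torsion_ref, rad (-pi, pi]
    fixed_coords: np.ndarray = None    # (N, 3) coords of frozen atoms (NaN for free)
    n_atoms: int = 0
    #: external placement of a fully mobile molecule
    root_position: np.ndarray = None   # (3,)
    orientation: np.ndarray = None     # rotation vector (3,), rad

    # -- flat coordinate vector -------------------------------------------

    def _layout(self):
        """Indices into the flat q vector: (bond_pos, angle_pos, torsion_pos).

        Each is a list of (entry_index, q_index).
        """
        bond_pos, angle_pos, torsion_pos = [], [], []
        qi = 0
        for ei, e in enumerate(self.zmatrix):
            if e.bond_ref >= 0:
                bond_pos.append((ei, qi)); qi += 1
        for ei, e in enumerate(self.zmatrix):
            if e.angle_ref >= 0:
                angle_pos.append((ei, qi)); qi += 1
        for ei, e in enumerate(self.zmatrix):
            if e.torsion_ref >= 0:
                torsion_pos.append((ei, qi)); qi += 1
        return bond_pos, angle_pos, torsion_pos

    @property
    def q(self) -> np.ndarray:
        bp, ap, tp = self._layout()
        n = len(bp) + len(ap) + len(tp)
        q = np.empty(n)
        for ei, qi in bp:
            q[qi] = self.bonds[ei]
        for ei, qi in ap:
            q[qi] = self.angles[ei]
        for ei, qi in tp:
            q[qi] = self.torsions[ei]
        return q

    def with_q(self, q: np.ndarray) -> "BATState":
        s = BATState(self.zmatrix, self.bonds.copy(), self.angles.copy(),
                     self.torsions.copy(), self.fixed_coords, self.n_atoms,
                     self.root_position, self.orientation)
        bp, ap, tp = self._layout()
        for ei, qi in bp:
            s.bonds[ei] = q[qi]
        for ei, qi in ap:
            s.angles[ei] = q[qi]
        for ei, qi in tp:
            s.torsions[ei] = _wrap_pi(q[qi])
        return s

    @property
    def bond_indices(self) -> np.ndarray:
        return np.array([qi for _, qi in self._layout()[0]], dtype=int)

    @property
    def angle_indices(self) -> np.ndarray:
        return np.array([qi for _, qi in self._layout()[1]], dtype=int)

    @property
    def torsion_indices(self) -> np.ndarray:
        return np.array([qi for _, qi in self._layout()[2]], dtype=int)

    @property
    def torsions_deg(self) -> np.ndarray:
        """Torsion coordinates in degrees, placement order."""
        return np.rad2deg(np.array(
            [self.torsions[ei] for ei, _ in self._layout()[2]]))


def _wrap_pi(a: float) -> float:
    w = (a + np.pi) % (2 * np.pi) - np.pi
    return np.pi if w == -np.pi else w


def _nerf(a, b, c, r, theta, phi):
    """Place atom d with |d-c| = r, angle(d,c,b) = theta, dihedral(d,c,b,a) = phi."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise DegenerateGeometryError("collinear reference triple in rebuild")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([-r * np.cos(theta),
                        r * np.sin(theta) * np.cos(phi),
                        -r * np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def cartesian_to_bat(system: ToyMolecularSystem, coords: np.ndarray = None,
                     zmatrix: list = None, root: int = None) -> BATState:
    """Extract BAT coordinates (bijective with :func:`bat_to_cartesian`)."""
    x = np.asarray(system.coords if coords is None else coords, float).reshape(-1, 3)
    zm = zmatrix if zmatrix is not None else build_zmatrix(system, x, root=root)
    n_e = len(zm)
    bonds = np.zeros(n_e)
    angles = np.zeros(n_e)
    torsions = np.zeros(n_e)
    for ei, e in enumerate(zm):
        k = e.atom
        if e.bond_ref >= 0:
            bonds[ei] = np.linalg.norm(x[k] - x[e.bond_ref])
        if e.angle_ref >= 0:
            if _collinear(x[k], x[e.bond_ref], x[e.angle_ref]):
                raise DegenerateGeometryError(
                    f"collinear reference triple {k}-{e.bond_ref}-{e.angle_ref}")
            angles[ei] = bend_angle(x[k], x[e.bond_ref], x[e.angle_ref])
        if e.torsion_ref >= 0:
            torsions[ei] = _wrap_pi(dihedral_angle(
                x[k], x[e.bond_ref], x[e.angle_ref], x[e.torsion_ref]))
    fixed = np.full((system.n_atoms, 3), np.nan)
    fixed[system.frozen] = x[system.frozen]
    state = BATState(zm, bonds, angles, torsions, fixed_coords=fixed,
                     n_atoms=system.n_atoms)
    if not np.any(system.frozen):
        # record external placement from the root triad
        canon = _rebuild(state, canonical=True)
        r0, r1, r2 = (zm[0].atom, zm[1].atom, zm[2].atom)
        A = np.stack([canon[r1] - canon[r0], canon[r2] - canon[r0],
                      np.cross(canon[r1] - canon[r0], canon[r2] - canon[r0])])
        B = np.stack([x[r1] - x[r0], x[r2] - x[r0],
                      np.cross(x[r1] - x[r0], x[r2] - x[r0])])
        rot, _ = Rotation.align_vectors(B, A)
        state.root_position = x[r0].copy()
        state.orientation = rot.as_rotvec()
    return state


def _rebuild(state: BATState, canonical: bool = False) -> np.ndarray:
    x = np.array(state.fixed_coords, float, copy=True)
    zm = state.zmatrix
    start = 0
    if zm and zm[0].bond_ref < 0:
        # free molecule: canonical root triad
        r0, r1, r2 = zm[0].atom, zm[1].atom, zm[2].atom
        x[r0] = (0.0, 0.0, 0.0)
        x[r1] = (state.bonds[1], 0.0, 0.0)
        th = state.angles[2]
        e2 = zm[2]
        base = x[e2.bond_ref]
        direction = 1.0 if e2.bond_ref == r1 else -1.0
        x[r2] = base + state.bonds[2] * np.array(
            [-direction * np.cos(th), np.sin(th), 0.0])
        start = 3
    for ei in range(start, len(zm)):
        e = zm[ei]
        if e.torsion_ref < 0:
            continue
        if not (0.0 < state.angles[ei] < np.pi):
            raise DegenerateGeometryError(
                f"angle for atom {e.atom} outside (0, pi): {state.angles[ei]}")
        x[e.atom] = _nerf(x[e.torsion_ref], x[e.angle_ref], x[e.bond_ref],
                          state.bonds[ei], state.angles[ei], state.torsions[ei])
    if not canonical and state.root_position is not None:
        r0 = zm[0].atom
        rot = Rotation.from_rotvec(state.orientation)
        x = rot.apply(x - x[r0]) + state.root_position
    return x


def bat_to_cartesian(state: BATState) -> np.ndarray:
    """Deterministic Cartesian reconstruction; frozen atoms are kept verbatim."""
    return _rebuild(state)


# ---------------------------------------------------------------------------
# BAT Hessian
# ---------------------------------------------------------------------------

@dataclass
class BATHessian:
    """Second derivatives of U+W in BAT coordinates.

    ``full`` spans all internal coordinates (bonds, then angles, then
    torsions, placement order); ``torsion_block`` is the sub-matrix with all
    bond and angle rows and columns removed, and ``eigenvalues``/
    ``eigenvectors`` are its spectral decomposition (kcal/mol/rad^2).
    """

    full: np.ndarray
    state: BATState
    torsion_indices: np.ndarray
    eigenvalues: np.ndarray = None
    eigenvectors: np.ndarray = None

    def __post_init__(self):
        if self.eigenvalues is None and len(self.torsion_indices):
            tb = self.torsion_block
            self.eigenvalues, self.eigenvectors = np.linalg.eigh(tb)
        elif self.eigenvalues is None:
            self.eigenvalues = np.array([])
            self.eigenvectors = np.zeros((0, 0))

    @property
    def torsion_block(self) -> np.ndarray:
        ti = self.torsion_indices
        return self.full[np.ix_(ti, ti)]

    @property
    def bond_angle_indices(self) -> np.ndarray:
        n = self.full.shape[0]
        return np.setdiff1d(np.arange(n), self.torsion_indices)


def bat_hessian(system: ToyMolecularSystem, coords: np.ndarray = None,
                solvation: SolvationModel = None, zmatrix: list = None,
                root: int = None, h: float = 1e-4) -> BATHessian:
    """Full BAT Hessian of U+W plus the torsion-block eigendecomposition."""
    x_in = np.asarray(system.coords if coords is None else coords, float).reshape(-1, 3)
    state = cartesian_to_bat(system, x_in, zmatrix=zmatrix, root=root)
    if state.root_position is not None:
        # evaluate in the canonical frame so the result depends on internal
        # coordinates only (exact invariance under global rotation/translation)
        state.root_position = None
        state.orientation = None
    x = bat_to_cartesian(state)
    q0 = state.q
    n = len(q0)
    free = np.flatnonzero(~np.repeat(system.frozen, 3))

    def rebuild(q):
        return bat_to_cartesian(state.with_q(q)).ravel()[free]

    hx = cartesian_hessian(system, x, solvation)[np.ix_(free, free)]
    gx = gradient(system, x, solvation).ravel()[free]
    # Jacobian dx/dq by central differences of the exact rebuild
    J = np.empty((len(free), n))
    for a in range(n):
        qp = q0.copy(); qp[a] += h
        qm = q0.copy(); qm[a] -= h
        J[:, a] = (rebuild(qp) - rebuild(qm)) / (2 * h)
    x0f = rebuild(q0)
    H = J.T @ hx @ J
    # curvature of the reconstruction map, g . d2x/dqdq; larger step with
    # higher-order stencils keeps roundoff ~1e-9 even far from a minimum
    hk = 1e-3

    def at(deltas):
        q = q0.copy()
        for idx, d in deltas:
            q[idx] += d
        return rebuild(q)

    for a in range(n):
        for b in range(a, n):
            if a == b:
                k_ab = (-at([(a, 2 * hk)]) + 16 * at([(a, hk)]) - 30 * x0f
                        + 16 * at([(a, -hk)]) - at([(a, 2 * -hk)])) / (12 * hk**2)
            else:
                k_ab = (at([(a, hk), (b, hk)]) - at([(a, hk), (b, -hk)])
                        - at([(a, -hk), (b, hk)]) + at([(a, -hk), (b, -hk)])) / (4 * hk**2)
            corr = float(gx @ k_ab)
            H[a, b] += corr
            if a != b:
                H[b, a] += corr
    H = 0.5 * (H + H.T)
    return BATHessian(full=H, state=state, torsion_indices=state.torsion_indices)


def bat_hessian_fd(system: ToyMolecularSystem, coords: np.ndarray = None,
                   solvation: SolvationModel = None, zmatrix: list = None,
                   h: float = 1e-4) -> np.ndarray:
    """Brute-force BAT Hessian: central differences of the energy in q.

    Independent oracle for :func:`bat_hessian` (no Jacobian transform).
    """
    x = np.asarray(system.coords if coords is None else coords, float).reshape(-1, 3)
    state = cartesian_to_bat(system, x, zmatrix=zmatrix)
    q0 = state.q
    n = len(q0)

    def f(q):
        return potential_energy(system, bat_to_cartesian(state.with_q(q)), solvation)

    e0 = f(q0)
    H = np.empty((n, n))
    for a in range(n):
        qp = q0.copy(); qp[a] += h
        qm = q0.copy(); qm[a] -= h
        H[a, a] = (f(qp) - 2 * e0 + f(qm)) / h**2
    for a in range(n):
        for b in range(a + 1, n):
            qpp = q0.copy(); qpp[[a, b]] += h
            qmm = q0.copy(); qmm[[a, b]] -= h
            qpm = q0.copy(); qpm[a] += h; qpm[b] -= h
            qmp = q0.copy(); qmp[a] -= h; qmp[b] += h
            H[a, b] = H[b, a] = (f(qpp) - f(qpm) - f(qmp) + f(qmm)) / (4 * h**2)
    return H
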