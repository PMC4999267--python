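"""Toy molecular systems with analytically countable minima.

This module is the synthetic-data generator of the package.  It provides a
minimal molecular-mechanics force field (harmonic bonds and angles, cosine
torsion series, 12-6 Lennard-Jones, unscreened Coulomb) together with builders
for chain molecules whose torsional energy landscape has a known number of
wells, a toy host--guest complex with a polar anchor triad and a hydrophobic
pocket, and synthetic dihedral trajectories drawn from circular (von Mises)
mixture distributions.  These stand in for the molecular-dynamics data of a
real receptor--ligand study while keeping every expected result enumerable.

Conventions
-----------
* Harmonic terms use the physics convention U = 1/2 k (x - x0)^2.
* Torsions use a cosine series U = sum_n V_n (1 + cos(n phi - gamma_n)).
* Lennard-Jones uses the Rmin convention U = eps [(Rmin/r)^12 - 2 (Rmin/r)^6]
  with Rmin_ij = rmin_half_i + rmin_half_j and eps_ij = sqrt(eps_i eps_j).
* Nonbonded pairs separated by one, two or three bonds are excluded entirely.
* Frozen atoms contribute to every energy term but carry no degrees of
  freedom: they never move under minimization or distortion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import COULOMB_CONSTANT


class ParameterError(ValueError):
    """Invalid force-field or generator parameter."""


# ---------------------------------------------------------------------------
# Force-field terms and the system container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    force_k: float   # kcal/mol/A^2
    r0: float        # A


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    force_k: float   # kcal/mol/rad^2
    theta0: float    # rad


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    #: cosine series: list of (V_n [kcal/mol], n [periodicity], gamma [rad])
    terms: tuple = ()


@dataclass
class ToyMolecularSystem:
    """Topology, force-field parameters and coordinates of a toy molecule.

    ``frozen`` marks atoms that belong to the rigid shell (the analog of the
    rigid "real set" surrounding the flexible region of a receptor): they
    enter all energy terms but are never moved.
    """

    elements: list
    charges: np.ndarray         # e
    lj_epsilon: np.ndarray      # kcal/mol
    lj_rmin_half: np.ndarray    # A
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    coords: np.ndarray = None   # (N, 3) A
    frozen: np.ndarray = None   # (N,) bool
    #: extra nonbonded exclusions beyond the automatic 1-2/1-3/1-4 ones
    extra_exclusions: set = field(default_factory=set)

    def __post_init__(self):
        n = len(self.elements)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
        for b in self.bonds:
            if b.force_k <= 0:
                raise ParameterError(f"bond {b.i}-{b.j}: force constant must be > 0")
        for a in self.angles:
            if a.force_k <= 0:
                raise ParameterError(f"angle {a.i}-{a.j}-{a.k}: force constant must be > 0")
        self._compiled = None

    # -- derived quantities ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def free_atoms(self) -> np.ndarray:
        return np.flatnonzero(~self.frozen)

    def bond_graph(self) -> dict:
        g = {i: set() for i in range(self.n_atoms)}
        for b in self.bonds:
            g[b.i].add(b.j)
            g[b.j].add(b.i)
        return g

    def exclusions(self) -> set:
        """Pairs (i < j) excluded from nonbonded terms: within 3 bonds."""
        g = self.bond_graph()
        excl = set(frozenset(p) for p in self.extra_exclusions)
        for i in range(self.n_atoms):
            # BFS to depth 3
            depth = {i: 0}
            frontier = [i]
            for d in range(1, 4):
                nxt = []
                for a in frontier:
                    for b in g[a]:
                        if b not in depth:
                            depth[b] = d
                            nxt.append(b)
                frontier = nxt
            for j, d in depth.items():
                if j != i:
                    excl.add(frozenset((i, j)))
        return {tuple(sorted(p)) for p in excl}

    def _compile(self):
        """Cache index arrays for vectorized energy evaluation."""
        if self._compiled is not None:
            return self._compiled
        c = {}
        c["b_idx"] = np.array([(b.i, b.j) for b in self.bonds], dtype=int).reshape(-1, 2)
        c["b_k"] = np.array([b.force_k for b in self.bonds], dtype=float)
        c["b_r0"] = np.array([b.r0 for b in self.bonds], dtype=float)
        c["a_idx"] = np.array([(a.i, a.j, a.k) for a in self.angles], dtype=int).reshape(-1, 3)
        c["a_k"] = np.array([a.force_k for a in self.angles], dtype=float)
        c["a_t0"] = np.array([a.theta0 for a in self.angles], dtype=float)
        # expand torsion cosine series: one row per (torsion, term)
        t_idx, t_v, t_n, t_g, t_of = [], [], [], [], []
        for ti, t in enumerate(self.torsions):
            for (v, n, g) in t.terms:
                t_idx.append((t.i, t.j, t.k, t.l))
                t_v.append(v)
                t_n.append(n)
                t_g.append(g)
                t_of.append(ti)
        c["t_idx"] = np.array(t_idx, dtype=int).reshape(-1, 4)
        c["t_v"] = np.array(t_v, dtype=float)
        c["t_n"] = np.array(t_n, dtype=float)
        c["t_g"] = np.array(t_g, dtype=float)
        excl = self.exclusions()
        pairs = [(i, j) for i in range(self.n_atoms) for j in range(i + 1, self.n_atoms)
                 if (i, j) not in excl]
        c["nb_idx"] = np.array(pairs, dtype=int).reshape(-1, 2)
        pi, pj = c["nb_idx"].T if len(pairs) else (np.array([], int), np.array([], int))
        c["nb_eps"] = np.sqrt(self.lj_epsilon[pi] * self.lj_epsilon[pj])
        c["nb_rmin"] = self.lj_rmin_half[pi] + self.lj_rmin_half[pj]
        c["nb_qq"] = self.charges[pi] * self.charges[pj]
        self._compiled = c
        return c

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "charges": self.charges.tolist(),
            "lj_epsilon": self.lj_epsilon.tolist(),
            "lj_rmin_half": self.lj_rmin_half.tolist(),
            "bonds": [[int(b.i), int(b.j), float(b.force_k), float(b.r0)]
                      for b in self.bonds],
            "angles": [[int(a.i), int(a.j), int(a.k), float(a.force_k), float(a.theta0)]
                       for a in self.angles],
            "torsions": [
                [int(t.i), int(t.j), int(t.k), int(t.l),
                 [[float(v), int(n), float(g)] for (v, n, g) in t.terms]]
                for t in self.torsions
            ],
            "coords": self.coords.tolist() if self.coords is not None else None,
            "frozen": self.frozen.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToyMolecularSystem":
        return cls(
            elements=list(d["elements"]),
            charges=np.asarray(d["charges"], float),
            lj_epsilon=np.asarray(d["lj_epsilon"], float),
            lj_rmin_half=np.asarray(d["lj_rmin_half"], float),
            bonds=[BondTerm(*b) for b in d.get("bonds", [])],
            angles=[AngleTerm(*a) for a in d.get("angles", [])],
            torsions=[TorsionTerm(t[0], t[1], t[2], t[3],
                                  tuple(tuple(x) for x in t[4]))
                      for t in d.get("torsions", [])],
            coords=np.asarray(d["coords"], float) if d.get("coords") is not None else None,
            frozen=np.asarray(d.get("frozen", [0] * len(d["elements"])), bool),
        )

    def save(self, path) -> None:
        """Write the system definition (topology + coordinates) as YAML."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ToyMolecularSystem":
        with open(path) as fh:
            text = fh.read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Solvation models
# ---------------------------------------------------------------------------

@dataclass
class SolvationModel:
    """Implicit-solvent term W(coords).

    kind:
      * ``none``         -- W = 0 everywhere.
      * ``born``         -- generalized-Born pairwise screening (Still f_GB)
                            between interior and exterior dielectrics.
      * ``surface-area`` -- nonpolar W = gamma * SASA (Shrake-Rupley).
      * ``born+sa``      -- sum of the two previous terms.
    """

    kind: str = "none"
    gamma: float = 0.00542            # kcal/mol/A^2
    eps_interior: float = 1.0
    eps_exterior: float = 80.0
    born_radii: np.ndarray = None     # A, per atom
    probe_radius: float = 1.4         # A
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.kind not in ("none", "born", "surface-area", "born+sa"):
            raise ParameterError(f"unknown solvation kind {self.kind!r}")
        if self.born_radii is not None:
            self.born_radii = np.asarray(self.born_radii, dtype=float)

    # -- polar (generalized Born) -----------------------------------------

    def _born_prefactor(self) -> float:
        return COULOMB_CONSTANT * (1.0 / self.eps_interior - 1.0 / self.eps_exterior)

    def born_energy(self, system: ToyMolecularSystem, coords: np.ndarray) -> float:
        a = self.born_radii
        if a is None:
            raise ParameterError("born solvation requires per-atom born_radii")
        q = system.charges
        pref = self._born_prefactor()
        w = -0.5 * pref * np.sum(q * q / a)
        n = system.n_atoms
        if n > 1:
            iu, ju = np.triu_indices(n, k=1)
            d = coords[iu] - coords[ju]
            r2 = np.einsum("ij,ij->i", d, d)
            aa = a[iu] * a[ju]
            f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
            w += -pref * np.sum(q[iu] * q[ju] / f)
        return w

    def born_gradient(self, system: ToyMolecularSystem, coords: np.ndarray) -> np.ndarray:
        a = self.born_radii
        q = system.charges
        pref = self._born_prefactor()
        grad = np.zeros_like(coords)
        n = system.n_atoms
        if n > 1:
            iu, ju = np.triu_indices(n, k=1)
            d = coords[iu] - coords[ju]
            r2 = np.einsum("ij,ij->i", d, d)
            r = np.sqrt(r2)
            aa = a[iu] * a[ju]
            e = np.exp(-r2 / (4.0 * aa))
            f = np.sqrt(r2 + aa * e)
            # df/dr = r (1 - e/4) / f
            dfdr = r * (1.0 - 0.25 * e) / f
            dWdr = pref * q[iu] * q[ju] / f**2 * dfdr
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
            fvec = dWdr[:, None] * unit
            np.add.at(grad, iu, fvec)
            np.add.at(grad, ju, -fvec)
        return grad

    # -- nonpolar (surface area) -------------------------------------------

    def sasa(self, system: ToyMolecularSystem, coords: np.ndarray) -> np.ndarray:
        """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2."""
        radii = system.lj_rmin_half + self.probe_radius
        pts = _golden_spiral(self.n_sphere_points)
        areas = np.zeros(system.n_atoms)
        for i in range(system.n_atoms):
            sphere = coords[i] + radii[i] * pts
            buried = np.zeros(len(pts), dtype=bool)
            for j in range(system.n_atoms):
                if j == i:
                    continue
                d2 = np.einsum("ij,ij->i", sphere - coords[j], sphere - coords[j])
                buried |= d2 < radii[j] ** 2
            areas[i] = 4.0 * np.pi * radii[i] ** 2 * np.mean(~buried)
        return areas

    def sasa_energy(self, system: ToyMolecularSystem, coords: np.ndarray) -> float:
        return self.gamma * float(np.sum(self.sasa(system, coords)))

    # -- combined ----------------------------------------------------------

    def energy(self, system: ToyMolecularSystem, coords: np.ndarray) -> float:
        """Solvation free energy W in kcal/mol (deterministic in coords)."""
        w = 0.0
        if self.kind in ("born", "born+sa"):
            w += self.born_energy(system, coords)
        if self.kind in ("surface-area", "born+sa"):
            w += self.sasa_energy(system, coords)
        return w

    def gradient(self, system: ToyMolecularSystem, coords: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(coords)
        if self.kind == "born":
            return self.born_gradient(system, coords)
        raise ParameterError(
            f"solvation kind {self.kind!r} is not differentiable; "
            "use it for trajectory post-processing only"
        )


def _golden_spiral(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (deterministic)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


#: convenience instance: no solvation
VACUUM = SolvationModel(kind="none")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (rad, in (-pi, pi]) by the standard four-point formula."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = np.arctan2(y, x)
    if ang <= -np.pi:
        ang += 2 * np.pi
    return ang


def bend_angle(p0, p1, p2) -> float:
    """Bond angle at p1 in rad."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _cross(a, b):
    """Row-wise cross product without numpy's moveaxis overhead."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _angles_vec(x, idx):
    """Bend angles (rad) for an (M, 3) index array."""
    u = x[idx[:, 0]] - x[idx[:, 1]]
    v = x[idx[:, 2]] - x[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.arccos(c)


def _dihedrals_vec(x, idx):
    """Signed dihedrals (rad) for an (M, 4) index array."""
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m = _cross(n1, b2 / nb2[:, None])
    return np.arctan2(np.einsum("ij,ij->i", m, n2), np.einsum("ij,ij->i", n1, n2))


# ---------------------------------------------------------------------------
# Energy and analytic gradient
# ---------------------------------------------------------------------------

def _mm_energy_grad(system: ToyMolecularSystem, x: np.ndarray):
    """Compiled evaluation of all molecular-mechanics terms and their gradient."""
    from ._kernels import energy_and_gradient
    c = system._compile()
    return energy_and_gradient(
        np.ascontiguousarray(x, dtype=float),
        c["b_idx"], c["b_k"], c["b_r0"], c["a_idx"], c["a_k"], c["a_t0"],
        c["t_idx"], c["t_v"], c["t_n"], c["t_g"],
        c["nb_idx"], c["nb_eps"], c["nb_rmin"], c["nb_qq"], COULOMB_CONSTANT)


def energy_components(system: ToyMolecularSystem, coords: np.ndarray = None,
                      solvation: SolvationModel = None, compiled: bool = True) -> dict:
    """All energy terms (kcal/mol): bond, angle, torsion, vdw, coul, w.

    ``val`` is the valence sum bond+angle+torsion; ``total`` includes W.
    ``compiled=False`` forces the reference numpy path (used as an
    independent cross-check of the compiled kernel).
    """
    x = system.coords if coords is None else np.asarray(coords, float).reshape(-1, 3)
    if compiled:
        eb, ea, et, ev, ec, _ = _mm_energy_grad(system, x)
        out = {"bond": eb, "angle": ea, "torsion": et, "vdw": ev, "coul": ec}
        out["val"] = eb + ea + et
        out["w"] = solvation.energy(system, x) if solvation is not None else 0.0
        out["total"] = out["val"] + ev + ec + out["w"]
        return out
    c = system._compile()
    out = {}
    # bonds
    if len(c["b_idx"]):
        d = x[c["b_idx"][:, 0]] - x[c["b_idx"][:, 1]]
        r = np.linalg.norm(d, axis=1)
        out["bond"] = float(np.sum(0.5 * c["b_k"] * (r - c["b_r0"]) ** 2))
    else:
        out["bond"] = 0.0
    # angles
    if len(c["a_idx"]):
        th = _angles_vec(x, c["a_idx"])
        out["angle"] = float(np.sum(0.5 * c["a_k"] * (th - c["a_t0"]) ** 2))
    else:
        out["angle"] = 0.0
    # torsions
    if len(c["t_idx"]):
        phi = _dihedrals_vec(x, c["t_idx"])
        out["torsion"] = float(np.sum(c["t_v"] * (1.0 + np.cos(c["t_n"] * phi - c["t_g"]))))
    else:
        out["torsion"] = 0.0
    # nonbonded
    if len(c["nb_idx"]):
        d = x[c["nb_idx"][:, 0]] - x[c["nb_idx"][:, 1]]
        r = np.linalg.norm(d, axis=1)
        sr6 = (c["nb_rmin"] / r) ** 6
        out["vdw"] = float(np.sum(c["nb_eps"] * (sr6 ** 2 - 2.0 * sr6)))
        out["coul"] = float(np.sum(COULOMB_CONSTANT * c["nb_qq"] / r))
    else:
        out["vdw"] = 0.0
        out["coul"] = 0.0
    out["val"] = out["bond"] + out["angle"] + out["torsion"]
    out["w"] = solvation.energy(system, x) if solvation is not None else 0.0
    out["total"] = out["val"] + out["vdw"] + out["coul"] + out["w"]
    return out


def potential_energy(system: ToyMolecularSystem, coords: np.ndarray = None,
                     solvation: SolvationModel = None) -> float:
    """U + W in kcal/mol."""
    return energy_components(system, coords, solvation)["total"]


def gradient(system: ToyMolecularSystem, coords: np.ndarray = None,
             solvation: SolvationModel = None, compiled: bool = True) -> np.ndarray:
    """Analytic gradient of U+W, (N, 3) kcal/mol/A."""
    x = system.coords if coords is None else np.asarray(coords, float).reshape(-1, 3)
    if compiled:
        g = _mm_energy_grad(system, x)[5]
        if solvation is not None and solvation.kind != "none":
            g = g + solvation.gradient(system, x)
        return g
    c = system._compile()
    g = np.zeros_like(x)
    # bonds
    if len(c["b_idx"]):
        bi, bj = c["b_idx"].T
        d = x[bi] - x[bj]
        r = np.linalg.norm(d, axis=1)
        dUdr = c["b_k"] * (r - c["b_r0"])
        f = (dUdr / r)[:, None] * d
        np.add.at(g, bi, f)
        np.add.at(g, bj, -f)
    # angles
    if len(c["a_idx"]):
        ai, aj, ak = c["a_idx"].T
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cth = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - cth * cth, 1e-16))
        dUdth = c["a_k"] * (np.arccos(cth) - c["a_t0"])
        gi = -(v / (nu * nv)[:, None] - (cth / nu**2)[:, None] * u) / s[:, None]
        gk = -(u / (nu * nv)[:, None] - (cth / nv**2)[:, None] * v) / s[:, None]
        np.add.at(g, ai, dUdth[:, None] * gi)
        np.add.at(g, ak, dUdth[:, None] * gk)
        np.add.at(g, aj, dUdth[:, None] * (-gi - gk))
    # torsions
    if len(c["t_idx"]):
        ti, tj, tk, tl = c["t_idx"].T
        b1 = x[tj] - x[ti]
        b2 = x[tk] - x[tj]
        b3 = x[tl] - x[tk]
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        phi = _dihedrals_vec(x, c["t_idx"])
        dUdphi = -c["t_v"] * c["t_n"] * np.sin(c["t_n"] * phi - c["t_g"])
        dpdri = (nb2 / np.einsum("ij,ij->i", n1, n1))[:, None] * n1
        dpdrl = -(nb2 / np.einsum("ij,ij->i", n2, n2))[:, None] * n2
        p = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
        q = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
        dpdrj = -(1.0 + p) * dpdri + q * dpdrl
        dpdrk = p * dpdri - (1.0 + q) * dpdrl
        du = dUdphi[:, None]
        np.add.at(g, ti, du * dpdri)
        np.add.at(g, tj, du * dpdrj)
        np.add.at(g, tk, du * dpdrk)
        np.add.at(g, tl, du * dpdrl)
    # nonbonded
    if len(c["nb_idx"]):
        pi, pj = c["nb_idx"].T
        d = x[pi] - x[pj]
        r = np.linalg.norm(d, axis=1)
        sr6 = (c["nb_rmin"] / r) ** 6
        dUdr = -12.0 * c["nb_eps"] / r * (sr6 ** 2 - sr6)
        dUdr += -COULOMB_CONSTANT * c["nb_qq"] / r ** 2
        f = (dUdr / r)[:, None] * d
        np.add.at(g, pi, f)
        np.add.at(g, pj, -f)
    if solvation is not None and solvation.kind != "none":
        g = g + solvation.gradient(system, x)
    return g


def cartesian_hessian(system: ToyMolecularSystem, coords: np.ndarray = None,
                      solvation: SolvationModel = None, step: float = 1e-5) -> np.ndarray:
    """(3N, 3N) Hessian of U+W by central differences of the analytic gradient."""
    x = (system.coords if coords is None else np.asarray(coords, float)).reshape(-1, 3).copy()
    n3 = x.size
    h = np.zeros((n3, n3))
    flat = x.ravel()
    for a in range(n3):
        orig = flat[a]
        flat[a] = orig + step
        gp = gradient(system, flat.reshape(-1, 3), solvation).ravel()
        flat[a] = orig - step
        gm = gradient(system, flat.reshape(-1, 3), solvation).ravel()
        flat[a] = orig
        h[a] = (gp - gm) / (2.0 * step)
    return 0.5 * (h + h.T)


def interaction_terms(system: ToyMolecularSystem, coords: np.ndarray,
                      mask_a: np.ndarray, mask_b: np.ndarray) -> dict:
    """Nonbonded interaction energy between two atom groups (vdw, coul).

    Only pairs with one atom in each group, honoring exclusions.
    """
    x = np.asarray(coords, float).reshape(-1, 3)
    c = system._compile()
    out = {"vdw": 0.0, "coul": 0.0}
    if len(c["nb_idx"]):
        pi, pj = c["nb_idx"].T
        cross = (mask_a[pi] & mask_b[pj]) | (mask_b[pi] & mask_a[pj])
        if np.any(cross):
            d = x[pi[cross]] - x[pj[cross]]
            r = np.linalg.norm(d, axis=1)
            sr6 = (c["nb_rmin"][cross] / r) ** 6
            out["vdw"] = float(np.sum(c["nb_eps"][cross] * (sr6 ** 2 - 2.0 * sr6)))
            out["coul"] = float(np.sum(COULOMB_CONSTANT * c["nb_qq"][cross] / r))
    return out


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

_TET_ANGLE = np.deg2rad(109.471)


def _chain_coords(n_atoms: int, bond_r0: float, theta0: float,
                  torsions_deg: Sequence[float] = None) -> np.ndarray:
    """Cartesian coordinates of a chain with given internal coordinates."""
    from .internal_coords import _nerf  # local import to avoid cycle at import time
    x = np.zeros((n_atoms, 3))
    x[0] = (0.0, 0.0, 0.0)
    if n_atoms > 1:
        x[1] = (bond_r0, 0.0, 0.0)
    if n_atoms > 2:
        x[2] = x[1] + bond_r0 * np.array([-np.cos(theta0), np.sin(theta0), 0.0])
    for k in range(3, n_atoms):
        phi = np.deg2rad(torsions_deg[k - 3]) if torsions_deg is not None else np.pi
        x[k] = _nerf(x[k - 3], x[k - 2], x[k - 1], bond_r0, theta0, phi)
    return x


def build_chain(n_torsions: int, torsion_params: Iterable = ((2.5, 3, 0.0),),
                seed: int = 0, bond_k: float = 300.0, bond_r0: float = 1.53,
                angle_k: float = 60.0, theta0: float = _TET_ANGLE,
                lj_epsilon: float = 0.0, lj_rmin_half: float = 1.7,
                charges: Sequence[float] = None) -> ToyMolecularSystem:
    """Linear chain molecule with ``n_torsions`` rotatable bonds.

    With the default 3-fold torsion profile, positive force constants and no
    nonbonded clash (the default has LJ switched off) the landscape has
    exactly 3**n_torsions distinct minima.

    torsion_params: cosine series [(V kcal/mol, n, gamma rad), ...] applied to
    every rotatable bond.  An amplitude of zero gives a free rotor.
    """
    if n_torsions < 1:
        raise ParameterError("n_torsions must be >= 1")
    terms = tuple(tuple(t) for t in torsion_params)
    for (v, n, g) in terms:
        if v < 0:
            raise ParameterError("torsion amplitudes must be >= 0")
    if bond_k <= 0 or angle_k <= 0:
        raise ParameterError("force constants must be > 0")
    n_atoms = n_torsions + 3
    coords = _chain_coords(n_atoms, bond_r0, theta0,
                           torsions_deg=[180.0] * n_torsions)
    sys_ = ToyMolecularSystem(
        elements=["C"] * n_atoms,
        charges=np.zeros(n_atoms) if charges is None else np.asarray(charges, float),
        lj_epsilon=np.full(n_atoms, lj_epsilon),
        lj_rmin_half=np.full(n_atoms, lj_rmin_half),
        bonds=[BondTerm(i, i + 1, bond_k, bond_r0) for i in range(n_atoms - 1)],
        angles=[AngleTerm(i, i + 1, i + 2, angle_k, theta0) for i in range(n_atoms - 2)],
        torsions=[TorsionTerm(i, i + 1, i + 2, i + 3, terms) for i in range(n_torsions)],
        coords=coords,
    )
    return sys_


def build_host_guest(seed: int = 0):
    """Toy host--guest pair emulating two-point anchoring.

    The host is a rigid pocket: a hexagonal hydrophobic floor plus a triad of
    positively charged anchor atoms; two rim atoms bonded to the floor stay
    flexible.  The guest is a chain with a negatively charged head (pairs with
    the anchor triad) and a bulky apolar tail (sits on the floor), so its free
    state has both folded and extended conformer families.

    Returns (host, guest, complex) where the complex concatenates both with
    the host frozen outside the flexible rim.
    """
    # host: hexagon floor (frozen), anchor triad (frozen), two flexible rim atoms
    hex_r = 3.6
    floor = np.array([[hex_r * np.cos(a), hex_r * np.sin(a), 0.0]
                      for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)])
    triad = np.array([[-4.8, -1.6, 2.4], [-4.8, 1.6, 2.4], [-5.8, 0.0, 3.4]])
    rim_anchor = [1, 4]
    rim = floor[rim_anchor] * 1.0
    rim[:, 2] += 1.5
    host_coords = np.vstack([floor, triad, rim])
    nh = len(host_coords)
    host_frozen = np.ones(nh, dtype=bool)
    host_frozen[[nh - 2, nh - 1]] = False
    host_bonds = [BondTerm(i, (i + 1) % 6, 400.0,
                           float(np.linalg.norm(floor[i] - floor[(i + 1) % 6])))
                  for i in range(6)]
    # bond the triad internally so its members see no mutual nonbonded terms
    for (i, j) in ((6, 7), (6, 8), (7, 8)):
        host_bonds.append(BondTerm(i, j, 100.0,
                                   float(np.linalg.norm(host_coords[i] - host_coords[j]))))
    host_bonds += [BondTerm(rim_anchor[0], nh - 2, 150.0, 1.5),
                   BondTerm(rim_anchor[1], nh - 1, 150.0, 1.5)]
    host_angles = [AngleTerm((rim_anchor[0] + 1) % 6, rim_anchor[0], nh - 2, 40.0, np.pi / 2),
                   AngleTerm((rim_anchor[1] + 1) % 6, rim_anchor[1], nh - 1, 40.0, np.pi / 2)]
    host = ToyMolecularSystem(
        elements=["C"] * 6 + ["N"] * 3 + ["C"] * 2,
        charges=np.concatenate([np.zeros(6), np.full(3, 0.30), np.zeros(2)]),
        lj_epsilon=np.concatenate([np.full(6, 0.15), np.full(3, 0.10), np.full(2, 0.10)]),
        lj_rmin_half=np.concatenate([np.full(6, 1.9), np.full(3, 1.6), np.full(2, 1.7)]),
        bonds=host_bonds,
        angles=host_angles,
        coords=host_coords,
        frozen=host_frozen,
    )
    # guest: 6-atom chain, charged head, bulky apolar tail
    guest = build_chain(3, torsion_params=((1.8, 3, 0.0),),
                        lj_epsilon=0.12, lj_rmin_half=1.7)
    guest.charges[0] = -0.90
    guest.lj_epsilon[5] = 0.35
    guest.lj_rmin_half[5] = 2.2
    guest.elements = ["O"] + ["C"] * 4 + ["S"]
    guest._compiled = None
    # complex: head in reach of the triad, chain running across the pocket
    # so the bulky tail sits over the hydrophobic floor
    g_coords = guest.coords - guest.coords[0] + np.array([-2.4, 0.0, 3.2])
    comp = concatenate_systems(host, guest, guest_coords=g_coords)
    return host, guest, comp


def _rotz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def concatenate_systems(a: ToyMolecularSystem, b: ToyMolecularSystem,
                        guest_coords: np.ndarray = None) -> ToyMolecularSystem:
    """Noncovalent union of two systems (no bonded terms across the parts)."""
    na = a.n_atoms
    shift = lambda term, d: dataclasses.replace(
        term, **{f: getattr(term, f) + d for f in ("i", "j", "k", "l") if hasattr(term, f)})
    return ToyMolecularSystem(
        elements=list(a.elements) + list(b.elements),
        charges=np.concatenate([a.charges, b.charges]),
        lj_epsilon=np.concatenate([a.lj_epsilon, b.lj_epsilon]),
        lj_rmin_half=np.concatenate([a.lj_rmin_half, b.lj_rmin_half]),
        bonds=list(a.bonds) + [shift(t, na) for t in b.bonds],
        angles=list(a.angles) + [shift(t, na) for t in b.angles],
        torsions=list(a.torsions) + [shift(t, na) for t in b.torsions],
        coords=np.vstack([a.coords, b.coords if guest_coords is None else guest_coords]),
        frozen=np.concatenate([a.frozen, b.frozen]),
    )


# ---------------------------------------------------------------------------
# Synthetic dihedral trajectories
# ---------------------------------------------------------------------------

@dataclass
class DihedralState:
    center_deg: float      # in [-180, 180)
    concentration: float   # von Mises kappa
    weight: float


@dataclass
class SyntheticTrajectorySpec:
    """Circular-mixture specification for one or more dihedral series."""

    #: mapping name -> list of DihedralState (or (center, kappa, weight) tuples)
    dihedrals: dict = field(default_factory=dict)
    n_frames: int = 1000
    seed: int = 0
    #: probability of re-using the previous frame's mixture component
    correlation: float = 0.0

    def __post_init__(self):
        clean = {}
        for name, states in self.dihedrals.items():
            ss = [s if isinstance(s, DihedralState) else DihedralState(*s) for s in states]
            wsum = sum(s.weight for s in ss)
            if abs(wsum - 1.0) > 1e-9:
                raise ParameterError(
                    f"dihedral {name!r}: state weights sum to {wsum}, expected 1")
            for s in ss:
                if not (-180.0 <= s.center_deg < 180.0):
                    raise ParameterError(
                        f"dihedral {name!r}: center {s.center_deg} outside [-180, 180)")
            clean[name] = ss
        self.dihedrals = clean
        if not (0.0 <= self.correlation < 1.0):
            raise ParameterError("correlation must lie in [0, 1)")


def wrap_angle_deg(a):
    """Wrap angle(s) to [-180, 180)."""
    return (np.asarray(a, float) + 180.0) % 360.0 - 180.0


def generate_dihedral_trajectory(spec: SyntheticTrajectorySpec):
    """Draw a synthetic dihedral trajectory from the circular mixture spec.

    Returns an :class:`~miningminima.ensemble_analysis.DihedralTrajectory`
    with angles wrapped to [-180, 180).  Bit-reproducible under a fixed seed.
    """
    from .ensemble_analysis import DihedralTrajectory
    rng = np.random.default_rng(spec.seed)
    data = {"frame": np.arange(spec.n_frames)}
    for name, states in spec.dihedrals.items():
        weights = np.array([s.weight for s in states])
        comp = np.empty(spec.n_frames, dtype=int)
        prev = None
        for t in range(spec.n_frames):
            if prev is not None and spec.correlation > 0 and rng.random() < spec.correlation:
                comp[t] = prev
            else:
                comp[t] = rng.choice(len(states), p=weights)
            prev = comp[t]
        ang = np.empty(spec.n_frames)
        for ci, s in enumerate(states):
            m = comp == ci
            ang[m] = rng.vonmises(np.deg2rad(s.center_deg), s.concentration, size=int(m.sum()))
        data[name] = wrap_angle_deg(np.rad2deg(ang))
    return DihedralTrajectory(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# XYZ I/O (plain text, one or many frames)
# ---------------------------------------------------------------------------

def write_xyz(path, elements: Sequence[str], frames: np.ndarray, comment: str = "") -> None:
    """Write one or many frames in XYZ format."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for fi, x in enumerate(frames):
            fh.write(f"{len(elements)}\n{comment} frame {fi}\n")
            for el, (a, b, c) in zip(elements, x):
                fh.write(f"{el} {a:.8f} {b:.8f} {c:.8f}\n")


def read_xyz(path):
    """Read a (multi-frame) XYZ file -> (elements, frames (F, N, 3))."""
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        block = lines[i + 2: i + 2 + n]
        els, xyz = [], []
        for ln in block:
            parts = ln.split()
            els.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        frames.append(xyz)
        i += 2 + n
    return elements, np.asarray(frames, float)
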