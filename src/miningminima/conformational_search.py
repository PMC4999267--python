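"""Conformational search for distinct low-energy wells.

The search alternates torsional-mode distortion and two-stage minimization:
starting from each conformer in the pool, the system is displaced along each
eigenvector of the torsion-block BAT Hessian by a ladder of signed
amplitudes, each distorted geometry is energy minimized (a gradient-descent
stage followed by a Newton stage), repeats are detected and removed by a
wrap-aware torsion distance, conformers far above the current best well are
discarded, and the accumulated free energy of the pool is tracked until it
stops changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .constants import R_KCAL
from .internal_coords import (
    BATHessian, bat_hessian, bat_to_cartesian, cartesian_to_bat, reference_zmatrix,
)
from .toy_systems import (
    SolvationModel, ToyMolecularSystem, gradient, potential_energy,
)

logger = logging.getLogger(__name__)

#: default distortion ladder (degrees): a complete sweep along each mode
DEFAULT_AMPLITUDES_DEG = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


class SearchError(RuntimeError):
    pass


@dataclass
class SearchConfig:
    """Knobs of the conformational search."""

    #: signed distortion amplitudes applied along each torsional mode (rad)
    amplitudes: tuple = tuple(np.deg2rad(a) for a in DEFAULT_AMPLITUDES_DEG)
    max_iterations: int = 10
    #: inf-norm gradient tolerance at a converged minimum, kcal/mol/A
    gradient_tol: float = 1e-6
    #: circular max-torsion distance below which two minima are repeats, deg
    duplicate_threshold_deg: float = 10.0
    #: energy agreement required to call two minima repeats, kcal/mol
    duplicate_energy_tol: float = 1e-4
    #: discard conformers more than retention_window * RT above the best
    retention_window: float = 10.0
    temperature: float = 300.0
    #: stop when the accumulated free energy changes less than this, kcal/mol
    convergence_tol: float = 0.05
    #: two equal-energy stationary points joined by a torsional path that
    #: never rises more than this above them sit in one (flat) well
    degenerate_path_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.retention_window <= 0:
            raise ValueError("retention window must be > 0")
        if not len(self.amplitudes):
            raise ValueError("amplitude ladder must be nonempty")


@dataclass
class ConformerRecord:
    """One distinct local minimum of U+W."""

    coords: np.ndarray = None         # minimized coordinates, A
    energy: float = np.nan            # (U+W)_min, kcal/mol
    torsions_deg: np.ndarray = None   # torsion vector, deg, placement order
    hessian: BATHessian = None        # BAT Hessian at the minimum
    converged: bool = True
    provenance: str = "start"
    # set by local_thermodynamics:
    z: float = None                   # local configuration integral
    log_z: float = None               # ln Z_i (used for accumulation)
    mean_energy: float = None         # harmonic/quadrature <U+W> within the well
    n_soft_modes: int = 0
    components: dict = None           # energy terms at the minimum


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize(system: ToyMolecularSystem, coords: np.ndarray = None,
             solvation: SolvationModel = None, gradient_tol: float = 1e-6,
             max_iterations: int = 500):
    """Two-stage minimization: conjugate-gradient descent, then Newton.

    Frozen atoms never move.  Returns ``(coords, energy, converged)`` with
    energy <= the starting energy and inf-norm gradient below ``gradient_tol``
    when converged.
    """
    x0 = np.asarray(system.coords if coords is None else coords, float).reshape(-1, 3)
    free = np.flatnonzero(~np.repeat(system.frozen, 3))
    flat0 = x0.ravel().copy()

    def embed(v):
        flat = flat0.copy()
        flat[free] = v
        return flat.reshape(-1, 3)

    def f(v):
        return potential_energy(system, embed(v), solvation)

    def jac(v):
        return gradient(system, embed(v), solvation).ravel()[free]

    e_start = f(flat0[free])
    if not np.isfinite(e_start):
        raise SearchError("non-finite starting energy")

    def descend(v0):
        # stage 1: conjugate gradient
        res = scipy_minimize(f, v0, jac=jac, method="CG",
                             options={"maxiter": 60, "gtol": 1e-3})
        v = res.x
        # stage 2: damped Newton with backtracking line search
        e = f(v)
        ok = False
        for _ in range(60):
            g = jac(v)
            if np.max(np.abs(g)) < gradient_tol:
                ok = True
                break
            h = _free_hessian(system, embed(v), solvation, free)
            lam = 0.0
            step = None
            for _ in range(12):
                try:
                    hh = h + lam * np.eye(len(g)) if lam else h
                    np.linalg.cholesky(hh)
                    step = -np.linalg.solve(hh, g)
                    break
                except np.linalg.LinAlgError:
                    lam = max(2.0 * lam, 1e-4)
            if step is None:
                break
            t = 1.0
            e_new = e
            for _ in range(30):
                e_new = f(v + t * step)
                if e_new <= e + 1e-12:
                    break
                t *= 0.5
            else:
                break
            v = v + t * step
            e = e_new
        return v, f(v), ok

    v, e, converged = descend(flat0[free])
    # stage 3: escape stationary points with downhill curvature (saddles);
    # zero modes of a free molecule (overall rotation/translation) sit near 0
    for _ in range(5):
        if not converged:
            break
        h = _free_hessian(system, embed(v), solvation, free)
        evals, evecs = np.linalg.eigh(h)
        if evals[0] > -1e-4:
            break
        vec = evecs[:, 0]
        best = None
        for sign in (1.0, -1.0):
            v1, e1, ok1 = descend(v + sign * 0.25 * vec)
            if ok1 and e1 < e - 1e-9 and (best is None or e1 < best[1]):
                best = (v1, e1)
        if best is None:
            converged = False
            break
        v, e = best
    if e > e_start + 1e-9:   # never return a point above the start
        v, e, converged = flat0[free], e_start, False
    return embed(v), float(e), converged


def _free_hessian(system, coords, solvation, free, step=1e-5):
    from .toy_systems import cartesian_hessian
    return cartesian_hessian(system, coords, solvation, step=step)[np.ix_(free, free)]


def make_conformer(system: ToyMolecularSystem, coords: np.ndarray,
                   solvation: SolvationModel = None, config: SearchConfig = None,
                   provenance: str = "start", with_hessian: bool = True) -> ConformerRecord:
    """Minimize from ``coords`` and package the result as a ConformerRecord."""
    config = config or SearchConfig()
    x, e, ok = minimize(system, coords, solvation, gradient_tol=config.gradient_tol)
    rec = ConformerRecord(coords=x, energy=e, converged=ok, provenance=provenance)
    if ok and with_hessian:
        attach_hessian(system, rec, solvation)
    elif ok:
        st = cartesian_to_bat(system, x, zmatrix=reference_zmatrix(system))
        rec.torsions_deg = st.torsions_deg
    return rec


def attach_hessian(system, rec: ConformerRecord, solvation=None) -> None:
    rec.hessian = bat_hessian(system, rec.coords, solvation,
                              zmatrix=reference_zmatrix(system))
    rec.torsions_deg = rec.hessian.state.torsions_deg


# ---------------------------------------------------------------------------
# Distortion, deduplication
# ---------------------------------------------------------------------------

def distort_and_descend(system: ToyMolecularSystem, parent: ConformerRecord,
                        config: SearchConfig, solvation: SolvationModel = None) -> list:
    """Displace the parent along every torsional eigenmode and re-minimize.

    For each eigenvector of the parent's torsion-block Hessian and each
    signed amplitude of the ladder, the torsions are displaced along the
    (normalized) mode, the geometry rebuilt, and the whole system minimized.
    Failed minimizations are dropped with a log entry.
    """
    if parent.hessian is None:
        attach_hessian(system, parent, solvation)
    hess = parent.hessian
    state = hess.state
    q0 = state.q
    ti = state.torsion_indices
    out = []
    if not len(ti):
        return out
    for mi in range(hess.eigenvectors.shape[1]):
        mode = hess.eigenvectors[:, mi]
        for amp in config.amplitudes:
            for sign in (+1.0, -1.0):
                q = q0.copy()
                q[ti] = q[ti] + sign * amp * mode
                try:
                    x_start = bat_to_cartesian(state.with_q(q))
                    rec = make_conformer(system, x_start, solvation, config,
                                         provenance=f"{parent.provenance}|m{mi}a{sign*amp:+.2f}",
                                         with_hessian=False)
                except Exception as exc:   # failed rebuild/minimization
                    logger.info("distortion dropped (mode %d amp %.2f): %s", mi, amp, exc)
                    continue
                if rec.converged:
                    out.append(rec)
                else:
                    logger.info("unconverged minimization dropped (mode %d amp %.2f)", mi, amp)
    return out


def circular_torsion_distance(a_deg, b_deg) -> float:
    """Max over torsions of the circular angle difference, degrees."""
    d = np.abs(np.asarray(a_deg, float) - np.asarray(b_deg, float)) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    return float(np.max(d)) if d.size else 0.0


def deduplicate(conformers: list, threshold_deg: float = 10.0,
                energy_tol: float = 1e-4) -> list:
    """Remove repeats: keep the lowest-energy representative of each well.

    Two records are repeats when every torsion agrees within the circular
    ``threshold_deg`` AND the energies agree within ``energy_tol``.
    Idempotent; survivors come back sorted by energy.
    """
    ordered = sorted(conformers, key=lambda r: r.energy)
    kept: list = []
    for rec in ordered:
        dup = False
        for k in kept:
            if abs(rec.energy - k.energy) <= energy_tol and \
               circular_torsion_distance(rec.torsions_deg, k.torsions_deg) <= threshold_deg:
                dup = True
                break
        if not dup:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# The full search
# ---------------------------------------------------------------------------

def _flat_torsional_path(system: ToyMolecularSystem, a: ConformerRecord,
                         b: ConformerRecord, tol: float,
                         solvation: SolvationModel = None, n_steps: int = 13) -> bool:
    """True when the straight torsional path a->b never leaves the well floor.

    Degeneracy handling for free-rotor torsions: distortions along a flat
    torsional profile produce stationary points everywhere, all belonging to
    the same well.  Interpolates torsions along the circular shortest path
    (bonds/angles held at ``a``'s values) and checks the energy stays within
    ``tol`` of the endpoints.
    """
    state = cartesian_to_bat(system, a.coords, zmatrix=reference_zmatrix(system))
    q0 = state.q
    ti = state.torsion_indices
    if not len(ti):
        return True
    ta = np.deg2rad(a.torsions_deg)
    tb = np.deg2rad(b.torsions_deg)
    diff = (tb - ta + np.pi) % (2 * np.pi) - np.pi
    cap = max(a.energy, b.energy) + tol
    for s in np.linspace(0.0, 1.0, n_steps):
        q = q0.copy()
        q[ti] = ta + s * diff
        e = potential_energy(system, bat_to_cartesian(state.with_q(q)), solvation)
        if e > cap:
            return False
    return True


def collapse_degenerate(system: ToyMolecularSystem, conformers: list,
                        config: SearchConfig, solvation: SolvationModel = None) -> list:
    """Merge equal-energy stationary points that share one flat well."""
    kept: list = []
    for rec in sorted(conformers, key=lambda r: r.energy):
        dup = False
        for k in kept:
            if abs(rec.energy - k.energy) <= config.duplicate_energy_tol and \
               _flat_torsional_path(system, k, rec, config.degenerate_path_tol,
                                    solvation):
                dup = True
                break
        if not dup:
            kept.append(rec)
    return kept


def run_search(system: ToyMolecularSystem, solvation: SolvationModel = None,
               config: SearchConfig = None, start_coords: np.ndarray = None):
    """Iterated distort-and-descend search over distinct energy wells.

    Every iteration re-seeds distortions from every pool member, minimizes,
    deduplicates, drops conformers above the retention window, recomputes the
    accumulated free energy, and stops once the free energy stops improving.

    Returns ``(conformers, history)`` where history is the accumulated free
    energy (kcal/mol) after each iteration.
    """
    from .local_thermodynamics import ThermoConfig, accumulate_free_energy, local_integral

    config = config or SearchConfig()
    thermo = ThermoConfig(temperature=config.temperature)
    start = make_conformer(system, start_coords, solvation, config, provenance="start")
    if not start.converged:
        raise SearchError("no minimum found from the starting geometry")
    pool = [start]
    rt = R_KCAL * config.temperature

    def ledger_g(members):
        for rec in members:
            if rec.z is None:
                if rec.hessian is None:
                    attach_hessian(system, rec, solvation)
                local_integral(system, rec, thermo, solvation)
        return accumulate_free_energy(members, thermo).free_energy

    history = [ledger_g(pool)]
    for it in range(config.max_iterations):
        candidates = list(pool)
        for parent in pool:
            candidates.extend(distort_and_descend(system, parent, config, solvation))
        pool = deduplicate(candidates, config.duplicate_threshold_deg,
                           config.duplicate_energy_tol)
        pool = collapse_degenerate(system, pool, config, solvation)
        best = pool[0].energy
        pool = [r for r in pool if r.energy <= best + config.retention_window * rt]
        g = ledger_g(pool)
        history.append(g)
        if abs(history[-2] - g) < config.convergence_tol:
            break
    return pool, history


def end_to_end_distances(system: ToyMolecularSystem, conformers: list,
                         i: int = None, j: int = None) -> np.ndarray:
    """Distance between two atoms (default: first/last mobile) per conformer."""
    free = system.free_atoms
    i = free[0] if i is None else i
    j = free[-1] if j is None else j
    return np.array([np.linalg.norm(r.coords[i] - r.coords[j]) for r in conformers])


def enumerate_minima_grid(system: ToyMolecularSystem, solvation: SolvationModel = None,
                          grid_points: int = 12, config: SearchConfig = None) -> list:
    """Brute-force oracle: minimize from a dense grid of torsion vectors.

    Seeds one minimization from every point of a ``grid_points``-per-torsion
    grid and deduplicates the results.  Exponential in the number of
    torsions; intended for small systems only.
    """
    import itertools

    config = config or SearchConfig()
    state = cartesian_to_bat(system, zmatrix=reference_zmatrix(system))
    ti = state.torsion_indices
    q0 = state.q
    grid = np.deg2rad(np.arange(grid_points) * 360.0 / grid_points - 180.0)
    recs = []
    for combo in itertools.product(grid, repeat=len(ti)):
        q = q0.copy()
        q[ti] = combo
        x = bat_to_cartesian(state.with_q(q))
        rec = make_conformer(system, x, solvation, config,
                             provenance="grid", with_hessian=False)
        if rec.converged:
            recs.append(rec)
    return deduplicate(recs, config.duplicate_threshold_deg, config.duplicate_energy_tol)
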