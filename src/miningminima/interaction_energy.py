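"""Single-trajectory interaction-energy decomposition (MM/PBSA style).

For every frame of a complex trajectory the energy of the complex, of the
receptor alone and of the ligand alone is evaluated on the SAME coordinates,
and the interaction energy is the trajectory average

    Delta(U+W) = <E_complex> - <E_receptor> - <E_ligand>.

Because both subsystems keep their intra-molecular geometry, every bonded
(valence) term cancels exactly, frame by frame; what remains is the
intermolecular Lennard-Jones and Coulomb energy plus the change in implicit
solvation: polar (generalized-Born screening between interior dielectric 1
and exterior dielectric 80 by default) and nonpolar (gamma * SASA).
Statistical errors come from the deviation between contiguous block
averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_analysis import block_average_error
from .toy_systems import (
    AngleTerm, BondTerm, ParameterError, SolvationModel, TorsionTerm,
    ToyMolecularSystem, interaction_terms,
)


@dataclass
class InteractionBreakdown:
    """Trajectory-averaged interaction energy and its components (kcal/mol).

    Invariants: du_val == 0 exactly (single-trajectory contract) and
    delta_total == e_np + e_polar to machine precision.
    """

    delta_total: float            # Delta(U+W)
    delta_total_err: float
    du_vdw: float
    dw_np: float
    du_coul: float
    dw_polar: float
    du_val: float = 0.0
    errors: dict = field(default_factory=dict)
    n_frames: int = 0
    n_blocks: int = 0

    @property
    def e_np(self) -> float:
        """Nonpolar part: Delta U_VDW + Delta W_NP."""
        return self.du_vdw + self.dw_np

    @property
    def e_polar(self) -> float:
        """Polar part: Delta U_Coul + Delta W_polar."""
        return self.du_coul + self.dw_polar

    def to_frame(self) -> pd.DataFrame:
        row = {
            "d_U_plus_W": self.delta_total, "d_U_plus_W_err": self.delta_total_err,
            "dU_VDW": self.du_vdw, "dW_NP": self.dw_np, "dE_NP": self.e_np,
            "dU_Coul": self.du_coul, "dW_polar": self.dw_polar,
            "dE_polar": self.e_polar, "dU_val": self.du_val,
            "n_frames": self.n_frames, "n_blocks": self.n_blocks,
        }
        return pd.DataFrame([row])


def subsystem(system: ToyMolecularSystem, mask: np.ndarray) -> ToyMolecularSystem:
    """Extract the sub-molecule selected by a boolean mask.

    Raises if any bonded term crosses the mask boundary: the masks must
    partition whole molecules or valence cancellation would not be exact.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    remap = {int(a): i for i, a in enumerate(idx)}

    def keep(term, atoms):
        inside = [a in remap for a in atoms]
        if all(inside):
            return True
        if any(inside):
            raise ParameterError(f"bonded term {atoms} crosses the mask boundary")
        return False

    bonds = [BondTerm(remap[b.i], remap[b.j], b.force_k, b.r0)
             for b in system.bonds if keep(b, (b.i, b.j))]
    angles = [AngleTerm(remap[a.i], remap[a.j], remap[a.k], a.force_k, a.theta0)
              for a in system.angles if keep(a, (a.i, a.j, a.k))]
    torsions = [TorsionTerm(remap[t.i], remap[t.j], remap[t.k], remap[t.l], t.terms)
                for t in system.torsions if keep(t, (t.i, t.j, t.k, t.l))]
    extra = {tuple(sorted((remap[i], remap[j]))) for (i, j) in
             {tuple(sorted(p)) for p in system.extra_exclusions}
             if i in remap and j in remap}
    return ToyMolecularSystem(
        elements=[system.elements[a] for a in idx],
        charges=system.charges[idx], lj_epsilon=system.lj_epsilon[idx],
        lj_rmin_half=system.lj_rmin_half[idx],
        bonds=bonds, angles=angles, torsions=torsions,
        coords=system.coords[idx] if system.coords is not None else None,
        frozen=system.frozen[idx], extra_exclusions=extra,
    )


def _solvation_for(solvation: SolvationModel, mask: np.ndarray) -> SolvationModel:
    if solvation is None or solvation.born_radii is None:
        return solvation
    sub = SolvationModel(kind=solvation.kind, gamma=solvation.gamma,
                         eps_interior=solvation.eps_interior,
                         eps_exterior=solvation.eps_exterior,
                         born_radii=solvation.born_radii[np.asarray(mask, bool)],
                         probe_radius=solvation.probe_radius,
                         n_sphere_points=solvation.n_sphere_points)
    return sub


def single_trajectory_decomposition(system: ToyMolecularSystem, frames: np.ndarray,
                                    receptor_mask, ligand_mask,
                                    solvation: SolvationModel = None,
                                    n_blocks: int = 5,
                                    discard_fraction: float = 0.0) -> InteractionBreakdown:
    """Frame-wise interaction decomposition from a single complex trajectory.

    ``frames`` is (F, N, 3); the two boolean masks must partition the atoms.
    ``discard_fraction`` drops the leading fraction of frames (equilibration)
    before averaging.  Solvation differences use the supplied model for the
    complex and each isolated subsystem; molecular-mechanics differences are
    exact intermolecular sums, so the valence difference is identically zero.
    """
    receptor_mask = np.asarray(receptor_mask, dtype=bool)
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    if np.any(receptor_mask & ligand_mask) or not np.all(receptor_mask | ligand_mask):
        raise ParameterError("masks must partition the complex atoms")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] != system.n_atoms:
        raise ParameterError(
            f"frames have {frames.shape[1]} atoms, system has {system.n_atoms}")
    if discard_fraction:
        start = int(round(discard_fraction * len(frames)))
        frames = frames[start:]
    if len(frames) < n_blocks:
        raise ParameterError("need at least n_blocks frames after discarding")
    rec_sys = subsystem(system, receptor_mask)
    lig_sys = subsystem(system, ligand_mask)
    rec_solv = _solvation_for(solvation, receptor_mask)
    lig_solv = _solvation_for(solvation, ligand_mask)
    has_w = solvation is not None and solvation.kind != "none"
    per = {"vdw": [], "coul": [], "w_polar": [], "w_np": []}
    from .toy_systems import energy_components
    max_dval = 0.0
    for x in frames:
        # single-trajectory contract: valence terms cancel frame by frame
        dval = (energy_components(system, x)["val"]
                - energy_components(rec_sys, x[receptor_mask])["val"]
                - energy_components(lig_sys, x[ligand_mask])["val"])
        max_dval = max(max_dval, abs(dval))
        if max_dval > 1e-9:
            raise AssertionError(
                f"valence cancellation violated: |dU_val| = {max_dval:.3g}")
        inter = interaction_terms(system, x, receptor_mask, ligand_mask)
        per["vdw"].append(inter["vdw"])
        per["coul"].append(inter["coul"])
        wp = wn = 0.0
        if has_w:
            xr = x[receptor_mask]
            xl = x[ligand_mask]
            if solvation.kind in ("born", "born+sa"):
                wp = (solvation.born_energy(system, x)
                      - rec_solv.born_energy(rec_sys, xr)
                      - lig_solv.born_energy(lig_sys, xl))
            if solvation.kind in ("surface-area", "born+sa"):
                wn = (solvation.sasa_energy(system, x)
                      - rec_solv.sasa_energy(rec_sys, xr)
                      - lig_solv.sasa_energy(lig_sys, xl))
        per["w_polar"].append(wp)
        per["w_np"].append(wn)
    per = {k: np.asarray(v) for k, v in per.items()}
    total = per["vdw"] + per["coul"] + per["w_polar"] + per["w_np"]
    errors = {k: block_average_error(v, n_blocks) for k, v in per.items()}
    return InteractionBreakdown(
        delta_total=float(np.mean(total)),
        delta_total_err=block_average_error(total, n_blocks),
        du_vdw=float(np.mean(per["vdw"])), dw_np=float(np.mean(per["w_np"])),
        du_coul=float(np.mean(per["coul"])), dw_polar=float(np.mean(per["w_polar"])),
        du_val=0.0,   # intermolecular bonded terms do not exist by construction
        errors=errors, n_frames=len(frames), n_blocks=n_blocks,
    )


def born_ion_solvation(charge: float, radius: float, eps_in: float = 1.0,
                       eps_out: float = 80.0) -> float:
    """Analytic Born formula for a single charged sphere (kcal/mol).

    Independent closed-form oracle for the generalized-Born backend, which
    reduces to it exactly in the single-atom case.
    """
    from .constants import COULOMB_CONSTANT
    return -0.5 * COULOMB_CONSTANT * charge**2 * (1.0 / eps_in - 1.0 / eps_out) / radius
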