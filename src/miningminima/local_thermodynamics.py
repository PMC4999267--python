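"""Local configuration integrals, accumulated free energies and entropy.

The configurational partition function is approximated by a sum of local
configuration integrals over the distinct energy wells found by the search,

    Z_total = sum_i Z_i,        Z_i = int_{well i} exp(-beta (U+W)) dr_int,

and the standard free energy of a species is

    G0 = -RT ln( (8 pi^2 / C0') Z_total ),

with C0' the standard concentration in molecules/A^3 (so the binding free
energy of complex formation carries the conventional 1 M reference exactly
once).  Each Z_i is evaluated with an enhanced harmonic approximation in BAT
coordinates: bond and angle coordinates contribute Gaussian factors from
their Hessian block; torsional modes with eigenvalue above a stiffness
threshold contribute sqrt(2 pi RT / lambda); soft torsional modes (below the
threshold) are integrated numerically along their eigenvector to capture
anharmonicity.

From the Boltzmann-averaged well energy <U+W> the configurational entropy
follows as -T S_config = G0 - <U+W>; it splits into a conformational part
RT ln(M / k) (M wells within the retention window, k bound conformations)
and a vibrational remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL, standard_concentration_per_A3
from .internal_coords import bat_to_cartesian
from .toy_systems import SolvationModel, ToyMolecularSystem, potential_energy, energy_components


class ThermoError(ValueError):
    pass


@dataclass
class ThermoConfig:
    """Temperature, standard state, and soft-mode handling."""

    temperature: float = 300.0            # K
    gas_constant: float = R_KCAL          # kcal/mol/K
    standard_concentration: float = 1.0   # mol/L
    #: torsional eigenvalues below this are treated anharmonically
    #: (kcal/mol/rad^2)
    soft_mode_threshold: float = 2.0
    #: half-range of the soft-mode quadrature, in harmonic sigma
    quadrature_sigma: float = 6.0
    quadrature_points: int = 201
    #: carry the BAT volume element r^2 sin(theta) inside Z_i ("local")
    #: or treat it as constant across wells ("constant")
    jacobian: str = "constant"
    #: multiply G0 by the external-rotation/standard-state factor; the
    #: alternative convention divides by C0' instead of multiplying by 8pi^2/C0'
    standard_state_convention: str = "multiply"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ThermoError("temperature must be > 0")
        if self.standard_concentration <= 0:
            raise ThermoError("standard concentration must be > 0")
        if self.soft_mode_threshold < 0:
            raise ThermoError("soft-mode threshold must be >= 0")
        if self.jacobian not in ("constant", "local"):
            raise ThermoError("jacobian must be 'constant' or 'local'")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.rt

    @property
    def external_log_factor(self) -> float:
        """ln of the external-rotation / standard-state prefactor of G0."""
        c = standard_concentration_per_A3(self.standard_concentration)
        if self.standard_state_convention == "multiply":
            return float(np.log(8.0 * np.pi**2 / c))
        return float(np.log(8.0 * np.pi**2 * c))

    def compatible_with(self, other: "ThermoConfig") -> bool:
        return (abs(self.temperature - other.temperature) < 1e-9 and
                abs(self.standard_concentration - other.standard_concentration) < 1e-12 and
                self.standard_state_convention == other.standard_state_convention)


# ---------------------------------------------------------------------------
# Local configuration integral
# ---------------------------------------------------------------------------

def local_integral(system: ToyMolecularSystem, conformer, config: ThermoConfig = None,
                   solvation: SolvationModel = None) -> float:
    """Enhanced-harmonic local configuration integral Z_i of one well.

    Sets ``conformer.z``, ``conformer.log_z`` and ``conformer.mean_energy``
    (the within-well Boltzmann average of U+W) and returns Z_i.  The returned
    value excludes the external 8 pi^2 / C0' factor, which is applied once per
    species in :func:`accumulate_free_energy`.
    """
    config = config or ThermoConfig()
    hess = conformer.hessian
    if hess is None:
        raise ThermoError("conformer carries no BAT Hessian; run attach_hessian first")
    rt = config.rt
    evals = hess.eigenvalues
    if len(evals) and np.min(evals) < -1e-6:
        raise ThermoError(
            f"not a minimum: torsion-block eigenvalue {np.min(evals):.3g} < 0")
    # bond/angle block: Gaussian factors from the BAT Hessian determinant
    ba = hess.bond_angle_indices
    log_z = 0.0
    mean_e = conformer.energy
    if len(ba):
        block = hess.full[np.ix_(ba, ba)]
        ba_evals = np.linalg.eigvalsh(block)
        if np.min(ba_evals) <= 0:
            raise ThermoError("bond/angle Hessian block not positive definite")
        log_z += 0.5 * np.sum(np.log(2.0 * np.pi * rt / ba_evals))
        mean_e += 0.5 * rt * len(ba)
    # torsional modes
    n_soft = 0
    for mi, lam in enumerate(evals):
        if lam >= config.soft_mode_threshold:
            log_z += 0.5 * np.log(2.0 * np.pi * rt / lam)
            mean_e += 0.5 * rt
        else:
            n_soft += 1
            zq, eq = _soft_mode_quadrature(system, conformer, hess, mi, config, solvation)
            log_z += np.log(zq)
            mean_e += eq
    if config.jacobian == "local":
        state = hess.state
        bi = state.bond_indices
        ai = state.angle_indices
        q = state.q
        log_z += float(2.0 * np.sum(np.log(q[bi])) + np.sum(np.log(np.sin(q[ai]))))
    log_z -= config.beta * conformer.energy
    conformer.z = float(np.exp(log_z))
    conformer.log_z = float(log_z)
    conformer.mean_energy = float(mean_e)
    conformer.n_soft_modes = n_soft
    if conformer.components is None:
        conformer.components = energy_components(system, conformer.coords, solvation)
    return conformer.z


def _soft_mode_quadrature(system, conformer, hess, mode_index, config, solvation):
    """1-D trapezoid integral of exp(-beta dU) along a soft eigenvector.

    Range is +-quadrature_sigma harmonic standard deviations, clipped to the
    torsional period; returns (Z_mode, <dU>_mode).
    """
    rt = config.rt
    lam = hess.eigenvalues[mode_index]
    vec = hess.eigenvectors[:, mode_index]
    sigma = np.sqrt(rt / max(lam, 1e-3))
    half = min(config.quadrature_sigma * sigma, np.pi)
    s = np.linspace(-half, half, config.quadrature_points)
    state = hess.state
    q0 = state.q
    ti = state.torsion_indices
    e0 = conformer.energy
    du = np.empty_like(s)
    for k, sk in enumerate(s):
        q = q0.copy()
        q[ti] = q[ti] + sk * vec
        x = bat_to_cartesian(state.with_q(q))
        du[k] = potential_energy(system, x, solvation) - e0
    w = np.exp(-du / rt)
    z = np.trapezoid(w, s)
    mean_du = np.trapezoid(du * w, s) / z
    return float(z), float(mean_du)


# ---------------------------------------------------------------------------
# Accumulation into a ledger
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyLedger:
    """Accumulated thermodynamics of one species."""

    label: str
    conformers: list
    config: ThermoConfig
    free_energy: float = np.nan          # G0, kcal/mol
    mean_energy: float = np.nan          # <U+W>, kcal/mol
    minus_t_s_config: float = np.nan     # -T S_config = G0 - <U+W>
    weights: np.ndarray = None           # Boltzmann weights, sum to 1
    n_conformers_window: int = 0         # M within the retention window
    retention_window: float = 10.0       # in RT
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "temperature": self.config.temperature,
            "standard_concentration": self.config.standard_concentration,
            "free_energy": self.free_energy,
            "mean_energy": self.mean_energy,
            "minus_t_s_config": self.minus_t_s_config,
            "n_conformers": len(self.conformers),
            "n_conformers_window": self.n_conformers_window,
            "weights": self.weights.tolist() if self.weights is not None else None,
            "conformer_energies": [r.energy for r in self.conformers],
            "history": list(self.history),
        }


def accumulate_free_energy(conformers: list, config: ThermoConfig = None,
                           label: str = "species", retention_window: float = 10.0,
                           history: list = None) -> FreeEnergyLedger:
    """Fold local integrals into G0, <U+W> and -T S_config.

    Uses log-sum-exp so arbitrarily deep wells cannot overflow.  Conformer
    order never changes the result.
    """
    config = config or ThermoConfig()
    if not conformers:
        raise ThermoError("cannot accumulate an empty conformer list")
    for r in conformers:
        if r.log_z is None:
            raise ThermoError("conformer has no local integral; run local_integral first")
    logz = np.array([r.log_z for r in conformers], dtype=float)
    m = np.max(logz)
    log_total = m + np.log(np.sum(np.exp(logz - m)))
    rt = config.rt
    g = -rt * (config.external_log_factor + log_total)
    w = np.exp(logz - log_total)
    mean_e = float(np.sum(w * np.array([r.mean_energy for r in conformers])))
    energies = np.array([r.energy for r in conformers])
    m_window = int(np.sum(energies <= np.min(energies) + retention_window * rt))
    return FreeEnergyLedger(
        label=label, conformers=list(conformers), config=config,
        free_energy=float(g), mean_energy=mean_e,
        minus_t_s_config=float(g - mean_e), weights=w,
        n_conformers_window=m_window, retention_window=retention_window,
        history=list(history) if history else [],
    )


# ---------------------------------------------------------------------------
# Binding free energy and entropy split
# ---------------------------------------------------------------------------

@dataclass
class BindingResult:
    """Standard binding free energy and its decomposition."""

    delta_g: float                 # kcal/mol at the 1 M standard state
    delta_mean_energy: float       # Delta <U+W>
    minus_t_delta_s: float         # -T Delta S_config
    components: dict = None        # term-by-term Delta <.> differences
    label: str = ""

    def to_dict(self) -> dict:
        return {"label": self.label, "delta_g": self.delta_g,
                "delta_mean_energy": self.delta_mean_energy,
                "minus_t_delta_s": self.minus_t_delta_s,
                "components": self.components}


def binding_free_energy(complex_ledger: FreeEnergyLedger,
                        receptor_ledger: FreeEnergyLedger,
                        ligand_ledger: FreeEnergyLedger,
                        label: str = "") -> BindingResult:
    """Delta G0 = G0_complex - G0_receptor - G0_ligand, with decomposition.

    The identity Delta G0 = Delta<U+W> + (-T Delta S_config) holds to
    machine precision by construction.
    """
    cfgs = (complex_ledger.config, receptor_ledger.config, ligand_ledger.config)
    if not (cfgs[0].compatible_with(cfgs[1]) and cfgs[0].compatible_with(cfgs[2])):
        raise ThermoError("ledgers computed at different temperature or standard state")
    dg = complex_ledger.free_energy - receptor_ledger.free_energy - ligand_ledger.free_energy
    duw = complex_ledger.mean_energy - receptor_ledger.mean_energy - ligand_ledger.mean_energy
    mtds = (complex_ledger.minus_t_s_config - receptor_ledger.minus_t_s_config
            - ligand_ledger.minus_t_s_config)
    comps = None
    if all(l.conformers and l.conformers[0].components is not None
           for l in (complex_ledger, receptor_ledger, ligand_ledger)):
        comps = {}
        for key in ("val", "vdw", "coul", "w"):
            def avg(ledger):
                vals = np.array([r.components[key] for r in ledger.conformers])
                return float(np.sum(ledger.weights * vals))
            comps[key] = avg(complex_ledger) - avg(receptor_ledger) - avg(ligand_ledger)
    return BindingResult(delta_g=float(dg), delta_mean_energy=float(duw),
                         minus_t_delta_s=float(mtds), components=comps, label=label)


def entropy_split(ledger: FreeEnergyLedger, n_bound_conformations: int = 1):
    """Split -T S_config into conformational and vibrational parts.

    The conformational penalty counts wells: RT ln(M / k) with M the number
    of conformations within the retention window and k the number of bound
    conformations credited; the vibrational part is the remainder (average
    well width).  Returns ``(minus_t_ds_conf, minus_t_ds_vib)``.
    """
    m = ledger.n_conformers_window
    if m == 0:
        raise ThermoError("ledger has no conformers within the retention window")
    if not (1 <= n_bound_conformations <= m):
        raise ThermoError("need M >= n_bound_conformations >= 1")
    rt = ledger.config.rt
    conf = rt * np.log(m / n_bound_conformations)
    vib = ledger.minus_t_s_config - conf
    return float(conf), float(vib)


def conformational_entropy_bound(n_conformations: int, n_bound: int = 1,
                                 temperature: float = 300.0) -> float:
    """RT ln(M / k): the maximum conformational-entropy penalty (kcal/mol).

    E.g. 482 free wells collapsing to one bound pose at 300 K cost at most
    RT ln 482 ~ 3.7 kcal/mol.
    """
    if n_conformations < 1 or n_bound < 1:
        raise ThermoError("conformation counts must be >= 1")
    return R_KCAL * temperature * float(np.log(n_conformations / n_bound))
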