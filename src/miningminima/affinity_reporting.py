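"""Experimental affinity conversions and enthalpy--entropy compensation.

Measured IC50 or dissociation constants are converted to (relative) binding
free energies through

    ddG = RT ln( IC50_X / IC50_ref )          (relative, same assay)
    dG  = RT ln( K_d [mol/L] )                (absolute, 1 M standard state)

at T = 300 K with R = 1.9872e-3 kcal/(mol K).  Censored measurements
(e.g. "IC50 > 250 uM") propagate as one-sided bounds, never as values.
The compensation table collects (Delta<U+W>, -T Delta S) pairs across a
ligand series and fits the entropic term on the enthalpic one by ordinary
least squares with a confidence interval on the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_KCAL


class AffinityError(ValueError):
    pass


@dataclass(frozen=True)
class CensoredBound:
    """A one-sided bound on a derived free energy (kcal/mol)."""

    bound: float
    direction: str   # ">" or "<"

    def __str__(self):
        return f"{self.direction}{self.bound:.2f}"


@dataclass
class AffinityRecord:
    """One measured ligand affinity."""

    ligand_id: str
    measure: str              # "IC50" or "Kd"
    value_uM: float           # the value, or the bound if censored
    uncertainty_uM: float = None
    censored: bool = False    # True: value_uM is a lower bound ("> value")

    def __post_init__(self):
        if self.measure not in ("IC50", "Kd"):
            raise AffinityError(f"unknown measure {self.measure!r}")
        if self.value_uM <= 0:
            raise AffinityError("IC50/Kd must be > 0")


def _rt(temperature: float) -> float:
    return R_KCAL * temperature


def ic50_to_relative_dg(ic50_x_uM: float, ic50_ref_uM: float,
                        temperature: float = DEFAULT_TEMPERATURE,
                        censored: bool = False):
    """ddG = RT ln(IC50_X / IC50_ref), kcal/mol; antisymmetric in its arguments.

    With ``censored=True`` the first argument is a lower bound and the result
    is returned as a :class:`CensoredBound` (ddG > RT ln(bound/ref)).
    """
    if ic50_x_uM <= 0 or ic50_ref_uM <= 0:
        raise AffinityError("IC50 values must be > 0")
    ddg = _rt(temperature) * float(np.log(ic50_x_uM / ic50_ref_uM))
    if censored:
        return CensoredBound(bound=ddg, direction=">")
    return ddg


def kd_to_dg(kd_uM: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """dG = RT ln(K_d) with K_d converted from uM to mol/L, kcal/mol."""
    if kd_uM <= 0:
        raise AffinityError("Kd must be > 0")
    return _rt(temperature) * float(np.log(kd_uM * 1e-6))


def ic50_to_dg_enzyme_corrected(ic50_uM: float, c_enzyme_uM: float = 0.0,
                                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """dG = RT ln(IC50 + 0.5 C_enzyme) in mol/L, kcal/mol.

    The half-enzyme-concentration correction accounts for ligand depletion
    in a competition assay; it reduces to :func:`kd_to_dg` at C_enzyme = 0.
    """
    if ic50_uM <= 0 or c_enzyme_uM < 0:
        raise AffinityError("concentrations must be positive")
    return _rt(temperature) * float(np.log((ic50_uM + 0.5 * c_enzyme_uM) * 1e-6))


# ---------------------------------------------------------------------------
# Batch conversion
# ---------------------------------------------------------------------------

def convert_affinity_table(records: Iterable, reference_id: str = None,
                           temperature: float = DEFAULT_TEMPERATURE) -> pd.DataFrame:
    """Convert a panel of affinity records to (relative) free energies.

    IC50 rows are converted to ddG against ``reference_id`` (required when
    IC50 rows are present); Kd rows are converted to absolute dG.  Censored
    rows appear with ``censored=True`` and the bound in the value column.
    """
    records = [r if isinstance(r, AffinityRecord) else AffinityRecord(**r)
               for r in records]
    ref = None
    if any(r.measure == "IC50" for r in records):
        if reference_id is None:
            raise AffinityError("IC50 rows need a reference ligand")
        ref = next((r for r in records if r.ligand_id == reference_id), None)
        if ref is None:
            raise AffinityError(f"reference ligand {reference_id!r} not in the table")
        if ref.censored:
            raise AffinityError("reference ligand must not be censored")
    rows = []
    for r in records:
        if r.measure == "IC50":
            res = ic50_to_relative_dg(r.value_uM, ref.value_uM, temperature,
                                      censored=r.censored)
            kind = "ddG"
        else:
            if r.censored:
                res = CensoredBound(kd_to_dg(r.value_uM, temperature), ">")
            else:
                res = kd_to_dg(r.value_uM, temperature)
            kind = "dG"
        if isinstance(res, CensoredBound):
            rows.append({"ligand_id": r.ligand_id, "quantity": kind,
                         "value_kcal_mol": res.bound, "censored": True,
                         "direction": res.direction})
        else:
            rows.append({"ligand_id": r.ligand_id, "quantity": kind,
                         "value_kcal_mol": res, "censored": False,
                         "direction": "="})
    return pd.DataFrame(rows)


def read_affinity_csv(path) -> list:
    """Read `id,measure,value_uM,censored` CSV into AffinityRecords."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(AffinityRecord(
            ligand_id=str(row["id"]), measure=str(row["measure"]),
            value_uM=float(row["value_uM"]),
            censored=bool(row.get("censored", False))))
    return out


# ---------------------------------------------------------------------------
# Enthalpy--entropy compensation
# ---------------------------------------------------------------------------

@dataclass
class CompensationFit:
    slope: float
    intercept: float
    intercept_ci: tuple      # (low, high), 95 %
    slope_ci: tuple
    r_squared: float
    n: int


def compensation_table(entries: Iterable, alpha: float = 0.05):
    """Tabulate (Delta<U+W>, -T Delta S) pairs and fit one on the other.

    ``entries``: iterables of (label, delta_mean_energy, minus_t_delta_s) or
    objects with those attributes (e.g. BindingResult).  Returns
    ``(DataFrame, CompensationFit or None)``; the fit is declined (None) for
    fewer than 3 points or a degenerate (zero-variance) energy column.
    """
    import statsmodels.api as sm

    rows = []
    for e in entries:
        if hasattr(e, "delta_mean_energy"):
            rows.append({"label": getattr(e, "label", ""),
                         "delta_mean_energy": e.delta_mean_energy,
                         "minus_t_delta_s": e.minus_t_delta_s})
        else:
            label, duw, mtds = e
            rows.append({"label": label, "delta_mean_energy": float(duw),
                         "minus_t_delta_s": float(mtds)})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        return table, None
    x = table["delta_mean_energy"].to_numpy()
    y = table["minus_t_delta_s"].to_numpy()
    if np.ptp(x) < 1e-12:
        return table, None   # declined: no variance in the predictor
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    fit = CompensationFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(model.rsquared), n=len(table))
    return table, fit


# ---------------------------------------------------------------------------
# Published BRCT(BRCA1) ligand panel
# ---------------------------------------------------------------------------

#: Measured affinities of the BRCT(BRCA1) ligand library: pSer-X-X-Phe
#: tetrapeptides and analogs (IC50, competition assay, vs the reference
#: peptide P1) and four long phosphopeptides (Kd).  ">250" entries are
#: censored at the assay ceiling.
BRCT_LIGAND_PANEL = [
    AffinityRecord("P1", "IC50", 1.0, 0.2),
    AffinityRecord("P2", "IC50", 1.6, 0.3),
    AffinityRecord("P3", "IC50", 3.2, 0.8),
    AffinityRecord("P4", "IC50", 4.6, 0.9),
    AffinityRecord("P5", "IC50", 7.1, 1.4),
    AffinityRecord("P6", "IC50", 14.9, 2.8),
    AffinityRecord("P7", "IC50", 15.0, 1.7),
    AffinityRecord("P8", "IC50", 18.4, 1.8),
    AffinityRecord("P9", "IC50", 30.1, 7.2),
    AffinityRecord("P10", "IC50", 35.0, 7.9),
    AffinityRecord("P11", "IC50", 52.8, 1.6),
    AffinityRecord("P12", "IC50", 98.4, 23.1),
    AffinityRecord("P13", "IC50", 250.0, censored=True),
    AffinityRecord("P14", "IC50", 250.0, censored=True),
    AffinityRecord("C1", "IC50", 0.31),
    AffinityRecord("N1", "IC50", 250.0, censored=True),
    AffinityRecord("L1", "Kd", 0.9),
    AffinityRecord("L2", "Kd", 3.7),
    AffinityRecord("L3", "Kd", 0.4),
    AffinityRecord("L4", "Kd", 5.2),
]

#: Expected relative/absolute free energies (kcal/mol) as printed for the
#: non-censored rows of the panel, used for round-trip verification.
BRCT_PANEL_PRINTED = {
    "P1": 0.00, "P2": 0.28, "P3": 0.69, "P4": 0.91, "P5": 1.17, "P6": 1.61,
    "P7": 1.61, "P8": 1.74, "P9": 2.03, "P10": 2.12, "P11": 2.36, "P12": 2.74,
    "C1": -0.70,
    "L1": -8.30, "L2": -7.46, "L3": -8.78, "L4": -7.25,
}
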