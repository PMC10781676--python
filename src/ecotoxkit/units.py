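"""Standardization of concentration and solubility values to mg/L.

ECOTOX effect records report concentrations in a mix of mass-per-volume
(g/L, mg/L, µg/L, ng/L), dimensionless mass ratios (ppm, ppb; equated to
mg/L and µg/L under the dilute aqueous assumption), and molar units
(mol/L, mmol/L, µmol/L).  Molar units require the chemical's average
molecular mass in g/mol.  Unsupported units never raise: they yield a
missing value and are tallied in a :class:`UnitReport` so losses stay
auditable across a release-wide run.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MASS_FACTORS",
    "MOLAR_FACTORS",
    "UnitReport",
    "normalize_unit",
    "is_aqueous_unit",
    "dosing_group_for_unit",
    "to_mg_per_L",
    "sw_to_mg_per_L",
    "standardize_concentrations",
    "read_mol_weight_table",
]

# factor × value gives mg/L directly
MASS_FACTORS: dict[str, float] = {
    "g/l": 1e3,
    "mg/l": 1.0,
    "ug/l": 1e-3,
    "ng/l": 1e-6,
    "ppm": 1.0,    # dilute aqueous: 1 ppm ≡ 1 mg/L
    "ppb": 1e-3,   # 1 ppb ≡ 1 µg/L
}

# factor × value × mw gives mg/L (mw in g/mol)
MOLAR_FACTORS: dict[str, float] = {
    "mol/l": 1e3,
    "mmol/l": 1.0,
    "umol/l": 1e-3,
    "m": 1e3,
    "mm": 1.0,
    "um": 1e-3,
}

# units that dose the test medium itself (water concentration) as opposed to
# body burden (per kg organism) or food/soil dosing
_BODY_BURDEN_TOKENS = ("/kg", "/g bdwt", "bdwt", "/mg org")

_UNIT_ALIASES = {
    "µg/l": "ug/l",
    "μg/l": "ug/l",
    "µmol/l": "umol/l",
    "μmol/l": "umol/l",
    "µm": "um",
    "ppm w/v": "ppm",
    "mg/dm3": "mg/l",
    "g/dm3": "g/l",
    "ae mg/l": "mg/l",
    "ai mg/l": "mg/l",
}


def normalize_unit(unit: str | None) -> str:
    """Lower-case, trim, and collapse known spelling variants of a unit code."""
    if unit is None or (isinstance(unit, float) and math.isnan(unit)):
        return ""
    u = str(unit).strip().lower()
    return _UNIT_ALIASES.get(u, u)


def is_aqueous_unit(unit: str) -> bool:
    """True if the unit expresses a concentration in the aqueous test medium."""
    u = normalize_unit(unit)
    return u in MASS_FACTORS or u in MOLAR_FACTORS


def dosing_group_for_unit(unit: str) -> str:
    """Classify a dosing unit into a dosing group.

    Aqueous concentration units map to ``"water_concentration"`` (the only
    group the curation keeps), mass-per-body-weight units to
    ``"body_burden"``, anything else to ``"other"``.
    """
    u = normalize_unit(unit)
    if is_aqueous_unit(u):
        return "water_concentration"
    if any(tok in u for tok in _BODY_BURDEN_TOKENS):
        return "body_burden"
    return "other"


@dataclass
class UnitReport:
    """Tally of conversions that could not be performed."""

    unsupported: Counter = field(default_factory=Counter)
    missing_mw: Counter = field(default_factory=Counter)

    @property
    def n_lost(self) -> int:
        return sum(self.unsupported.values()) + sum(self.missing_mw.values())


def to_mg_per_L(
    value: float,
    unit: str,
    mw: float | None = None,
    report: UnitReport | None = None,
) -> float:
    """Convert a single concentration to mg/L.

    Parameters
    ----------
    value
        Concentration, finite and > 0.
    unit
        Unit code; spelling variants are normalized first.
    mw
        Average molecular mass in g/mol; required for molar units.
    report
        Optional :class:`UnitReport` collecting unsupported units and
        molar conversions lacking a molecular weight.

    Returns
    -------
    float
        Concentration in mg/L, or NaN when the unit is unsupported or a
        molar unit has no molecular weight.
    """
    if value is None or not np.isfinite(value):
        return float("nan")
    if value <= 0:
        raise ValueError(f"concentration must be > 0, got {value!r}")
    u = normalize_unit(unit)
    if u in MASS_FACTORS:
        return value * MASS_FACTORS[u]
    if u in MOLAR_FACTORS:
        if mw is None or not np.isfinite(mw) or mw <= 0:
            if report is not None:
                report.missing_mw[u] += 1
            return float("nan")
        return value * MOLAR_FACTORS[u] * mw
    if report is not None:
        report.unsupported[u] += 1
    return float("nan")


def sw_to_mg_per_L(log_sw: float, mw: float) -> float:
    """Water solubility in mg/L from log10 solubility in mol/L.

    ``Sw[mg/L] = 10**logSw * mw * 1000`` with ``mw`` in g/mol.
    """
    if mw is None or not np.isfinite(mw) or mw <= 0:
        return float("nan")
    if log_sw is None or not np.isfinite(log_sw):
        return float("nan")
    return 10.0 ** log_sw * mw * 1000.0


def standardize_concentrations(
    records: pd.DataFrame,
    mw_by_cas: dict[str, float] | pd.Series | None = None,
    value_col: str = "conc_value",
    unit_col: str = "conc_unit",
    cas_col: str = "cas_number",
    out_col: str = "conc_mg_per_L",
) -> tuple[pd.DataFrame, UnitReport]:
    """Add an mg/L column to a joined-record table.

    Molar units are resolved through ``mw_by_cas`` (the
    ``ecotoxgroup_mol_weight.csv`` lookup keyed by digits-only CAS).
    Returns the augmented copy and the :class:`UnitReport` of losses.
    """
    if isinstance(mw_by_cas, pd.Series):
        mw_by_cas = mw_by_cas.to_dict()
    mw_by_cas = mw_by_cas or {}
    report = UnitReport()
    out = records.copy()

    def _convert(row: pd.Series) -> float:
        v = row[value_col]
        if pd.isna(v):
            return float("nan")
        mw = mw_by_cas.get(str(row[cas_col]))
        return to_mg_per_L(float(v), row[unit_col], mw=mw, report=report)

    out[out_col] = out.apply(_convert, axis=1) if len(out) else pd.Series(dtype=float)
    return out, report


def read_mol_weight_table(path, cas_col: str = "cas_number",
                          mw_col: str = "average_mass") -> dict[str, float]:
    """Read a molecular-weight lookup CSV into a digits-only-CAS → g/mol dict."""
    from .io import normalize_cas  # local import to avoid a cycle

    df = pd.read_csv(path, dtype={cas_col: str})
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        key = normalize_cas(row[cas_col])
        mw = pd.to_numeric(row[mw_col], errors="coerce")
        if key and pd.notna(mw) and mw > 0:
            out[key] = float(mw)
    return out
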