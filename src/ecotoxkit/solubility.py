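"""Solubility-domain classification of effect concentrations.

A chemical cannot truly be tested above its water solubility: nominal
effect concentrations above the solubility limit are suspect because the
dissolved exposure was likely lower than dosed.  Each aggregated effect
concentration is therefore compared against the chemical's predicted water
solubility Sw (mg/L) and assigned an ordinal class:

* class 3 — ECx ≤ Sw (within solubility; valid)
* class 2 — Sw < ECx ≤ Sw·10^0.5 (up to half a log step above; tolerable,
  solvation agents or test media can enhance solubility this far)
* class 1 — Sw·10^0.5 < ECx ≤ Sw·10^1.0 (half to one log step above)
* class 0 — ECx > Sw·10^1.0 (more than one log step above; use with
  caution, confirm experimentally)

The half-step and full-step boundary exponents are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .aggregate import STATISTIC_NAMES, AggregateSummary
from .units import sw_to_mg_per_L

__all__ = [
    "DEFAULT_BOUNDARY_EXPONENTS",
    "SolubilityProfile",
    "classify_domain",
    "classify_summary",
    "read_solubility_output",
]

#: log10 multiples of Sw separating classes 2|1 and 1|0 (class 3|2 sits at Sw)
DEFAULT_BOUNDARY_EXPONENTS = (0.5, 1.0)


@dataclass(frozen=True)
class SolubilityProfile:
    """Predicted water solubility of one chemical.

    ``log_sw`` is log10 of the solubility in mol/L as exported by the
    solubility QSAR; ``sw_mg_per_L`` the derived value in mg/L; ``ad_flag``
    passes the predictor's applicability-domain text through verbatim.
    """

    chemical_id: str
    log_sw: float
    mw: float
    sw_mg_per_L: float = float("nan")
    ad_flag: str = ""

    def __post_init__(self):
        if np.isnan(self.sw_mg_per_L):
            object.__setattr__(
                self, "sw_mg_per_L", sw_to_mg_per_L(self.log_sw, self.mw)
            )


def classify_domain(
    ecx: float,
    sw: float,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARY_EXPONENTS,
) -> float:
    """Solubility-domain class of one effect concentration.

    Both ``ecx`` and ``sw`` are mg/L.  Returns 3, 2, 1 or 0 (see module
    docstring); missing ``sw`` yields NaN.  Non-positive inputs are errors.
    """
    if sw is None or (isinstance(sw, float) and np.isnan(sw)):
        return float("nan")
    if ecx is None or np.isnan(ecx):
        return float("nan")
    if ecx <= 0 or sw <= 0:
        raise ValueError(f"ecx and sw must be > 0, got ecx={ecx}, sw={sw}")
    half, full = boundaries
    if ecx <= sw:
        return 3.0
    if ecx <= sw * 10.0 ** half:
        return 2.0
    if ecx <= sw * 10.0 ** full:
        return 1.0
    return 0.0


def classify_summary(
    summary: AggregateSummary,
    profile: SolubilityProfile | None,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARY_EXPONENTS,
) -> AggregateSummary:
    """Attach one domain class per statistic (P5, mean, geomean, median,
    min, max) to an aggregate summary.

    A missing profile yields all-missing classes.  Because the classifier
    is non-increasing in the effect concentration, class(min) ≥ class(max)
    always holds within one summary.
    """
    sw = profile.sw_mg_per_L if profile is not None else float("nan")
    classes = {
        s: classify_domain(summary.statistic(s), sw, boundaries)
        for s in STATISTIC_NAMES
    }
    return replace(summary, classes=classes)


def read_solubility_output(
    path,
    id_col: str = "MoleculeID",
    log_sw_col: str = "LogWS_pred",
    ad_col: str = "AD_WS",
    mw_by_id: dict[str, float] | None = None,
) -> dict[str, SolubilityProfile]:
    """Parse the solubility predictor's delimited export into profiles.

    Column names default to the OPERA CSV layout and are overridable.
    ``mw_by_id`` supplies molecular weights keyed by the same compound ID;
    compounds without a weight get a NaN Sw (classes stay missing).
    """
    df = pd.read_csv(path, dtype={id_col: str})
    for col in (id_col, log_sw_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not in solubility output (has {list(df.columns)})"
            )
    mw_by_id = mw_by_id or {}
    profiles: dict[str, SolubilityProfile] = {}
    for _, row in df.iterrows():
        cid = str(row[id_col])
        if cid in profiles:
            raise ValueError(f"duplicate compound {cid!r} in solubility output")
        profiles[cid] = SolubilityProfile(
            chemical_id=cid,
            log_sw=float(pd.to_numeric(row[log_sw_col], errors="coerce")),
            mw=float(mw_by_id.get(cid, float("nan"))),
            ad_flag=str(row[ad_col]) if ad_col in df.columns and pd.notna(row.get(ad_col)) else "",
        )
    return profiles
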