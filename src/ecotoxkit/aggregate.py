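"""Aggregation of filtered effect records into one summary per chemical × BQE.

For every chemical and biological quality element (algae, crustaceans, or
fish) the curation reduces all retained mg/L effect concentrations to seven
statistics — n, 5th percentile, arithmetic mean, geometric mean, median,
minimum, maximum — each rounded to four significant digits *after*
computation on the unrounded values.  The raw values and their provenance
(endpoints, effects, measurements, species, durations, reference IDs) are
collapsed into one delimited string per category so every aggregate remains
reviewable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "PROVENANCE_DELIMITER",
    "AggregateSummary",
    "percentile",
    "geometric_mean",
    "signif_round",
    "collapse_provenance",
    "summarize_chemical",
    "summarize_all",
    "datapoint_spread",
]

#: intra-field delimiter for collapsed provenance strings; distinct from the
#: CSV field delimiter and survives a quoted CSV round trip
PROVENANCE_DELIMITER = "; "

STATISTIC_NAMES = ("P5", "mean", "geomean", "median", "min", "max")

PROVENANCE_CATEGORIES = {
    "raw_values": "conc_mg_per_L",
    "endpoints": "endpoint",
    "effects": "effect",
    "measurements": "measurement",
    "species": "species_name",
    "durations": "duration",
    "references": "reference_number",
}


def percentile(values, p: float) -> float:
    """Linear-interpolation percentile on sorted order statistics.

    With ``n`` sorted values ``x(1..n)`` and rank ``h = (n-1)p + 1`` the
    result is ``x(⌊h⌋) + (h-⌊h⌋)·(x(⌈h⌉) - x(⌊h⌋))`` — the type-7 scheme
    that is the default of R's ``quantile`` and therefore the one the
    published tables were computed with.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("percentile of empty input")
    if n == 1:
        return float(x[0])
    h = (n - 1) * p + 1  # 1-based rank
    lo = int(math.floor(h))
    hi = int(math.ceil(h))
    return float(x[lo - 1] + (h - lo) * (x[hi - 1] - x[lo - 1]))


def geometric_mean(values) -> float:
    """exp(mean(log x)); all values must be strictly positive."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of empty input")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def signif_round(x: float, digits: int = 4) -> float:
    """Round to ``digits`` significant digits, ties half-to-even.

    Decimal-exact: the binary double is converted to its exact decimal
    expansion before rounding, so results match IEEE-correct formatting
    (no rescaling round-off).
    """
    if x is None:
        return float("nan")
    x = float(x)
    if not np.isfinite(x):
        return x
    if x == 0:
        return 0.0
    d = Decimal(x)  # exact binary expansion
    q = d.quantize(Decimal(1).scaleb(d.adjusted() - digits + 1),
                   rounding=ROUND_HALF_EVEN)
    return float(q)


@dataclass
class AggregateSummary:
    """One curated effect value set for a chemical within one BQE.

    Statistics are mg/L, rounded to four significant digits; provenance
    fields each collapse n entries with :data:`PROVENANCE_DELIMITER`.
    Solubility-domain classes (one per statistic) are attached later by the
    solubility module and default to missing.
    """

    chemical_id: str
    cas_number: str
    bqe: str
    n: int
    P5: float
    mean: float
    geomean: float
    median: float
    min: float
    max: float
    provenance: dict[str, str] = field(default_factory=dict)
    classes: dict[str, float] = field(default_factory=dict)

    def statistic(self, name: str) -> float:
        if name not in STATISTIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_row(self) -> dict:
        row = {
            "chemical_id": self.chemical_id,
            "cas_number": self.cas_number,
            "bqe": self.bqe,
            "n": self.n,
        }
        for s in STATISTIC_NAMES:
            row[s] = getattr(self, s)
        for cat in PROVENANCE_CATEGORIES:
            row[cat] = self.provenance.get(cat, "")
        for s in STATISTIC_NAMES:
            row[f"class_{s}"] = self.classes.get(s, float("nan"))
        return row

    @classmethod
    def from_row(cls, row: dict) -> "AggregateSummary":
        classes = {
            s: row.get(f"class_{s}", float("nan")) for s in STATISTIC_NAMES
        }
        return cls(
            chemical_id=str(row["chemical_id"]),
            cas_number=str(row["cas_number"]),
            bqe=str(row["bqe"]),
            n=int(row["n"]),
            P5=float(row["P5"]),
            mean=float(row["mean"]),
            geomean=float(row["geomean"]),
            median=float(row["median"]),
            min=float(row["min"]),
            max=float(row["max"]),
            provenance={c: ("" if pd.isna(row.get(c, "")) else str(row.get(c, "")))
                        for c in PROVENANCE_CATEGORIES},
            classes={k: float(v) if pd.notna(v) else float("nan")
                     for k, v in classes.items()},
        )


def collapse_provenance(records: pd.DataFrame) -> dict[str, str]:
    """Collapse each provenance category into one delimited string.

    Values are joined in input order; the entry count per field equals the
    number of records.  ``duration`` joins value and unit ("96 h").
    """
    if len(records) == 0:
        raise ValueError("collapse_provenance of empty record set")
    out: dict[str, str] = {}
    for category, col in PROVENANCE_CATEGORIES.items():
        if category == "durations":
            vals = [
                f"{_fmt(v)} {u}".strip()
                for v, u in zip(records["duration_value"], records["duration_unit"])
            ]
        else:
            vals = [_fmt(v) for v in records[col]]
        out[category] = PROVENANCE_DELIMITER.join(vals)
    return out


def _fmt(v) -> str:
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)
    return str(v)


def summarize_chemical(
    records: pd.DataFrame,
    p: float = 0.05,
    bqe: str | None = None,
    chemical_id: str | None = None,
    digits: int = 4,
) -> AggregateSummary:
    """Compute the seven statistics for one chemical × BQE record group.

    All records must share one chemical (CAS) and one BQE; concentrations
    are taken from the mg/L column.  Statistics are computed on the
    unrounded values, then rounded to ``digits`` significant digits.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record group")
    cas_values = set(records["cas_number"].astype(str))
    if len(cas_values) > 1:
        raise ValueError(f"records mix chemicals: {sorted(cas_values)}")
    if bqe is None:
        groups = set(records["ecotox_group"].astype(str)) if "ecotox_group" in records else set()
        if len(groups) > 1:
            raise ValueError(f"records mix BQEs: {sorted(groups)}")
        bqe = groups.pop() if groups else ""
    values = records["conc_mg_per_L"].astype(float).to_numpy()
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("all concentrations must be finite, positive mg/L")
    r = lambda x: signif_round(x, digits)
    return AggregateSummary(
        chemical_id=str(chemical_id) if chemical_id is not None else "",
        cas_number=cas_values.pop(),
        bqe=str(bqe),
        n=len(values),
        P5=r(percentile(values, p)),
        mean=r(float(np.mean(values))),
        geomean=r(geometric_mean(values)),
        median=r(float(np.median(values))),
        min=r(float(np.min(values))),
        max=r(float(np.max(values))),
        provenance=collapse_provenance(records),
    )


def summarize_all(
    records: pd.DataFrame,
    p: float = 0.05,
    bqe: str | None = None,
    chemical_ids: dict[str, str] | None = None,
) -> list[AggregateSummary]:
    """Group filtered records by chemical and summarize each group.

    ``chemical_ids`` maps digits-only CAS to the internal chemical ID used
    in the published tables; summaries are sorted by that ID (falling back
    to CAS) as the output tables require.
    """
    chemical_ids = chemical_ids or {}
    summaries = []
    for cas, group in records.groupby("cas_number", sort=False):
        summaries.append(
            summarize_chemical(
                group, p=p, bqe=bqe,
                chemical_id=chemical_ids.get(str(cas), str(cas)),
            )
        )
    summaries.sort(key=lambda s: (s.chemical_id, s.cas_number))
    return summaries


def datapoint_spread(summaries: list[AggregateSummary]) -> dict[str, float]:
    """Geometric mean and geometric SD of data points per chemical.

    The catalog reports the spread of per-chemical data-point counts as
    geoMean/geoSD; both are returned along with the plain total.
    """
    counts = np.array([s.n for s in summaries], dtype=float)
    if counts.size == 0:
        return {"total": 0, "geomean": float("nan"), "geosd": float("nan")}
    logs = np.log(counts)
    return {
        "total": int(counts.sum()),
        "geomean": float(np.exp(logs.mean())),
        "geosd": float(np.exp(logs.std(ddof=1))) if counts.size > 1 else float("nan"),
    }
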