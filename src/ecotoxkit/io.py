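"""Reading ECOTOX-style release archives and writing curated output tables.

ECOTOX knowledgebase releases are ZIP archives of pipe-delimited ASCII
tables (one header row, UTF-8 with legacy Latin-1 stragglers).  The
curation consumes five of them — tests, results, species, chemicals,
references — joins them on their ID columns into one flat effect-record
table, and finally writes one curated summary table per species group in
the published CSV schema.
"""

from __future__ import annotations

import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import (
    PROVENANCE_CATEGORIES,
    STATISTIC_NAMES,
    AggregateSummary,
)
from .units import dosing_group_for_unit

__all__ = [
    "DEFAULT_TABLES",
    "RawTables",
    "JoinReport",
    "read_ecotox_archive",
    "join_records",
    "read_chemical_list",
    "write_bqe_table",
    "read_bqe_table",
    "normalize_cas",
    "parse_concentration",
]

DEFAULT_TABLES = ("tests", "results", "species", "chemicals", "references")


@dataclass
class RawTables:
    """The five release tables as string DataFrames, column names lower-cased."""

    tests: pd.DataFrame
    results: pd.DataFrame
    species: pd.DataFrame
    chemicals: pd.DataFrame
    references: pd.DataFrame
    release_tag: str = ""

    def table(self, name: str) -> pd.DataFrame:
        if name not in DEFAULT_TABLES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class JoinReport:
    """Accounting of rows lost while joining the release tables."""

    n_results: int = 0
    n_joined: int = 0
    orphans: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_results - self.n_joined


def _read_table(data: bytes, name: str, lenient: bool = False) -> pd.DataFrame:
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        text = data.decode("latin-1")
    from io import StringIO

    df = pd.read_csv(
        StringIO(text),
        sep="|",
        dtype=str,
        quotechar='"',
        keep_default_na=False,
        on_bad_lines="warn" if lenient else "error",
        engine="python",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_ecotox_archive(
    path,
    tables: tuple[str, ...] = DEFAULT_TABLES,
    lenient: bool = False,
) -> RawTables:
    """Load the requested pipe-delimited tables from a release archive.

    ``path`` may be a ZIP archive or a directory of ``<table>.txt`` files.
    A requested table missing from the archive raises a ``FileNotFoundError``
    naming it and listing what is available.  Under ``lenient=True`` rows
    with the wrong field count are skipped with a warning instead of
    raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"archive not found: {path}")
    loaded: dict[str, pd.DataFrame] = {}
    if path.is_dir():
        available = {p.stem: p for p in path.glob("*.txt")}
        for name in tables:
            if name not in available:
                raise FileNotFoundError(
                    f"table {name!r} not in {path}; available: {sorted(available)}"
                )
            loaded[name] = _read_table(available[name].read_bytes(), name, lenient)
    else:
        with zipfile.ZipFile(path) as zf:
            members = {Path(m).stem: m for m in zf.namelist() if m.endswith(".txt")}
            for name in tables:
                if name not in members:
                    raise FileNotFoundError(
                        f"table {name!r} not in {path.name}; "
                        f"available: {sorted(members)}"
                    )
                loaded[name] = _read_table(zf.read(members[name]), name, lenient)
    empty = pd.DataFrame()
    return RawTables(
        tests=loaded.get("tests", empty),
        results=loaded.get("results", empty),
        species=loaded.get("species", empty),
        chemicals=loaded.get("chemicals", empty),
        references=loaded.get("references", empty),
        release_tag=path.name,
    )


def normalize_cas(cas) -> str:
    """Canonical digits-only CAS key: strip hyphens/spaces, keep leading zeros.

    Returns ``""`` for missing or digit-free input.
    """
    if cas is None or (isinstance(cas, float) and np.isnan(cas)):
        return ""
    s = re.sub(r"[\s\-]", "", str(cas).strip())
    return s if s.isdigit() else ""


_QUALIFIERS = {">": "censored-above", "<": "censored-below", "~": "approximate"}


def parse_concentration(text) -> tuple[float, str]:
    """Split a reported concentration into (numeric value, qualifier flag).

    Leading ``>``, ``<`` or ``~`` become the flags ``censored-above``,
    ``censored-below`` and ``approximate``; a trailing ``*`` (author-
    calculated marker) is dropped; non-numeric remnants such as ``NR``
    yield NaN with flag ``none``.
    """
    if text is None:
        return float("nan"), "none"
    s = str(text).strip()
    flag = "none"
    if s[:1] in _QUALIFIERS:
        flag = _QUALIFIERS[s[:1]]
        s = s[1:].strip()
    s = s.rstrip("*").replace(",", "")  # thousands separators, never decimals
    try:
        value = float(s)
    except ValueError:
        return float("nan"), "none"
    return value, flag


#: canonical columns of a joined effect record
JOINED_COLUMNS = [
    "test_id", "cas_number", "species_number", "reference_number",
    "ecotox_group", "habitat", "species_name",
    "endpoint", "effect", "measurement", "dosing_group",
    "conc_value", "conc_qualifier", "conc_unit",
    "duration_value", "duration_unit",
]


def _require_unique(df: pd.DataFrame, key: str, table: str) -> None:
    if df[key].duplicated().any():
        dup = df[key][df[key].duplicated()].iloc[0]
        raise ValueError(f"duplicate key {key}={dup!r} in table {table!r} (ambiguous join)")


def join_records(raw: RawTables) -> tuple[pd.DataFrame, JoinReport]:
    """Join results → tests → species/chemicals/references into flat records.

    One output row per results row whose ``test_id`` resolves to a test and
    whose test keys resolve in the species, chemicals and references
    tables.  Unresolvable rows are dropped and counted per key in the
    returned :class:`JoinReport`.  Duplicate primary keys in any lookup
    table raise (the join would be ambiguous).
    """
    results, tests = raw.results.copy(), raw.tests.copy()
    report = JoinReport(n_results=len(results))
    if len(results) == 0:
        return pd.DataFrame(columns=JOINED_COLUMNS), report

    for df, key, table in (
        (tests, "test_id", "tests"),
        (raw.species, "species_number", "species"),
        (raw.chemicals, "cas_number", "chemicals"),
        (raw.references, "reference_number", "references"),
    ):
        if key not in df.columns:
            raise ValueError(f"key column {key!r} missing from table {table!r}")
        _require_unique(df, key, table)

    m = results.merge(tests, on="test_id", how="inner", suffixes=("", "_test"))
    report.orphans["test_id"] = len(results) - len(m)

    n = len(m)
    m = m.merge(
        raw.species[["species_number", "latin_name", "ecotox_group", "habitat"]],
        on="species_number", how="inner",
    )
    report.orphans["species_number"] = n - len(m)

    n = len(m)
    m = m.merge(raw.chemicals[["cas_number"]], on="cas_number", how="inner")
    report.orphans["cas_number"] = n - len(m)

    n = len(m)
    m = m.merge(raw.references[["reference_number"]], on="reference_number", how="inner")
    report.orphans["reference_number"] = n - len(m)

    parsed = m["conc1_mean"].map(parse_concentration)
    out = pd.DataFrame(
        {
            "test_id": m["test_id"],
            "cas_number": m["cas_number"].map(normalize_cas),
            "species_number": m["species_number"],
            "reference_number": m["reference_number"],
            "ecotox_group": m["ecotox_group"].str.strip(),
            "habitat": m["habitat"].str.strip(),
            "species_name": m["latin_name"].str.strip(),
            "endpoint": m["endpoint"].str.strip(),
            "effect": m["effect"].str.strip(),
            "measurement": m["measurement"].str.strip() if "measurement" in m else "",
            "conc_value": [v for v, _ in parsed],
            "conc_qualifier": [q for _, q in parsed],
            "conc_unit": m["conc1_unit"].str.strip(),
            "duration_value": pd.to_numeric(m["obs_duration_mean"], errors="coerce"),
            "duration_unit": m["obs_duration_unit"].str.strip().str.lower(),
        }
    )
    out["dosing_group"] = out["conc_unit"].map(dosing_group_for_unit)
    out = out[JOINED_COLUMNS].reset_index(drop=True)
    report.n_joined = len(out)
    return out, report


def read_chemical_list(path, sep: str = ",") -> pd.DataFrame:
    """Read the study's chemical list (Table B layout) into a DataFrame.

    Adds ``cas_key`` (digits-only CAS; empty string when no CAS, such
    entries stay in the list but can never match an effect record).
    Duplicate internal IDs raise.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    id_col = "id" if "id" in df.columns else df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate internal ID {dup!r} in chemical list")
    cas_col = next((c for c in df.columns if c in ("cas", "cas_number", "casrn")), None)
    df["cas_key"] = df[cas_col].map(normalize_cas) if cas_col else ""
    if "average_mass" in df.columns:
        df["average_mass"] = pd.to_numeric(df["average_mass"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# curated output tables (published Table D/E/F layout)

_BQE_COLUMNS = (
    ["chemical_id", "cas_number", "bqe", "n"]
    + list(STATISTIC_NAMES)
    + list(PROVENANCE_CATEGORIES)
    + [f"class_{s}" for s in STATISTIC_NAMES]
)


def write_bqe_table(summaries: list[AggregateSummary], path) -> None:
    """Write curated per-chemical summaries as CSV in the published layout.

    One column per statistic and per solubility class, one collapsed
    provenance column per category.  The file round-trips exactly through
    :func:`read_bqe_table` and is byte-stable across runs.
    """
    rows = [s.to_row() for s in summaries]
    df = pd.DataFrame(rows, columns=_BQE_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_bqe_table(path) -> list[AggregateSummary]:
    """Read a curated summary table back into :class:`AggregateSummary` rows."""
    df = pd.read_csv(path, dtype={"chemical_id": str, "cas_number": str, "bqe": str})
    for cat in PROVENANCE_CATEGORIES:
        df[cat] = df[cat].fillna("")
    return [AggregateSummary.from_row(row) for _, row in df.iterrows()]
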