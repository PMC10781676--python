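"""Record-selection criteria per biological quality element (BQE).

The curation keeps, for each of the three BQEs (algae, crustaceans, fish),
only acute water-exposure effect records:

* water-based dosing only (``dosing_group = "water_concentration"``);
* exposure duration within 0–5 days (0–120 h, 0–7200 min) expressed in a
  recognized day, hour or minute unit code;
* aquatic habitat, matching species group, and — for crustaceans and fish —
  a configurable whitelist of standard test species (algae keep all
  species);
* an acute effect code (MOR, GRO, POP, REP, MPH, DEV; crustaceans also
  ITX);
* an endpoint from the acute effect/lethal-level families (ECx, EDx, ELx,
  ICx, LCx, LDx, LLx, LTx with x in 1–99, plus LOEC and LETC);
* a CAS present in the study's chemical list and a numeric concentration.

Rejections are attributed to the *first* failing criterion in a fixed
order so the filter report is stable; the retained set itself is
order-independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "ENDPOINT_FAMILIES",
    "SPECIAL_ENDPOINTS",
    "EFFECTS_BY_BQE",
    "REJECTION_ORDER",
    "FilterCriteria",
    "FilteredSet",
    "match_endpoint",
    "match_duration",
    "match_effect",
    "select_species",
    "apply_filters",
    "default_criteria",
    "load_standard_species",
]

ENDPOINT_FAMILIES = ("EC", "ED", "EL", "IC", "LC", "LD", "LL", "LT")
SPECIAL_ENDPOINTS = ("LOEC", "LETC")

EFFECTS_BY_BQE = {
    "Algae": ("MOR", "GRO", "POP", "REP", "MPH", "DEV"),
    "Crustacean": ("MOR", "GRO", "POP", "REP", "MPH", "DEV", "ITX"),
    "Fish": ("MOR", "GRO", "POP", "REP", "MPH", "DEV"),
}

#: fixed attribution order for the rejection report
REJECTION_ORDER = (
    "chemical", "dosing", "species", "effect", "endpoint", "duration",
    "concentration",
)

_ENDPOINT_RE = re.compile(
    r"^(?:%s)$|^(?:%s)([1-9][0-9]?)$"
    % ("|".join(SPECIAL_ENDPOINTS), "|".join(ENDPOINT_FAMILIES))
)


@dataclass(frozen=True)
class FilterCriteria:
    """Full parameterization of the per-BQE selection rules.

    Duration maxima default to the mutually consistent 5 d = 120 h =
    7200 min acute window; quantile ``p`` is the percentile reported as
    the robust low-effect statistic.
    """

    ecotoxgroup: str = "Algae"
    dosing_group: str = "water_concentration"
    day_units: tuple[str, ...] = ("d", "dph", "dpf")
    hour_units: tuple[str, ...] = ("h", "ht", "hph", "hpf", "hv")
    minute_units: tuple[str, ...] = ("mi",)
    min_d: float = 0.0
    max_d: float = 5.0
    min_h: float = 0.0
    max_h: float = 120.0
    min_m: float = 0.0
    max_m: float = 7200.0
    habitat: str = "Water"
    species_selection: str = "all"  # "all" | "standard_test_species"
    standard_species: tuple[str, ...] = ()
    effects: tuple[str, ...] = EFFECTS_BY_BQE["Algae"]
    endpoint_families: tuple[str, ...] = ENDPOINT_FAMILIES
    special_endpoints: tuple[str, ...] = SPECIAL_ENDPOINTS
    quantile: float = 0.05

    def __post_init__(self):
        if not 0 < self.quantile < 1:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.species_selection not in ("all", "standard_test_species"):
            raise ValueError(
                f"species_selection must be 'all' or 'standard_test_species', "
                f"got {self.species_selection!r}"
            )


@dataclass
class FilteredSet:
    """Result of applying the selection rules to a joined-record table."""

    records: pd.DataFrame
    rejections: dict[str, int]
    criteria: FilterCriteria

    @property
    def n_retained(self) -> int:
        return len(self.records)

    @property
    def n_input(self) -> int:
        return self.n_retained + sum(self.rejections.values())


def _strip_modifiers(code: str) -> str:
    return code.strip().rstrip("*/").strip().upper()


def match_endpoint(code: str, c: FilterCriteria | None = None) -> bool:
    """True iff the endpoint code belongs to an acute effect/lethal family.

    Trailing ``*`` and ``/`` modifiers are stripped first; the remainder
    must be LOEC, LETC, or a family code (EC, ED, EL, IC, LC, LD, LL, LT)
    followed by an integer 1–99.  Total function: anything else is False.
    """
    if not code or not str(code).strip():
        return False
    stripped = _strip_modifiers(str(code))
    if c is not None and (
        c.endpoint_families != ENDPOINT_FAMILIES
        or c.special_endpoints != SPECIAL_ENDPOINTS
    ):
        if stripped in {s.upper() for s in c.special_endpoints}:
            return True
        m = re.match(r"^([A-Z]+)([1-9][0-9]?)$", stripped)
        return bool(m) and m.group(1) in {f.upper() for f in c.endpoint_families}
    return bool(_ENDPOINT_RE.match(stripped))


def match_duration(value, unit, c: FilterCriteria) -> bool:
    """True iff duration value falls in the closed window for its unit class.

    Unit codes select the day, hour or minute window; a missing value or a
    unit outside all three code sets fails.
    """
    if value is None or pd.isna(value):
        return False
    u = str(unit).strip().lower() if unit is not None else ""
    v = float(value)
    if u in {x.lower() for x in c.day_units}:
        return c.min_d <= v <= c.max_d
    if u in {x.lower() for x in c.hour_units}:
        return c.min_h <= v <= c.max_h
    if u in {x.lower() for x in c.minute_units}:
        return c.min_m <= v <= c.max_m
    return False


def match_effect(code, c: FilterCriteria) -> bool:
    """True iff the (modifier-stripped) effect code is in the BQE's set."""
    if code is None or not str(code).strip():
        return False
    return _strip_modifiers(str(code)) in {e.upper() for e in c.effects}


def _species_mask(records: pd.DataFrame, c: FilterCriteria) -> pd.Series:
    group_ok = records["ecotox_group"].str.strip().str.lower() == c.ecotoxgroup.lower()
    habitat_ok = records["habitat"].str.strip().str.lower() == c.habitat.lower()
    mask = group_ok & habitat_ok
    if c.species_selection == "standard_test_species":
        if not c.standard_species:
            raise ValueError(
                "standard_test_species selection requires a non-empty whitelist"
            )
        whitelist = {s.strip().lower() for s in c.standard_species}
        mask &= records["species_name"].str.strip().str.lower().isin(whitelist)
    return mask


def select_species(records: pd.DataFrame, c: FilterCriteria) -> pd.DataFrame:
    """Keep records matching species group, aquatic habitat and — in
    standard-species mode — the whitelist."""
    return records[_species_mask(records, c)]


def apply_filters(
    records: pd.DataFrame,
    chemicals: pd.DataFrame | set | None,
    c: FilterCriteria,
) -> FilteredSet:
    """Apply every selection rule; retain records passing all of them.

    ``chemicals`` is the study's chemical list (DataFrame with a
    ``cas_key`` column, or a plain set of digits-only CAS keys); ``None``
    disables the chemical-list criterion.  Each rejected record is counted
    against the first criterion it fails, in :data:`REJECTION_ORDER`.
    """
    if chemicals is None:
        cas_keys = None
    elif isinstance(chemicals, pd.DataFrame):
        cas_keys = set(chemicals["cas_key"]) - {""}
    else:
        cas_keys = set(chemicals) - {""}

    masks = {
        "chemical": records["cas_number"].isin(cas_keys)
        if cas_keys is not None
        else pd.Series(True, index=records.index),
        "dosing": records["dosing_group"].str.strip().str.lower()
        == c.dosing_group.lower(),
        "species": _species_mask(records, c),
        "effect": records["effect"].map(lambda x: match_effect(x, c)),
        "endpoint": records["endpoint"].map(lambda x: match_endpoint(x, c)),
        "duration": records.apply(
            lambda r: match_duration(r["duration_value"], r["duration_unit"], c),
            axis=1,
        )
        if len(records)
        else pd.Series(dtype=bool),
        "concentration": records["conc_value"].notna()
        & (pd.to_numeric(records["conc_value"], errors="coerce") > 0),
    }

    rejections = {k: 0 for k in REJECTION_ORDER}
    surviving = pd.Series(True, index=records.index)
    for criterion in REJECTION_ORDER:
        failed_here = surviving & ~masks[criterion]
        rejections[criterion] = int(failed_here.sum())
        surviving &= masks[criterion]
    return FilteredSet(
        records=records[surviving].reset_index(drop=True),
        rejections=rejections,
        criteria=c,
    )


def load_standard_species(path=None) -> tuple[str, ...]:
    """Load the standard-test-species whitelist (one Latin name per line,
    ``#`` comments allowed).  Defaults to the packaged OECD-seeded list."""
    if path is None:
        text = (
            resources.files("ecotoxkit.data")
            .joinpath("standard_test_species.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return tuple(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


def default_criteria(bqe: str, config_path=None) -> FilterCriteria:
    """The shipped selection rules for one BQE.

    Reads the packaged ``default_criteria.yaml`` (or ``config_path``) and
    fills the standard-species whitelist for crustaceans and fish.
    """
    if config_path is None:
        text = (
            resources.files("ecotoxkit.data")
            .joinpath("default_criteria.yaml")
            .read_text()
        )
    else:
        with open(config_path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    if bqe not in cfg:
        raise KeyError(f"no criteria for BQE {bqe!r}; have {sorted(cfg)}")
    block = dict(cfg[bqe])
    for key in (
        "day_units", "hour_units", "minute_units", "effects",
        "endpoint_families", "special_endpoints", "standard_species",
    ):
        if key in block:
            block[key] = tuple(block[key])
    crit = FilterCriteria(ecotoxgroup=bqe, **block)
    if crit.species_selection == "standard_test_species" and not crit.standard_species:
        crit = replace(crit, standard_species=load_standard_species())
    return crit
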