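"""Parsing, validation and summary statistics of the annotation catalog.

Each compound in the catalog carries hand-curated annotations: whether it
is a parent compound, a transformation product (TP) or both; its use
group(s) out of eight categories; and its broad and specific mode-of-action
(MoA) assignments.  Multi-valued fields use a small separator grammar —
``","`` between top-level entries, ``" + "`` between application sectors,
``"/"`` between uses within one sector.

Summary counting follows the catalog's reporting conventions: "parent +
TP" compounds count as parents; the "Biocide" and "Drug of abuse" use
groups merge into "Pesticide/Biocide" and "Pharmaceutical/Drug of abuse";
compounds in more than one merged use group land in a single "Multiple
use" bucket; compounds with more than one broad MoA are excluded from the
single-category MoA table and counted once as multi-MoA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "USE_GROUPS",
    "USE_GROUP_MERGES",
    "CompoundAnnotation",
    "ControlledVocabulary",
    "split_multivalue",
    "read_annotations",
    "count_by_use_group",
    "count_by_moa",
    "validate_annotations",
]

USE_GROUPS = (
    "Industrial Chemical", "Pesticide", "Biocide", "Pharmaceutical",
    "Drug of abuse", "Natural", "Food additive", "Metal",
)

#: analysis-time category merges
USE_GROUP_MERGES = {
    "pesticide": "Pesticide/Biocide",
    "biocide": "Pesticide/Biocide",
    "pharmaceutical": "Pharmaceutical/Drug of abuse",
    "drug of abuse": "Pharmaceutical/Drug of abuse",
    "industrial chemical": "Industrial Chemical",
    "natural": "Natural",
    "food additive": "Food additive",
    "metal": "Metal",
}

MULTIPLE_USE = "Multiple use"
UNKNOWN = "unknown"

_SEPARATORS = {"top": ",", "sector": "+", "within-sector": "/"}


def split_multivalue(text, level: str = "top") -> list[str]:
    """Split a multi-valued annotation field into trimmed tokens.

    ``level`` selects the separator: ``top`` (","), ``sector`` ("+"),
    ``within-sector`` ("/").  Empty tokens are dropped, order preserved.
    """
    if level not in _SEPARATORS:
        raise ValueError(f"level must be one of {sorted(_SEPARATORS)}, got {level!r}")
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return []
    tokens = [t.strip() for t in str(text).split(_SEPARATORS[level])]
    return [t for t in tokens if t]


def _norm(s: str) -> str:
    return " ".join(str(s).split()).lower()


@dataclass
class CompoundAnnotation:
    """One row of the annotation catalog (use groups, parent/TP, MoAs)."""

    chemical_id: str
    name: str = ""
    parent_or_tp: str = "unknown"  # parent | TP | parent + TP | unknown
    tp_of: list[str] = field(default_factory=list)
    use_group: list[str] = field(default_factory=list)
    use_group_details: str = ""
    additional_use_info: str = ""
    moa_broad: list[str] = field(default_factory=list)
    moa_specific: list[str] = field(default_factory=list)
    molecular_target: list[str] = field(default_factory=list)
    further_moa_info: str = ""
    nontarget_taxa: str = ""
    nontarget_taxa_alert: str = ""
    source: str = ""

    @property
    def is_parent(self) -> bool:
        """Parents and 'parent + TP' compounds count as parent substances."""
        return _norm(self.parent_or_tp) in ("parent", "parent + tp")

    @property
    def is_pure_tp(self) -> bool:
        return _norm(self.parent_or_tp) == "tp"


@dataclass(frozen=True)
class ControlledVocabulary:
    """Canonical category lists; matching is case/whitespace-insensitive."""

    moa_broad: tuple[str, ...]
    use_groups: tuple[str, ...] = USE_GROUPS

    @classmethod
    def default(cls, moa_path=None) -> "ControlledVocabulary":
        if moa_path is None:
            text = (
                resources.files("ecotoxkit.data")
                .joinpath("moa_broad_categories.txt")
                .read_text()
            )
        else:
            with open(moa_path) as fh:
                text = fh.read()
        cats = tuple(
            line.strip()
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        )
        if len(set(_norm(c) for c in cats)) != len(cats):
            raise ValueError("duplicate entries in broad-MoA vocabulary")
        return cls(moa_broad=cats)

    def canonical_use_group(self, token: str) -> str | None:
        lut = {_norm(g): g for g in self.use_groups}
        return lut.get(_norm(token))

    def canonical_moa(self, token: str) -> str | None:
        lut = {_norm(c): c for c in self.moa_broad}
        return lut.get(_norm(token))


def _parse_parent_or_tp(raw: str) -> str:
    n = _norm(raw).replace(" ", "")
    if n in ("parent",):
        return "parent"
    if n in ("tp",):
        return "TP"
    if n in ("parent+tp", "tp+parent"):
        return "parent + TP"
    return "unknown"


def read_annotations(path, sep: str = ",") -> list[CompoundAnnotation]:
    """Read an annotation catalog CSV into annotation records.

    Column names follow the published column dictionary (``parent_or_TP``,
    ``TP_of``, ``use_group``, ``MoA_broad``, ``MoA_specific``,
    ``molecular_target``, ...); matching is case-insensitive.  Duplicate
    internal IDs raise.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    id_col = "id" if "id" in df.columns else df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate internal ID {dup!r} in annotation table")

    def col(row, name):
        return row.get(name, "")

    out = []
    for _, row in df.iterrows():
        out.append(
            CompoundAnnotation(
                chemical_id=str(row[id_col]),
                name=col(row, "name"),
                parent_or_tp=_parse_parent_or_tp(col(row, "parent_or_tp")),
                tp_of=split_multivalue(col(row, "tp_of")),
                use_group=split_multivalue(col(row, "use_group")),
                use_group_details=col(row, "use_group_details"),
                additional_use_info=col(row, "additional_use_info"),
                moa_broad=split_multivalue(col(row, "moa_broad")),
                moa_specific=split_multivalue(col(row, "moa_specific")),
                molecular_target=split_multivalue(col(row, "molecular_target")),
                further_moa_info=col(row, "further_moa_info"),
                nontarget_taxa=col(row, "nontarget_taxa"),
                nontarget_taxa_alert=col(row, "nontarget_taxa_alert"),
                source=col(row, "source"),
            )
        )
    return out


def count_by_use_group(
    annotations: list[CompoundAnnotation],
    vocab: ControlledVocabulary | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-use-group compound counts, split into parent vs TP columns.

    Applies the analysis merges (Biocide → Pesticide/Biocide, Drug of
    abuse → Pharmaceutical/Drug of abuse); a compound whose merged
    categories still number more than one is counted once under
    "Multiple use"; empty use groups count as "unknown".  "parent + TP"
    compounds tally as parents.  Tokens outside the vocabulary are
    returned in the unknown-token report (second element), never dropped
    silently.
    """
    vocab = vocab or ControlledVocabulary.default()
    counts: dict[str, Counter] = {}
    unknown_tokens: list[str] = []
    for ann in annotations:
        merged: list[str] = []
        for token in ann.use_group:
            canon = vocab.canonical_use_group(token)
            if canon is None:
                unknown_tokens.append(token)
                continue
            m = USE_GROUP_MERGES[_norm(canon)]
            if m not in merged:
                merged.append(m)
        if not merged:
            category = UNKNOWN
        elif len(merged) > 1:
            category = MULTIPLE_USE
        else:
            category = merged[0]
        kind = "TP" if ann.is_pure_tp else "parent"
        counts.setdefault(category, Counter())[kind] += 1
    table = (
        pd.DataFrame(
            [
                {"use_group": cat, "parent": c.get("parent", 0), "TP": c.get("TP", 0)}
                for cat, c in counts.items()
            ]
        )
        .sort_values("use_group")
        .reset_index(drop=True)
    )
    return table, unknown_tokens


def count_by_moa(
    annotations: list[CompoundAnnotation],
    level: str = "broad",
    vocab: ControlledVocabulary | None = None,
) -> dict[str, object]:
    """MoA category counts under the catalog's figure semantics.

    Returns a dict with:

    * ``single`` — per-category counts over compounds with exactly one
      category at the requested level (multi-MoA compounds excluded, as in
      the published figures);
    * ``total`` — per-category assignment counts including multi-MoA
      compounds (one tally per assignment);
    * ``n_single``, ``n_multi``, ``n_unknown`` — compounds with one, more
      than one, and zero assignments.  These three always sum to the
      number of annotations.
    """
    if level not in ("broad", "specific"):
        raise ValueError(f"level must be 'broad' or 'specific', got {level!r}")
    single: Counter = Counter()
    total: Counter = Counter()
    n_single = n_multi = n_unknown = 0
    for ann in annotations:
        cats = ann.moa_broad if level == "broad" else ann.moa_specific
        if not cats:
            n_unknown += 1
            continue
        for cat in cats:
            total[cat] += 1
        if len(cats) == 1:
            n_single += 1
            single[cats[0]] += 1
        else:
            n_multi += 1
    return {
        "single": pd.Series(single).sort_index(),
        "total": pd.Series(total).sort_index(),
        "n_single": n_single,
        "n_multi": n_multi,
        "n_unknown": n_unknown,
    }


def validate_annotations(
    annotations: list[CompoundAnnotation],
    vocab: ControlledVocabulary | None = None,
) -> pd.DataFrame:
    """Report-only quality gate over the annotation catalog.

    Findings: use-group or broad-MoA tokens outside the controlled
    vocabulary, TP entries with no parent reference, and duplicate IDs.
    Returns a DataFrame with columns chemical_id, kind, detail (empty when
    the catalog is clean).
    """
    vocab = vocab or ControlledVocabulary.default()
    findings: list[dict] = []
    seen: set[str] = set()
    for ann in annotations:
        if ann.chemical_id in seen:
            findings.append(
                {"chemical_id": ann.chemical_id, "kind": "duplicate_id", "detail": ""}
            )
        seen.add(ann.chemical_id)
        for token in ann.use_group:
            if vocab.canonical_use_group(token) is None:
                findings.append(
                    {"chemical_id": ann.chemical_id, "kind": "unknown_use_group",
                     "detail": token}
                )
        for token in ann.moa_broad:
            if vocab.canonical_moa(token) is None:
                findings.append(
                    {"chemical_id": ann.chemical_id, "kind": "unknown_moa_broad",
                     "detail": token}
                )
        if _norm(ann.parent_or_tp) in ("tp", "parent + tp") and not ann.tp_of:
            findings.append(
                {"chemical_id": ann.chemical_id, "kind": "tp_without_parent",
                 "detail": ""}
            )
    return pd.DataFrame(findings, columns=["chemical_id", "kind", "detail"])
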