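"""End-to-end orchestration of the curation stages.

One :func:`run_pipeline` call reproduces the published workflow: read the
release archive, join the five tables, filter per BQE, standardize
concentrations to mg/L, aggregate per chemical, classify against
solubility, post-process QSAR predictions, summarize the annotation
catalog, and write one curated table per BQE plus a run report.  Every
intermediate is a plain delimited file so each stage can be audited or
re-run on its own through the CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import criteria as crit_mod
from . import moa as moa_mod
from . import qsar as qsar_mod
from .aggregate import STATISTIC_NAMES, datapoint_spread, summarize_all
from .io import (
    join_records,
    read_chemical_list,
    read_ecotox_archive,
    write_bqe_table,
)
from .qsar import DEFAULT_FISH_EXPONENT, correct_prediction, parse_qsar_outputs
from .solubility import (
    DEFAULT_BOUNDARY_EXPONENTS,
    classify_summary,
    read_solubility_output,
)
from .units import read_mol_weight_table, standardize_concentrations

__all__ = ["PipelineConfig", "run_pipeline"]

BQES = ("Algae", "Crustacean", "Fish")
_BQE_FILES = {"Algae": "table_D_algae.csv", "Crustacean": "table_E_crustacean.csv",
              "Fish": "table_F_fish.csv"}


@dataclass
class PipelineConfig:
    """Input paths and tunables for one curation run."""

    archive: str
    chemical_list: str
    mol_weight: str
    outdir: str
    solubility: str | None = None
    qsar_outputs: dict = field(default_factory=dict)  # model name -> path
    annotations: str | None = None
    criteria_config: str | None = None
    bqes: tuple[str, ...] = BQES
    quantile: float | None = None  # overrides the per-BQE criteria value
    fish_exponent: float = DEFAULT_FISH_EXPONENT
    boundaries: tuple[float, float] = DEFAULT_BOUNDARY_EXPONENTS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "boundaries" in raw:
            raw["boundaries"] = tuple(raw["boundaries"])
        if "bqes" in raw:
            raw["bqes"] = tuple(raw["bqes"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("archive", "chemical_list", "mol_weight"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        for model, p in self.qsar_outputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"QSAR output for {model} not found: {p}")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write per-BQE tables and ``run_report.json``.

    Returns the run report: record counts in and out of each stage, join
    orphans, unsupported-unit losses, the solubility-class histogram per
    BQE, and annotation validation findings.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"inputs": {
        "archive": _checksum(config.archive),
        "chemical_list": _checksum(config.chemical_list),
    }}

    raw = read_ecotox_archive(config.archive)
    records, join_report = join_records(raw)
    report["join"] = {"n_results": join_report.n_results,
                      "n_joined": join_report.n_joined,
                      "orphans": join_report.orphans}

    chemicals = read_chemical_list(config.chemical_list)
    mw_by_cas = read_mol_weight_table(config.mol_weight)
    id_by_cas = dict(zip(chemicals["cas_key"], chemicals[
        "id" if "id" in chemicals.columns else chemicals.columns[0]]))
    mw_by_id = {}
    if "average_mass" in chemicals.columns:
        idc = "id" if "id" in chemicals.columns else chemicals.columns[0]
        mw_by_id = {
            str(r[idc]): float(r["average_mass"])
            for _, r in chemicals.iterrows()
            if pd.notna(r["average_mass"])
        }

    profiles = {}
    if config.solubility:
        profiles = read_solubility_output(config.solubility, mw_by_id=mw_by_id)

    report["bqe"] = {}
    summaries_by_bqe = {}
    for bqe in config.bqes:
        criteria = crit_mod.default_criteria(bqe, config.criteria_config)
        filtered = crit_mod.apply_filters(records, chemicals, criteria)
        standardized, unit_report = standardize_concentrations(
            filtered.records, mw_by_cas)
        usable = standardized[
            standardized["conc_mg_per_L"].notna()
            & (standardized["conc_mg_per_L"] > 0)
        ].reset_index(drop=True)
        p = config.quantile if config.quantile is not None else criteria.quantile
        summaries = summarize_all(usable, p=p, bqe=bqe, chemical_ids=id_by_cas)
        summaries = [
            classify_summary(s, profiles.get(s.chemical_id), config.boundaries)
            for s in summaries
        ]
        summaries_by_bqe[bqe] = summaries
        write_bqe_table(summaries, outdir / _BQE_FILES[bqe])

        hist: dict[str, int] = {}
        for s in summaries:
            c = s.classes.get("geomean")
            key = "missing" if c is None or np.isnan(c) else str(int(c))
            hist[key] = hist.get(key, 0) + 1
        report["bqe"][bqe] = {
            "n_retained": filtered.n_retained,
            "rejections": filtered.rejections,
            "n_unit_lost": unit_report.n_lost,
            "unsupported_units": dict(unit_report.unsupported),
            "n_chemicals": len(summaries),
            "datapoints": datapoint_spread(summaries),
            "class_histogram_geomean": hist,
        }

    if config.qsar_outputs:
        preds = parse_qsar_outputs(config.qsar_outputs)
        rows = []
        for pred in preds:
            correct_prediction(pred, mw=mw_by_id.get(pred.chemical_id),
                               fish_exponent=config.fish_exponent)
            rows.append({
                "chemical_id": pred.chemical_id, "model": pred.model,
                "ec50_mmol_per_L": pred.ec50_mmol, "ec50_mg_per_L": pred.ec50_mg,
                "ad_assessment": pred.ad_assessment,
            })
        pd.DataFrame(rows).to_csv(outdir / "qsar_predictions.csv", index=False,
                                  lineterminator="\n")
        report["qsar"] = {"n_predictions": len(rows)}

    if config.annotations:
        annotations = moa_mod.read_annotations(config.annotations)
        vocab = moa_mod.ControlledVocabulary.default()
        findings = moa_mod.validate_annotations(annotations, vocab)
        findings.to_csv(outdir / "annotation_validation.csv", index=False,
                        lineterminator="\n")
        use_table, unknown = moa_mod.count_by_use_group(annotations, vocab)
        use_table.to_csv(outdir / "use_group_counts.csv", index=False,
                         lineterminator="\n")
        moa_counts = moa_mod.count_by_moa(annotations, "broad", vocab)
        moa_counts["single"].rename("n").to_csv(
            outdir / "moa_broad_counts.csv", index_label="moa_broad",
            lineterminator="\n")
        report["annotations"] = {
            "n": len(annotations),
            "n_findings": len(findings),
            "unknown_use_tokens": unknown,
            "moa": {k: int(moa_counts[k]) for k in
                    ("n_single", "n_multi", "n_unknown")},
        }

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
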