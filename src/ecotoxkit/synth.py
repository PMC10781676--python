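"""Seeded miniature fixtures for every input the curation pipeline consumes.

The generator writes a pipe-delimited release archive (tests, results,
species, chemicals, references), a chemical list, a molecular-weight
lookup, solubility- and effect-predictor exports, and an annotation
catalog — all at toy scale, with *planted* ground truth.  Alongside each
fixture it emits a JSON manifest of expected outcomes (survivor counts,
per-criterion rejection attribution, per-chemical statistics rounded to
four significant digits, solubility classes, expected corrected EC50s,
annotation count tables).

Everything in the manifest is computed here with independent primitives
(``numpy.quantile``, ``scipy.stats.gmean``, ``"%.4g"`` formatting, inline
class comparisons) so the test suite never checks the pipeline against
itself.  One integer seed determines every output byte; fixtures target
code paths, not the statistical texture of a real release.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FixtureSpec",
    "generate_ecotox_fixture",
    "generate_annotation_fixture",
    "generate_qsar_fixture",
]

BQES = ("Algae", "Crustacean", "Fish")

_GOOD_SPECIES = {
    "Algae": ("5001", "Raphidocelis subcapitata"),
    "Crustacean": ("5003", "Daphnia magna"),
    "Fish": ("5005", "Danio rerio"),
}
# fails the species criterion: wrong habitat for algae ("all" mode has no
# whitelist), non-whitelisted species for the standard-species BQEs
_BAD_SPECIES = {
    "Algae": ("5002", "Chlorella terricola", "Soil"),
    "Crustacean": ("5004", "Ceriodaphnia exotica", "Water"),
    "Fish": ("5006", "Barbus nonstandardus", "Water"),
}

_EFFECTS = {
    "Algae": ("POP", "GRO", "MPH"),
    "Crustacean": ("ITX", "MOR", "REP"),
    "Fish": ("MOR", "GRO", "DEV"),
}
_ENDPOINTS = ("LC50", "EC50", "IC25", "LOEC", "EL20", "LETC", "LD10", "EC50*", "LC50/")
_DURATIONS = ((96, "h"), (48, "h"), (5, "d"), (24, "h"), (7200, "mi"), (2, "d"), (120, "h"))
# (unit label, factor to mg/L, needs molecular weight)
_UNITS = (("mg/L", 1.0, False), ("ug/L", 1e-3, False), ("ppm", 1.0, False),
          ("g/L", 1e3, False), ("mmol/L", None, True))

ALL_CRITERIA = ("chemical", "dosing", "species", "effect", "endpoint",
                "duration", "concentration")

#: Sw/geomean multipliers planting solubility classes 3, 2, 1, 0
#: (ratios kept clear of the 10^0.5 and 10^1.0 class boundaries)
_CLASS_MULTIPLIERS = (10.0, 0.5, 0.2, 0.009)


@dataclass
class FixtureSpec:
    """Declarative plan for one fixture set.

    ``n_chemicals`` chemicals per BQE each receive between
    ``n_records[0]`` and ``n_records[1]`` surviving records;
    ``big_chemical`` optionally forces one (BQE, count) to stress the
    provenance collapsing; every criterion in ``violations[bqe]`` gets one
    planted single-violation reject; ``n_orphans`` results rows carry a
    dangling test_id.
    """

    seed: int = 0
    n_chemicals: dict = field(
        default_factory=lambda: {"Algae": 5, "Crustacean": 3, "Fish": 3}
    )
    n_records: tuple[int, int] = (3, 8)
    big_chemical: tuple | None = None
    violations: dict = field(
        default_factory=lambda: {b: ALL_CRITERIA for b in BQES}
    )
    n_orphans: int = 1
    n_annotations: int = 12

    def validate(self) -> None:
        if self.n_records[0] < 1 or self.n_records[1] < self.n_records[0]:
            raise ValueError(f"invalid n_records range {self.n_records}")
        for bqe in self.n_chemicals:
            if bqe not in BQES:
                raise ValueError(f"unknown BQE {bqe!r}")
        for bqe, crits in self.violations.items():
            unknown = set(crits) - set(ALL_CRITERIA)
            if unknown:
                raise ValueError(f"unknown criteria {sorted(unknown)} for {bqe}")


def _signif4(x: float) -> float:
    return float(f"{float(x):.4g}")


def _ref_stats(values, p=0.05) -> dict:
    v = np.sort(np.asarray(values, dtype=float))
    return {
        "P5": _signif4(np.quantile(v, p, method="linear")),
        "mean": _signif4(v.mean()),
        "geomean": _signif4(sps.gmean(v)),
        "median": _signif4(np.median(v)),
        "min": _signif4(v.min()),
        "max": _signif4(v.max()),
    }


def _ref_class(ecx: float, sw: float | None) -> float | None:
    if sw is None:
        return None
    if ecx <= sw:
        return 3
    if ecx <= sw * 10.0 ** 0.5:
        return 2
    if ecx <= sw * 10.0:
        return 1
    return 0


def _write_pipe(df: pd.DataFrame, name: str) -> str:
    return df.to_csv(sep="|", index=False, lineterminator="\n")


class _Roster:
    """Chemical roster shared by all fixture files."""

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, listed: bool, mw: float) -> dict:
        i = len(self.rows) + 1
        row = {
            "id": f"M{i:04d}",
            "name": f"compound-{i:04d}",
            "cas": str(100000 + 7 * i),
            "mw": round(mw, 2),
            "listed": listed,
        }
        self.rows.append(row)
        return row


def generate_ecotox_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write the release archive plus companion inputs and the manifest.

    Emits ``ecotox_release.zip``, ``chemical_list.csv``,
    ``ecotoxgroup_mol_weight.csv``, ``solubility_predictions.csv`` and
    ``manifest.json`` under ``outdir``; returns the manifest dict.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    roster = _Roster()

    tests_rows: list[dict] = []
    results_rows: list[dict] = []
    test_id = 0
    ref_cycle = ("9001", "9002", "9003")

    def add_record(cas: str, species_number: str, endpoint: str, effect: str,
                   conc: str, unit: str, dur_val, dur_unit: str) -> None:
        nonlocal test_id
        test_id += 1
        tests_rows.append({
            "test_id": str(test_id),
            "species_number": species_number,
            "cas_number": cas,
            "reference_number": ref_cycle[test_id % len(ref_cycle)],
        })
        results_rows.append({
            "test_id": str(test_id),
            "endpoint": endpoint,
            "effect": effect,
            "measurement": effect[:3] + "T",
            "conc1_mean": conc,
            "conc1_unit": unit,
            "obs_duration_mean": str(dur_val),
            "obs_duration_unit": dur_unit,
        })

    manifest_bqe: dict[str, dict] = {}
    counts_by_bqe: dict[str, dict[str, int]] = {}

    for bqe in BQES:
        n_chem = spec.n_chemicals.get(bqe, 0)
        sp_num, sp_name = _GOOD_SPECIES[bqe]
        chem_manifest: dict[str, dict] = {}

        for ci in range(n_chem):
            mw = float(rng.uniform(80, 400))
            chem = roster.add(listed=True, mw=mw)
            n = int(rng.integers(spec.n_records[0], spec.n_records[1] + 1))
            if spec.big_chemical and spec.big_chemical[0] == bqe and ci == 0:
                n = int(spec.big_chemical[1])
            mg_values: list[float] = []
            for k in range(n):
                unit, factor, needs_mw = _UNITS[k % len(_UNITS)]
                raw = round(float(10 ** rng.uniform(-1, 2)), 3)
                mg = raw * chem["mw"] if needs_mw else raw * factor
                mg_values.append(mg)
                dur = _DURATIONS[k % len(_DURATIONS)]
                add_record(chem["cas"], sp_num,
                           _ENDPOINTS[k % len(_ENDPOINTS)],
                           _EFFECTS[bqe][k % len(_EFFECTS[bqe])],
                           str(raw), unit, dur[0], dur[1])
            stats = _ref_stats(mg_values)
            # plant one solubility class per chemical, cycling 3..0,
            # final chemical of each BQE left without a profile
            if ci == n_chem - 1 and n_chem > 1:
                sw = None
            else:
                sw = float(sps.gmean(mg_values)) * _CLASS_MULTIPLIERS[ci % 4]
            chem_manifest[chem["id"]] = {
                "cas": chem["cas"],
                "mw": chem["mw"],
                "n": n,
                "stats": stats,
                "raw_mg": mg_values,
                "sw_mg_per_L": sw,
                "classes": {s: _ref_class(stats[s], sw) for s in stats},
            }

        # planted single-violation rejects, built on an otherwise-valid template
        template = {
            "cas": roster.rows[-1]["cas"] if n_chem else None,
            "species": sp_num,
            "endpoint": "LC50",
            "effect": _EFFECTS[bqe][1 % len(_EFFECTS[bqe])],
            "conc": "4.2",
            "unit": "mg/L",
            "dur": (96, "h"),
        }
        violations = tuple(spec.violations.get(bqe, ())) if n_chem else ()
        for crit in violations:
            t = dict(template)
            if crit == "chemical":
                unlisted = roster.add(listed=False, mw=float(rng.uniform(80, 400)))
                t["cas"] = unlisted["cas"]
            elif crit == "dosing":
                t["unit"] = "mg/kg"
            elif crit == "species":
                t["species"] = _BAD_SPECIES[bqe][0]
            elif crit == "effect":
                t["effect"] = "BEH"
            elif crit == "endpoint":
                t["endpoint"] = "NOEC"
            elif crit == "duration":
                t["dur"] = (144, "h")
            elif crit == "concentration":
                t["conc"] = "NR"
            add_record(t["cas"], t["species"], t["endpoint"], t["effect"],
                       t["conc"], t["unit"], t["dur"][0], t["dur"][1])

        counts_by_bqe[bqe] = {
            "survivors": sum(c["n"] for c in chem_manifest.values()),
            "violations": dict.fromkeys(violations, 1),
        }
        manifest_bqe[bqe] = {"chemicals": chem_manifest}

    # orphan results rows (dangling test_id) — dropped at the join
    for _ in range(spec.n_orphans):
        results_rows.append({
            "test_id": "999999",
            "endpoint": "LC50", "effect": "MOR", "measurement": "MORT",
            "conc1_mean": "1.0", "conc1_unit": "mg/L",
            "obs_duration_mean": "96", "obs_duration_unit": "h",
        })

    # expected per-criterion rejection attribution for each BQE's filter run:
    # records of *other* BQEs fail in attribution order — their chemical and
    # dosing plants fail those criteria first, everything else trips the
    # species (ecotoxgroup) check
    n_joined = len(tests_rows)
    for bqe in BQES:
        rej = dict.fromkeys(ALL_CRITERIA, 0)
        for other, cnt in counts_by_bqe.items():
            if other == bqe:
                for crit in cnt["violations"]:
                    rej[crit] += 1
            else:
                for crit in cnt["violations"]:
                    if crit in ("chemical", "dosing"):
                        rej[crit] += 1
                    else:
                        rej["species"] += 1
                rej["species"] += cnt["survivors"]
        manifest_bqe[bqe]["n_survivors"] = counts_by_bqe[bqe]["survivors"]
        manifest_bqe[bqe]["rejections"] = rej
        ns = [c["n"] for c in manifest_bqe[bqe]["chemicals"].values()]
        manifest_bqe[bqe]["spread"] = {
            "total": int(sum(ns)),
            "geomean": float(sps.gmean(ns)) if ns else None,
            "geosd": float(np.exp(np.std(np.log(ns), ddof=1)))
            if len(ns) > 1 else None,
        }

    # ---- write the archive ------------------------------------------------
    species_rows = []
    for bqe in BQES:
        num, name = _GOOD_SPECIES[bqe]
        species_rows.append({"species_number": num, "latin_name": name,
                             "common_name": name.split()[0],
                             "ecotox_group": bqe, "habitat": "Water"})
        bnum, bname, bhab = _BAD_SPECIES[bqe]
        species_rows.append({"species_number": bnum, "latin_name": bname,
                             "common_name": bname.split()[0],
                             "ecotox_group": bqe, "habitat": bhab})
    chem_rows = [{"cas_number": r["cas"], "chemical_name": r["name"]}
                 for r in roster.rows]
    ref_rows = [{"reference_number": r, "title": f"study {r}",
                 "publication_year": "2001"} for r in ref_cycle]

    tables = {
        "tests": pd.DataFrame(tests_rows),
        "results": pd.DataFrame(results_rows),
        "species": pd.DataFrame(species_rows),
        "chemicals": pd.DataFrame(chem_rows),
        "references": pd.DataFrame(ref_rows),
    }
    archive = outdir / "ecotox_release.zip"
    with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, df in tables.items():
            info = zipfile.ZipInfo(f"{name}.txt", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, _write_pipe(df, name))

    # ---- companion inputs -------------------------------------------------
    listed = [r for r in roster.rows if r["listed"]]
    pd.DataFrame({
        "id": [r["id"] for r in listed],
        "name": [r["name"] for r in listed],
        "cas": [r["cas"] for r in listed],
        "pubchem_cid": [str(20000 + i) for i in range(len(listed))],
        "dtxsid": [f"DTXSID{70000 + i}" for i in range(len(listed))],
        "inchikey": [f"SYNTHKEY{i:06d}-UHFFFAOYSA-N" for i in range(len(listed))],
        "smiles": ["C" * (1 + i % 5) for i in range(len(listed))],
        "qsar_ready_smiles": ["C" * (1 + i % 5) for i in range(len(listed))],
        "average_mass": [r["mw"] for r in listed],
    }).to_csv(outdir / "chemical_list.csv", index=False, lineterminator="\n")

    pd.DataFrame({
        "cas_number": [r["cas"] for r in roster.rows],
        "average_mass": [r["mw"] for r in roster.rows],
    }).to_csv(outdir / "ecotoxgroup_mol_weight.csv", index=False,
              lineterminator="\n")

    sol_rows = []
    id_by_cas = {r["cas"]: r["id"] for r in roster.rows}
    mw_by_id = {r["id"]: r["mw"] for r in roster.rows}
    for bqe in BQES:
        for cid, cm in manifest_bqe[bqe]["chemicals"].items():
            if cm["sw_mg_per_L"] is not None:
                log_sw = math.log10(cm["sw_mg_per_L"] / (cm["mw"] * 1000.0))
                # recompute the planted Sw through the same closed formula the
                # pipeline uses so boundary comparisons are bit-identical
                cm["sw_mg_per_L"] = 10.0 ** log_sw * cm["mw"] * 1000.0
                cm["classes"] = {s: _ref_class(cm["stats"][s], cm["sw_mg_per_L"])
                                 for s in cm["stats"]}
                sol_rows.append({"MoleculeID": cid,
                                 "LogWS_pred": repr(log_sw),
                                 "AD_WS": "inside"})
    pd.DataFrame(sol_rows, columns=["MoleculeID", "LogWS_pred", "AD_WS"]).to_csv(
        outdir / "solubility_predictions.csv", index=False, lineterminator="\n")

    manifest = {
        "seed": spec.seed,
        "bqe": manifest_bqe,
        "join": {
            "n_results": len(results_rows),
            "n_joined": n_joined,
            "orphans": {"test_id": spec.n_orphans, "species_number": 0,
                        "cas_number": 0, "reference_number": 0},
        },
        "id_by_cas": id_by_cas,
        "mw_by_id": mw_by_id,
        "files": {
            "archive": archive.name,
            "chemical_list": "chemical_list.csv",
            "mol_weight": "ecotoxgroup_mol_weight.csv",
            "solubility": "solubility_predictions.csv",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------


def generate_annotation_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write an annotation-catalog CSV plus its expected count tables."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)

    statuses = ("parent", "TP", "parent + TP", "unknown")
    groups = ("Industrial Chemical", "Pesticide", "Biocide", "Pharmaceutical",
              "Drug of abuse", "Natural", "Food additive", "Metal")
    moas = ("Neuroactive", "Endocrine", "Cardiovascular system",
            "Photosynthesis inhibition", "Nucleic acid damage")
    merge = {"Pesticide": "Pesticide/Biocide", "Biocide": "Pesticide/Biocide",
             "Pharmaceutical": "Pharmaceutical/Drug of abuse",
             "Drug of abuse": "Pharmaceutical/Drug of abuse"}

    rows = []
    for i in range(spec.n_annotations):
        status = statuses[i % len(statuses)]
        n_groups = 1 + (i % 3 == 2)  # every third compound gets two groups
        picked = list(rng.choice(groups, size=n_groups, replace=False))
        n_moa = int(rng.integers(0, 3))
        picked_moa = list(rng.choice(moas, size=n_moa, replace=False))
        rows.append({
            "ID": f"A{i + 1:04d}",
            "name": f"annotated-{i + 1:04d}",
            "parent_or_TP": status,
            "TP_of": f"A{(i % 3) + 1:04d}" if status in ("TP", "parent + TP") else "",
            "use_group": ", ".join(picked),
            "use_group_details": "I/A + PC" if n_groups == 2 else "H",
            "additional_use_info": "",
            "MoA_broad": ", ".join(picked_moa),
            "MoA_specific": "AChE inhibition" if "Neuroactive" in picked_moa else "",
            "molecular_target": "AChE" if "Neuroactive" in picked_moa else "",
            "further_MoA_info": "",
            "nontarget_taxa": "",
            "nontarget_taxa_alert": "",
            "source": "synthetic",
        })
    path = outdir / "annotations.csv"
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")

    # expected counts, tallied independently
    use_counts: dict[str, dict[str, int]] = {}
    moa_single: dict[str, int] = {}
    moa_total: dict[str, int] = {}
    n_single = n_multi = n_unknown = 0
    for r in rows:
        merged: list[str] = []
        for tok in [t.strip() for t in r["use_group"].split(",") if t.strip()]:
            m = merge.get(tok, tok)
            if m not in merged:
                merged.append(m)
        cat = ("unknown" if not merged
               else "Multiple use" if len(merged) > 1 else merged[0])
        kind = "TP" if r["parent_or_TP"] == "TP" else "parent"
        use_counts.setdefault(cat, {"parent": 0, "TP": 0})[kind] += 1
        mo = [t.strip() for t in r["MoA_broad"].split(",") if t.strip()]
        for m in mo:
            moa_total[m] = moa_total.get(m, 0) + 1
        if not mo:
            n_unknown += 1
        elif len(mo) == 1:
            n_single += 1
            moa_single[mo[0]] = moa_single.get(mo[0], 0) + 1
        else:
            n_multi += 1

    manifest = {
        "seed": spec.seed,
        "file": path.name,
        "n": len(rows),
        "use_group_counts": use_counts,
        "moa_broad": {
            "single": moa_single,
            "total": moa_total,
            "n_single": n_single,
            "n_multi": n_multi,
            "n_unknown": n_unknown,
        },
    }
    (outdir / "annotations_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_qsar_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write VEGA-style model exports plus expected corrected EC50 values.

    One compound per fixture receives an a-dimensional value below the
    box-cox domain (base ≤ 0) and expects a missing corrected value.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 2)

    n = max(3, spec.n_annotations // 3)
    ids = [f"Q{i + 1:04d}" for i in range(n)]
    mws = [round(float(rng.uniform(80, 400)), 2) for _ in ids]

    a_algae = [round(float(rng.uniform(-5, 5)), 4) for _ in ids]
    a_fish = [round(float(rng.uniform(-5, 5)), 4) for _ in ids]
    neglog = [round(float(rng.uniform(-2, 4)), 4) for _ in ids]
    a_algae[-1] = -20.0  # 1 + 0.07·(−20) < 0: out of the box-cox domain

    expected = {}
    for cid, mw, aa, af, nl in zip(ids, mws, a_algae, a_fish, neglog):
        base_a = aa * 0.07 + 1.0
        ec_a = base_a ** (1.0 / 0.07) if base_a > 0 else None
        ec_f = (af * 0.11 + 1.0) ** (1.0 / 0.07) if af * 0.11 + 1.0 > 0 else None
        ec_d = 10.0 ** (-nl)
        expected[cid] = {
            "mw": mw,
            "algae_mmol": ec_a,
            "algae_mg": ec_a * mw if ec_a is not None else None,
            "fish_mmol": ec_f,
            "fish_mg": ec_f * mw if ec_f is not None else None,
            "daphnia_mmol": ec_d,
            "daphnia_mg": ec_d * mw,
        }

    files = {}
    for model, col in (("algae_EC50", a_algae), ("fish_EC50", a_fish)):
        df = pd.DataFrame({
            "Id": ids,
            "Prediction": [repr(x) for x in neglog],
            "A_dimensional": [repr(x) for x in col],
            "AD_assessment": ["in domain"] * n,
        })
        fname = f"vega_{model}.csv"
        df.to_csv(outdir / fname, index=False, lineterminator="\n")
        files[model] = fname
    pd.DataFrame({
        "Id": ids,
        "Prediction": [repr(x) for x in neglog],
        "AD_assessment": ["in domain"] * n,
    }).to_csv(outdir / "vega_daphnia_EC50.csv", index=False, lineterminator="\n")
    files["daphnia_EC50"] = "vega_daphnia_EC50.csv"

    manifest = {"seed": spec.seed, "files": files,
                "mw_by_id": dict(zip(ids, mws)), "expected": expected}
    (outdir / "qsar_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
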