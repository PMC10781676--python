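# ecotoxkit

Curation of acute aquatic ecotoxicity data and a mode-of-action (MoA)
catalog for environmental chemicals.

Risk assessment for surface waters needs one robust effect concentration
per chemical and species group, but the raw evidence — effect records in
the US EPA ECOTOX knowledgebase — is heterogeneous in endpoints, units,
exposure durations, and species. `ecotoxkit` implements a reproducible
curation pipeline for the three biological quality elements (BQEs) of the
EU Water Framework Directive — algae, crustaceans, and fish:

1. **Ingest** an ECOTOX-style release archive (ZIP of pipe-delimited
   ASCII tables) and join the `tests`, `results`, `species`, `chemicals`
   and `references` tables on `test_id`, `cas_number`, `species_number`
   and `reference_number`.
2. **Filter** per BQE: water-based dosing only; acute exposure window
   0–5 d / 0–120 h / 0–7200 min in recognized duration-unit codes;
   aquatic habitat; all species (algae) or a standard-test-species
   whitelist (crustaceans, fish); acute effect codes (MOR, GRO, POP,
   REP, MPH, DEV, plus ITX for crustaceans); endpoint families
   EC/ED/EL/IC/LC/LD/LL/LT 1–99 plus LOEC and LETC; a usable numeric
   concentration; a CAS on the study's chemical list.
3. **Standardize** all concentrations to mg/L (molar units resolved via a
   molecular-weight lookup).
4. **Aggregate** per chemical × BQE: n, 5th percentile (type-7 linear
   interpolation, p = 0.05), arithmetic mean, geometric mean, median,
   min, max — each rounded to 4 significant digits *after* computation —
   with all raw values, endpoints, effects, measurements, species,
   durations and reference IDs collapsed into one reviewable field per
   category.
5. **Classify** every statistic against the chemical's predicted water
   solubility S_w (mg/L): class 3 if EC_x ≤ S_w, class 2 up to a half log
   step above (EC_x ≤ S_w·10^0.5), class 1 up to one log step
   (S_w·10^1.0), class 0 beyond — values far above solubility are suspect
   because nominal dosing overestimates dissolved exposure.
6. **Post-process QSAR predictions**: the VEGA IRFMN acute EC50 models
   report −log10(mmol/L) plus a raw a-dimensional value; the algae and
   fish predictions are back-transformed through the box-cox-type map
   EC50 = (a·λ + 1)^(1/0.07) with λ = 0.07 (algae) and 0.11 (fish), the
   Daphnia model via 10^(−pred); mmol/L → mg/L via the molecular mass.
7. **Summarize the MoA catalog**: parse the multi-value annotation
   grammar ("," between categories, " + " between sectors, "/" within a
   sector), validate against controlled vocabularies (8 use groups, 32
   broad MoA categories), and produce parent/TP-split use-group and MoA
   count tables with the catalog's merge rules (Biocide →
   Pesticide/Biocide, Drug of abuse → Pharmaceutical/Drug of abuse,
   "parent + TP" counted as parent, multi-MoA compounds excluded from
   single-category tables).

A seeded synthetic-fixture generator (`ecotoxkit.synth`) emulates every
input at miniature scale with planted ground truth and machine-readable
manifests, so the whole pipeline is testable offline.

## Worked example

```bash
ecotoxkit simulate --seed 7 --outdir demo
ecotoxkit run config.yaml        # or, in Python:
```

```python
from ecotoxkit import PipelineConfig, run_pipeline, read_bqe_table

cfg = PipelineConfig(
    archive="demo/ecotox_release.zip",
    chemical_list="demo/chemical_list.csv",
    mol_weight="demo/ecotoxgroup_mol_weight.csv",
    solubility="demo/solubility_predictions.csv",
    outdir="demo/out",
)
report = run_pipeline(cfg)
print(report["bqe"]["Algae"])
```

prints (seed 7):

```
{'n_retained': 36,
 'rejections': {'chemical': 3, 'dosing': 3, 'species': 43, 'effect': 1,
                'endpoint': 1, 'duration': 1, 'concentration': 1},
 'n_unit_lost': 0, 'unsupported_units': {}, 'n_chemicals': 5,
 'datapoints': {'total': 36, 'geomean': 7.09, 'geosd': 1.23},
 'class_histogram_geomean': {'3': 1, '2': 1, '1': 1, '0': 1, 'missing': 1}}
```

36 algae records survived the filters, each rejected record is attributed
to the first criterion it failed (records of the other two BQEs fall
under `species`), and the five curated chemicals span all four solubility
classes plus one without a solubility profile. The first row of the
curated table:

```python
s = read_bqe_table("demo/out/table_D_algae.csv")[0]
print(s.chemical_id, s.n, s.P5, s.geomean, s.max, s.classes["geomean"])
# M0001 7 0.007716 3.54 41750.0 3.0
```

chemical `M0001` has 7 data points with a 5th percentile of
0.007716 mg/L and a geometric mean of 3.54 mg/L, which lies below the
chemical's solubility limit (class 3).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the seeded fixture set from scratch, runs every pipeline
stage on it (ingest → filter → standardize → aggregate → classify →
QSAR correction → MoA counting), verifies the run against the planted
manifests, and writes the result JSON to `--out`.
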