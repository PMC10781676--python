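# Methods

## The curation model

The package reduces a heterogeneous body of acute aquatic toxicity
records to one effect-value summary per chemical and biological quality
element (BQE: algae, crustaceans, fish). The underlying assumptions:

* Only **water-based dosing** is comparable across studies. Dosing group
  is not a raw column of ECOTOX-style releases; it is derived here from
  the concentration unit: aqueous concentration units (mass/volume,
  ppm/ppb, molar) map to `water_concentration`, mass-per-body-weight
  units to `body_burden`, everything else to `other`. Only
  `water_concentration` records are kept.
* Only **acute** exposures are pooled: 0–5 days, with unit-code sets
  {d, dph, dpf}, {h, ht, hph, hpf, hv}, {mi} selecting the day, hour and
  minute windows (0–120 h, 0–7200 min). Records with missing durations
  are rejected, not imputed: the window is a hard criterion.
* The retained **endpoints** cover the whole concentration–effect
  distribution: EC/ED/EL/IC/LC/LD/LL/LT with effect level 1–99, plus
  LOEC and LETC. Trailing `*` and `/` modifiers are stripped before
  matching; NOEC (chronic reporting) is excluded.
* Pooling across species within a BQE is meaningful for **algae** without
  restriction, but for **crustaceans and fish** only across standard test
  species. The whitelist is configuration
  (`src/ecotoxkit/data/standard_test_species.txt`), seeded with OECD/ISO
  standard species; no authoritative printed list exists, so results that
  depend on it (full-scale coverage counts) are flagged accordingly.

### Aggregation

All retained concentrations are standardized to mg/L. Seven statistics
are computed per chemical × BQE: n, the 5th percentile, arithmetic mean,
geometric mean, median, minimum, maximum. The percentile uses the
(n−1)p+1 linear-interpolation scheme (R type 7 / numpy `linear`), stated
explicitly so the result is environment-independent. Statistics are
computed on unrounded values and only then rounded to 4 significant
digits (rounding first would bias the percentiles); rounding is
decimal-exact on the binary double with ties half-to-even. Provenance
(raw values, endpoints, effects, measurements, species, durations,
reference IDs) is collapsed to one `"; "`-delimited string per category —
the delimiter is distinct from the CSV field delimiter and survives a
quoted round trip.

Censored concentration qualifiers (`>`, `<`, `~`) are split off into a
flag and the numeric value is **kept** (flagged-and-kept default); a
strict caller can drop flagged records before aggregation. Non-numeric
values (`NR`) become missing and fail the concentration criterion.

### Solubility-domain classification

Each statistic is compared with the chemical's predicted water solubility
S_w = 10^logSw · MW · 1000 (logSw in log10 mol/L, MW in g/mol):

| class | condition |
|---|---|
| 3 | EC_x ≤ S_w |
| 2 | S_w < EC_x ≤ S_w·10^0.5 |
| 1 | S_w·10^0.5 < EC_x ≤ S_w·10^1.0 |
| 0 | EC_x > S_w·10^1.0 |

The source material prints the middle boundaries in a typographically
mangled form ("10^5 × log(S_w)"); the half-log-step/full-log-step reading
implemented here is the only one consistent with the accompanying prose
and with dimensional sanity. The boundary exponents (0.5, 1.0) are
overridable. The narrative speaks of "three classes" while four
inequalities are printed; this package exposes all four labels
{3, 2, 1, 0} and documents the mismatch rather than resolving it.
Because classification is monotone non-increasing in EC_x, classes within
one summary always satisfy class(min) ≥ class(P5) ≥ … ≥ class(max).

### QSAR post-processing

The VEGA IRFMN acute EC50 models report −log10(mmol/L) and a raw
a-dimensional value. Due to a molecular-weight bug in the deployed model
version, the algae and fish predictions are rebuilt from the
a-dimensional value via a box-cox-type back-transformation:

* algae: EC50 [mmol/L] = (a·0.07 + 1)^(1.0/0.07)
* fish:  EC50 [mmol/L] = (a·0.11 + 1)^(1.0/0.07)

The fish exponent 1.0/0.07 is implemented exactly as printed even though
box-cox symmetry would suggest 1.0/0.11; the printed form cannot be
ruled a typo from the source alone, so `correct_fish(..., exponent=1/0.11)`
selects the symmetric reading. No correction is printed for the Daphnia
model; its −log values are back-transformed directly (10^−pred). Inputs
outside the transformation domain (a·λ + 1 ≤ 0, i.e. a < −14.29 for
algae, a < −9.09 for fish) yield missing values with a warning — never
clipped. mg/L values are EC50[mmol/L] × MW.

### MoA catalog model

Annotations are hand-curated, so the parser is conservative: category
matching is case- and whitespace-insensitive but reported in canonical
casing; tokens outside the controlled vocabularies are reported, never
silently coerced or dropped. The 8 use-group categories are fixed; the
32-entry broad-MoA vocabulary is an editable list
(`src/ecotoxkit/data/moa_broad_categories.txt`) seeded with every
category named in the catalog narrative plus field-standard system-level
categories — the authoritative vocabulary ships with the catalog's own
column dictionary. Counting conventions: "parent + TP" compounds tally
as parents; Biocide/Drug-of-abuse merge into the combined categories;
compounds in more than one merged use group are counted once under
"Multiple use"; compounds with multiple broad MoAs are excluded from the
single-category table and reported as a separate multi-MoA count, so
single + multi + unknown always equals the catalog size. The per-chemical
data-point spread is reported both as geometric mean and geometric SD.

## Synthetic fixtures

`ecotoxkit.synth` writes miniature versions of every input with planted
ground truth: survivors with known mg/L values across the supported unit
dialect, one single-violation reject per criterion per BQE, a dangling
results row for the join report, solubility profiles spanning all four
classes (ratios kept clear of the class boundaries) plus one missing
profile, VEGA-style exports with one out-of-domain compound, and an
annotation table with planted categories. Expected outcomes are emitted
in JSON manifests computed with independent primitives (`numpy.quantile`,
`scipy.stats.gmean`, `"%.4g"` formatting, inline comparisons), so tests
never verify the pipeline against itself. One integer seed determines
every output byte (archive timestamps are pinned).

What fixtures do **not** emulate: the statistical texture of a real
release (scale, duplicated studies, exotic unit spellings, inconsistent
casing at volume). A green end-to-end test establishes that the
mechanics — joining, attribution, conversion, aggregation, rounding,
classification, counting — are exact on controlled input; it does not
establish full-scale reproduction, which additionally depends on the
standard-species whitelist and the pinned release (see the acceptance
tests that require `data/external/`).

## Numerical choices

* 4-significant-digit rounding via exact decimal expansion of the binary
  double, ties half-to-even.
* Percentile by the explicit (n−1)p+1 formula; singleton input returns
  the value itself.
* Geometric mean as exp(mean(log x)); non-positive values are a caller
  error (they are excluded upstream by the concentration criterion).
* Unit conversions: ppm ≡ mg/L and ppb ≡ µg/L under the dilute aqueous
  assumption; unsupported units yield missing values tallied in an
  auditable report rather than errors, so a release-wide run completes.
* Rejection attribution order is fixed (chemical, dosing,
  species/habitat, effect, endpoint, duration, concentration) for a
  stable report; the retained set itself is order-independent.
* Join: duplicate primary keys in lookup tables are an error (ambiguous
  join); dangling foreign keys are dropped and counted, since real
  releases contain them and the pipeline must proceed.

## Known limitations

* The standard-test-species whitelist and the broad-MoA vocabulary are
  best-effort seeds, not the authoritative lists; full-scale count
  reproduction is contingent on them.
* Censored values (`>`, `<`) are aggregated at face value (flagged);
  no survival-analysis treatment of censoring is attempted.
* No chronic (NOEC) pipeline; no dose-per-body-weight conversion; the
  solubility and effect predictors themselves are not executed — only
  their tabular outputs are consumed.
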