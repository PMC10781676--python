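"""Per-BQE record-selection rules: endpoint/effect/duration/species filters."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotoxkit.criteria import (
    ENDPOINT_FAMILIES,
    FilterCriteria,
    apply_filters,
    default_criteria,
    load_standard_species,
    match_duration,
    match_effect,
    match_endpoint,
    select_species,
)

ALGAE = default_criteria("Algae")
CRUSTACEAN = default_criteria("Crustacean")
FISH = default_criteria("Fish")


class TestEndpoint:
    @pytest.mark.parametrize("code,expected", [
        ("LC50", True), ("NOEC", False), ("EC50*", True), ("LC50/", True),
        ("LC0", False), ("LC100", False), ("LOEC", True), ("LETC", True),
        ("lc50", True), ("EL20", True), ("IC25", True), ("LT10", True),
        ("", False), ("XX50", False), ("LC", False), ("LC5.5", False),
    ])
    def test_examples(self, code, expected):
        assert match_endpoint(code) is expected

    def test_family_enumeration_oracle(self):
        """Every family code with level 1-99 matches; 0 and 100 never do."""
        for fam in ENDPOINT_FAMILIES:
            for level in range(0, 101):
                assert match_endpoint(f"{fam}{level}") is (1 <= level <= 99)


class TestDuration:
    @pytest.mark.parametrize("value,unit,expected", [
        (96, "h", True), (120, "h", True), (121, "h", False),
        (5, "d", True), (5.01, "d", False), (0, "d", True),
        (7200, "mi", True), (7201, "mi", False),
        (96, "ht", True), (2, "dph", True), (48, "hv", True),
        (96, "wk", False), (None, "h", False), (float("nan"), "d", False),
    ])
    def test_window(self, value, unit, expected):
        assert match_duration(value, unit, ALGAE) is expected


class TestEffect:
    @pytest.mark.parametrize("code,criteria,expected", [
        ("ITX", CRUSTACEAN, True), ("ITX", FISH, False), ("ITX", ALGAE, False),
        ("MOR", ALGAE, True), ("MOR", CRUSTACEAN, True), ("MOR", FISH, True),
        ("BEH", FISH, False), ("mor", FISH, True), ("GRO*", ALGAE, True),
    ])
    def test_membership(self, code, criteria, expected):
        assert match_effect(code, criteria) is expected


def _records(rows):
    defaults = {
        "cas_number": "1912249", "ecotox_group": "Fish", "habitat": "Water",
        "species_name": "Danio rerio", "endpoint": "LC50", "effect": "MOR",
        "dosing_group": "water_concentration", "conc_value": 1.2,
        "conc_qualifier": "none", "conc_unit": "mg/L",
        "duration_value": 96.0, "duration_unit": "h",
        "test_id": "1", "species_number": "5", "reference_number": "9",
        "measurement": "MORT",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestSelectSpecies:
    def test_algae_all_mode_keeps_any_water_species(self):
        recs = _records([{"ecotox_group": "Algae",
                          "species_name": "Raphidocelis subcapitata"}])
        assert len(select_species(recs, ALGAE)) == 1

    def test_fish_standard_mode_drops_unlisted_species(self):
        recs = _records([{"species_name": "Barbus nonstandardus"}])
        assert len(select_species(recs, FISH)) == 0

    def test_hand_filtered_six_record_fixture(self):
        recs = _records([
            {},                                          # kept
            {"habitat": "Soil"},                         # wrong habitat
            {"ecotox_group": "Crustacean"},              # wrong group
            {"species_name": "Oncorhynchus mykiss"},     # kept (whitelisted)
            {"species_name": "Barbus nonstandardus"},    # not whitelisted
            {"habitat": " water ", "species_name": "Danio rerio"},  # kept, trim
        ])
        kept = select_species(recs, FISH)
        assert list(kept.index) == [0, 3, 5]

    def test_standard_mode_without_whitelist_errors(self):
        bad = dataclasses.replace(FISH, standard_species=())
        with pytest.raises(ValueError, match="whitelist"):
            select_species(_records([{}]), bad)

    def test_shipped_whitelist_loads(self):
        species = load_standard_species()
        assert "Daphnia magna" in species and "Danio rerio" in species


class TestApplyFilters:
    def test_fully_conforming_record_retained(self):
        fs = apply_filters(_records([{}]), {"1912249"}, FISH)
        assert fs.n_retained == 1
        assert sum(fs.rejections.values()) == 0

    def test_long_duration_attributed_to_duration(self):
        fs = apply_filters(_records([{"duration_value": 144.0}]),
                           {"1912249"}, FISH)
        assert fs.n_retained == 0
        assert fs.rejections["duration"] == 1

    def test_planted_single_violation_fixture(self):
        recs = _records([
            {},
            {"cas_number": "99999"},
            {"dosing_group": "body_burden"},
            {"species_name": "Barbus nonstandardus"},
            {"habitat": "Soil"},
            {"effect": "BEH"},
            {"endpoint": "NOEC"},
            {"duration_value": 144.0},
            {"duration_unit": "wk"},
            {"conc_value": float("nan")},
            {"conc_value": -1.0},
            {"ecotox_group": "Algae"},
        ])
        fs = apply_filters(recs, {"1912249"}, FISH)
        assert fs.n_retained == 1
        assert fs.rejections == {"chemical": 1, "dosing": 1, "species": 3,
                                 "effect": 1, "endpoint": 1, "duration": 2,
                                 "concentration": 2}
        assert fs.n_input == len(recs)

    def test_idempotent(self):
        recs = _records([{}, {"duration_value": 144.0}, {"effect": "BEH"}])
        fs1 = apply_filters(recs, {"1912249"}, FISH)
        fs2 = apply_filters(fs1.records, {"1912249"}, FISH)
        pd.testing.assert_frame_equal(fs1.records, fs2.records)
        assert sum(fs2.rejections.values()) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_tightening_is_monotone(self, seed):
        """Shrinking the duration window or effect set never increases the
        retained count."""
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(12):
            rows.append({
                "effect": rng.choice(["MOR", "GRO", "BEH", "DEV"]),
                "endpoint": rng.choice(["LC50", "NOEC", "EC10"]),
                "duration_value": float(rng.integers(0, 200)),
                "duration_unit": rng.choice(["h", "d", "wk"]),
                "conc_value": float(rng.choice([1.0, np.nan])),
            })
        recs = _records(rows)
        base = apply_filters(recs, None, FISH).n_retained
        tighter_window = dataclasses.replace(
            FISH, max_h=48.0, max_d=2.0, max_m=2880.0)
        tighter_effects = dataclasses.replace(FISH, effects=("MOR",))
        assert apply_filters(recs, None, tighter_window).n_retained <= base
        assert apply_filters(recs, None, tighter_effects).n_retained <= base

    def test_retention_independent_of_attribution_order(self):
        """The retained set is the conjunction of all criteria, so shuffling
        the rows (and hence evaluation order) never changes membership."""
        recs = _records([
            {}, {"effect": "BEH", "endpoint": "NOEC"},
            {"duration_value": 144.0, "conc_value": float("nan")},
            {"species_name": "Oncorhynchus mykiss"},
        ])
        fs = apply_filters(recs, None, FISH)
        shuffled = recs.sample(frac=1, random_state=0).reset_index(drop=True)
        fs2 = apply_filters(shuffled, None, FISH)
        key = ["species_name", "duration_value", "effect"]
        assert sorted(map(tuple, fs.records[key].values.tolist())) == \
            sorted(map(tuple, fs2.records[key].values.tolist()))


class TestCriteriaConfig:
    def test_defaults_match_acute_window(self):
        for c in (ALGAE, CRUSTACEAN, FISH):
            assert (c.max_d, c.max_h, c.max_m) == (5.0, 120.0, 7200.0)
            assert c.dosing_group == "water_concentration"
            assert c.habitat == "Water"
            assert c.quantile == 0.05
        assert ALGAE.species_selection == "all"
        assert FISH.species_selection == "standard_test_species"
        assert "ITX" in CRUSTACEAN.effects and "ITX" not in FISH.effects

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError, match="quantile"):
            FilterCriteria(quantile=1.5)

    def test_unknown_bqe(self):
        with pytest.raises(KeyError):
            default_criteria("Insects")
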