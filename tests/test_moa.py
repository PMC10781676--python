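"""Annotation-catalog parsing, separator grammar, and summary counting."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotoxkit.moa import (
    CompoundAnnotation,
    ControlledVocabulary,
    count_by_moa,
    count_by_use_group,
    read_annotations,
    split_multivalue,
    validate_annotations,
)

VOCAB = ControlledVocabulary.default()


class TestSplitMultivalue:
    @pytest.mark.parametrize("text,level,expected", [
        ("Pesticide, Pharmaceutical", "top", ["Pesticide", "Pharmaceutical"]),
        ("I/A", "within-sector", ["I", "A"]),
        ("", "top", []),
        (None, "top", []),
        ("industrial chemical + insecticide", "sector",
         ["industrial chemical", "insecticide"]),
        (" a ,, b ", "top", ["a", "b"]),
    ])
    def test_grammar(self, text, level, expected):
        assert split_multivalue(text, level) == expected

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            split_multivalue("x", "paragraph")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")),
        min_size=1, max_size=8), max_size=6))
    def test_idempotent_on_rejoined_output(self, tokens):
        once = split_multivalue(", ".join(tokens), "top")
        again = split_multivalue(", ".join(once), "top")
        assert once == again


def _ann(**kw):
    base = dict(chemical_id="A1", parent_or_tp="parent",
                use_group=["Pesticide"], moa_broad=["Neuroactive"])
    base.update(kw)
    return CompoundAnnotation(**base)


class TestUseGroupCounts:
    def test_biocide_merged_into_pesticide_biocide(self):
        table, unknown = count_by_use_group([_ann(use_group=["Biocide"])], VOCAB)
        assert table.loc[0, "use_group"] == "Pesticide/Biocide"
        assert table.loc[0, "parent"] == 1
        assert unknown == []

    def test_parent_plus_tp_counts_as_parent(self):
        table, _ = count_by_use_group(
            [_ann(parent_or_tp="parent + TP", tp_of=["A9"])], VOCAB)
        assert table.loc[0, "parent"] == 1 and table.loc[0, "TP"] == 0

    def test_pesticide_and_biocide_merge_to_one_category_not_multiple(self):
        table, _ = count_by_use_group(
            [_ann(use_group=["Pesticide", "Biocide"])], VOCAB)
        assert list(table["use_group"]) == ["Pesticide/Biocide"]

    def test_cross_sector_compound_counted_once_as_multiple_use(self):
        table, _ = count_by_use_group(
            [_ann(use_group=["Pesticide", "Industrial Chemical"])], VOCAB)
        assert list(table["use_group"]) == ["Multiple use"]
        assert int(table["parent"].sum() + table["TP"].sum()) == 1

    def test_unknown_token_reported_not_dropped(self):
        table, unknown = count_by_use_group(
            [_ann(use_group=["Pestiicide"])], VOCAB)
        assert unknown == ["Pestiicide"]
        assert list(table["use_group"]) == ["unknown"]

    def test_permutation_invariant(self):
        anns = [_ann(chemical_id=f"A{i}",
                     use_group=[g], parent_or_tp="TP" if i % 2 else "parent",
                     tp_of=["A0"] if i % 2 else [])
                for i, g in enumerate(["Pesticide", "Metal", "Natural",
                                       "Pharmaceutical", "Biocide"])]
        t1, _ = count_by_use_group(anns, VOCAB)
        t2, _ = count_by_use_group(anns[::-1], VOCAB)
        pd.testing.assert_frame_equal(t1, t2)


class TestMoaCounts:
    def test_multi_moa_excluded_from_single_table(self):
        anns = [_ann(moa_broad=["Neuroactive", "Endocrine"])]
        out = count_by_moa(anns, "broad", VOCAB)
        assert out["n_multi"] == 1 and out["n_single"] == 0
        assert len(out["single"]) == 0
        assert out["total"]["Neuroactive"] == 1 and out["total"]["Endocrine"] == 1

    def test_empty_moa_is_unknown(self):
        out = count_by_moa([_ann(moa_broad=[])], "broad", VOCAB)
        assert out["n_unknown"] == 1

    def test_partition_invariant(self):
        anns = [
            _ann(chemical_id="A1", moa_broad=["Neuroactive"]),
            _ann(chemical_id="A2", moa_broad=["Neuroactive", "Endocrine"]),
            _ann(chemical_id="A3", moa_broad=[]),
            _ann(chemical_id="A4", moa_broad=["Endocrine"]),
        ]
        out = count_by_moa(anns, "broad", VOCAB)
        assert out["n_single"] + out["n_multi"] + out["n_unknown"] == len(anns)
        assert int(out["single"].sum()) == out["n_single"]

    def test_fixture_counts_match_manifest(self, fixture_set):
        d, manifests = fixture_set
        m = manifests["annotations"]
        anns = read_annotations(d / m["file"])
        assert len(anns) == m["n"]
        out = count_by_moa(anns, "broad", VOCAB)
        assert out["n_single"] == m["moa_broad"]["n_single"]
        assert out["n_multi"] == m["moa_broad"]["n_multi"]
        assert out["n_unknown"] == m["moa_broad"]["n_unknown"]
        assert out["single"].to_dict() == m["moa_broad"]["single"]
        assert out["total"].to_dict() == m["moa_broad"]["total"]
        table, unknown = count_by_use_group(anns, VOCAB)
        assert unknown == []
        got = {row["use_group"]: {"parent": int(row["parent"]),
                                  "TP": int(row["TP"])}
               for _, row in table.iterrows()}
        want = {k: {"parent": v.get("parent", 0), "TP": v.get("TP", 0)}
                for k, v in m["use_group_counts"].items()}
        assert got == want


class TestValidation:
    def test_clean_catalog_empty_report(self):
        report = validate_annotations(
            [_ann(), _ann(chemical_id="A2", parent_or_tp="TP", tp_of=["A1"])],
            VOCAB)
        assert len(report) == 0

    def test_tp_without_parent_reference(self):
        report = validate_annotations([_ann(parent_or_tp="TP")], VOCAB)
        assert list(report["kind"]) == ["tp_without_parent"]

    def test_misspelled_broad_category_named(self):
        report = validate_annotations(
            [_ann(moa_broad=["Neuroaktive"])], VOCAB)
        assert list(report["kind"]) == ["unknown_moa_broad"]
        assert list(report["detail"]) == ["Neuroaktive"]

    def test_duplicate_ids_flagged(self):
        report = validate_annotations([_ann(), _ann()], VOCAB)
        assert "duplicate_id" in set(report["kind"])


class TestReadAnnotations:
    def test_duplicate_internal_id_rejected(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("ID,parent_or_TP\nA1,parent\nA1,TP\n")
        with pytest.raises(ValueError, match="duplicate internal ID"):
            read_annotations(p)

    def test_parent_tp_spacing_variants(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("ID,parent_or_TP,TP_of\nA1,parent+TP,A9\nA2,Parent + tp,A9\n")
        anns = read_annotations(p)
        assert all(a.parent_or_tp == "parent + TP" for a in anns)
        assert all(a.is_parent for a in anns)

    def test_vocabulary_has_32_broad_categories(self):
        assert len(VOCAB.moa_broad) == 32
        assert len(VOCAB.use_groups) == 8
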