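"""Structural model, ODM XML round trips, validation and annotation access."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odmannotate import (AnnotationSignature, CodeList, CodeListEntry,
                         ConceptCode, DataItem, EmptyModelError,
                         EmptySignatureError, IntegrityError, OdmParseError,
                         UnknownTargetError, entry_oid, extract_annotations,
                         make_synonym_corpus, make_table1_fixture, read_odm,
                         set_annotation, validate, write_odm)
from conftest import small_model


# ---------------------------------------------------------------------------
# Concept codes and signatures
# ---------------------------------------------------------------------------

class TestSignature:
    def test_canonical_order_and_join(self):
        sig = AnnotationSignature.from_codes(
            [ConceptCode("C0027361"), ConceptCode("C0005615"), ConceptCode("C0011008")])
        assert sig.canonical == "C0005615+C0011008+C0027361"

    def test_duplicates_collapse(self):
        sig = AnnotationSignature.from_codes([ConceptCode("C0005890")] * 2)
        assert sig.canonical == "C0005890"

    def test_empty_rejected(self):
        with pytest.raises(EmptySignatureError):
            AnnotationSignature.from_codes([])

    @pytest.mark.parametrize("bad", ["", "C00 890", "a\tb"])
    def test_codes_reject_whitespace_and_empty(self, bad):
        with pytest.raises(ValueError):
            ConceptCode(bad)

    @given(st.permutations(["C0005615", "C0011008", "C0027361", "C0421451"]))
    def test_any_permutation_renders_identically(self, perm):
        sig = AnnotationSignature.from_codes([ConceptCode(v) for v in perm])
        assert sig.canonical == "C0005615+C0011008+C0027361+C0421451"

    def test_parse_inverts_canonical(self):
        sig = AnnotationSignature.parse("C0005615+C0011008")
        assert AnnotationSignature.parse(sig.canonical) == sig


# ---------------------------------------------------------------------------
# Reading and writing ODM XML
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_two_aliases_become_one_postcoordinated_signature(self):
        model = small_model(item_names=("Date of Birth",),
                            annotations=("C0011008+C0027361",))
        reread = read_odm(write_odm(model))
        assert reread.items[0].annotation.canonical == "C0011008+C0027361"

    def test_three_code_signature_yields_three_aliases_in_order(self):
        model = small_model(item_names=("Date of Birth",),
                            annotations=("C0027361+C0005615+C0011008",))
        xml = write_odm(model)
        positions = [xml.index(f'Name="{c}"')
                     for c in ("C0005615", "C0011008", "C0027361")]
        assert xml.count("<Alias") == 3
        assert positions == sorted(positions)

    def test_single_code_single_alias(self):
        xml = write_odm(small_model(annotations=("C0005890",)))
        assert xml.count("<Alias") == 1 and 'Name="C0005890"' in xml

    def test_write_is_deterministic(self):
        model = small_model(item_names=("Height", "Weight"),
                            annotations=("C0005890", "C0005910"))
        assert write_odm(model) == write_odm(model)

    @pytest.mark.parametrize("corpus_factory", [
        make_table1_fixture,
        lambda: make_synonym_corpus(3, 4, 2, seed=7)[0],
    ])
    def test_round_trip_over_synthetic_corpora(self, corpus_factory):
        for model in corpus_factory():
            assert read_odm(write_odm(model)) == model

    def test_round_trip_preserves_value_domain(self):
        model = small_model(annotations=("C0005890",))
        item = model.items[0]
        item.data_type = "float"
        item.description = "Standing height"
        item.question = "How tall is the patient?"
        item.question_lang = "en"
        item.range_min, item.range_max, item.unit = 30.0, 250.0, "cm"
        model.codelists.append(CodeList("CL.1", "BP location", [
            CodeListEntry("LA", "left arm", AnnotationSignature.parse("C0475440")),
            CodeListEntry("RA", "right arm"),
        ]))
        item.codelist_ref = "CL.1"
        assert read_odm(write_odm(model)) == model

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(OdmParseError):
            read_odm("<ODM><unclosed>")

    def test_zero_items_raises_empty_model_error(self):
        model = small_model()
        model.items.clear()
        model.groups[0].item_refs.clear()
        xml = write_odm(model)
        with pytest.raises(EmptyModelError):
            read_odm(xml)

    def test_dangling_reference_raises_integrity_error_naming_it(self):
        xml = write_odm(small_model()).replace('ItemOID="IT.1"', 'ItemOID="IT.9"')
        with pytest.raises(IntegrityError, match="IT.9"):
            read_odm(xml)

    def test_write_refuses_invalid_model(self):
        model = small_model()
        model.items[0].codelist_ref = "CL.MISSING"
        with pytest.raises(IntegrityError):
            write_odm(model)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

class TestValidate:
    def test_valid_fixture_corpus_has_zero_issues(self, table1_corpus):
        assert all(validate(m) == [] for m in table1_corpus)

    def test_dangling_codelist_ref(self):
        model = small_model()
        model.items[0].codelist_ref = "CL.MISSING"
        issues = validate(model)
        assert [i.kind for i in issues] == ["dangling-ref"]
        assert "CL.MISSING" in issues[0].message

    def test_range_order(self):
        model = small_model()
        model.items[0].range_min, model.items[0].range_max = 10, 5
        assert [i.kind for i in validate(model)] == ["range-order"]

    def test_duplicate_oid(self):
        model = small_model()
        model.items.append(DataItem(oid="IT.1", name="dup"))
        model.groups[0].item_refs.append("IT.1")
        assert "duplicate-oid" in {i.kind for i in validate(model)}


# ---------------------------------------------------------------------------
# set_annotation / extract_annotations
# ---------------------------------------------------------------------------

class TestAnnotationAccess:
    def test_set_then_extract(self):
        model = small_model(item_names=("Height",))
        set_annotation(model, "IT.1", AnnotationSignature.parse("C0005890"))
        rows = extract_annotations(model)
        assert [(r.owner_oid, r.owner_kind, r.signature.canonical)
                for r in rows] == [("IT.1", "item", "C0005890")]

    def test_set_is_idempotent_and_replacing(self):
        model = small_model(annotations=("C0475440",))
        sig = AnnotationSignature.parse("C0005890")
        set_annotation(model, "IT.1", sig)
        snapshot = write_odm(model)
        set_annotation(model, "IT.1", sig)
        assert write_odm(model) == snapshot

    def test_set_on_codelist_entry(self):
        model = small_model()
        model.codelists.append(CodeList("CL.BP", "BP location",
                                        [CodeListEntry("LA", "left arm")]))
        model.items[0].codelist_ref = "CL.BP"
        set_annotation(model, entry_oid("CL.BP", "LA"),
                       AnnotationSignature.parse("C0475440"))
        rows = extract_annotations(model)
        kinds = {r.owner_kind for r in rows if r.name == "left arm"}
        assert kinds == {"codelist_entry"}

    def test_unknown_target(self):
        with pytest.raises(UnknownTargetError):
            set_annotation(small_model(), "IT.99",
                           AnnotationSignature.parse("C0005890"))

    def test_partial_annotation_counts(self):
        model = small_model(item_names=("a", "b", "c"),
                            annotations=("C0005890", None, None))
        assert len(extract_annotations(model)) == 1

    def test_table1_corpus_row_total_matches_bookkeeping(self, table1_corpus):
        total = sum(len(extract_annotations(m)) for m in table1_corpus)
        assert total == 86 + 85 + 66 + 29 + 37
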