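"""JSON/YAML text forms: naming, omission, determinism, round-trips."""

import pytest

from phenokit import (
    DocumentFormat,
    HydrationError,
    OntologyClass,
    ParseError,
    PhenotypicFeature,
    SyntheticConfig,
    UnknownFieldError,
    convert,
    generate_synthetic,
    read_document,
    write_document,
)
from phenokit.serialization import from_jsonable, to_jsonable

JSON = DocumentFormat.JSON
YAML = DocumentFormat.YAML


class TestWireForm:
    def test_field_names_are_lower_camel_case(self, retinoblastoma):
        data = to_jsonable(retinoblastoma)
        assert "phenotypicFeatures" in data
        assert "metaData" in data
        gi = data["interpretations"][0]["diagnosis"]["genomicInterpretations"][0]
        assert "subjectOrBiosampleId" in gi
        assert data["subject"]["timeAtLastEncounter"] == {"age": "P6M"}

    def test_default_values_omitted(self):
        feature = PhenotypicFeature(type=OntologyClass(id="HP:0000486", label="Strabismus"), excluded=False)
        assert "excluded" not in to_jsonable(feature)
        assert "excluded" in to_jsonable(feature.replace(excluded=True))

    def test_enum_values_use_wire_names(self, retinoblastoma):
        data = to_jsonable(retinoblastoma)
        assert data["subject"]["sex"] == "FEMALE"
        assert data["interpretations"][0]["progressStatus"] == "SOLVED"
        descriptor = data["interpretations"][0]["diagnosis"]["genomicInterpretations"][1][
            "variantInterpretation"
        ]["variationDescriptor"]
        assert descriptor["moleculeContext"] == "genomic"

    def test_map_keys_sorted_and_reference_range_nested(self, retinoblastoma):
        data = to_jsonable(retinoblastoma)
        attrs = data["files"][0]["fileAttributes"]
        assert list(attrs) == sorted(attrs)
        rr = data["measurements"][0]["quantity"]["referenceRange"]
        assert rr["low"] == 10 and rr["high"] == 21 and rr["unit"]["id"] == "UCUM:mm[Hg]"

    def test_serialization_deterministic(self, retinoblastoma):
        for fmt in (JSON, YAML):
            assert write_document(retinoblastoma, fmt) == write_document(retinoblastoma, fmt)


class TestEquivalenceAcrossFormats:
    def test_yaml_and_json_hydrate_to_the_same_value(self):
        yaml_text = "id: 'HP:0001875'\nlabel: Neutropenia\n"
        json_text = '{"id": "HP:0001875", "label": "Neutropenia"}'
        import json as json_mod

        import yaml as yaml_mod

        from_yaml = from_jsonable(yaml_mod.safe_load(yaml_text), OntologyClass)
        from_json = from_jsonable(json_mod.loads(json_text), OntologyClass)
        assert from_yaml == from_json == OntologyClass(id="HP:0001875", label="Neutropenia")

    def test_round_trip_both_formats(self, retinoblastoma):
        for fmt in (JSON, YAML):
            assert read_document(write_document(retinoblastoma, fmt), fmt) == retinoblastoma

    def test_convert_is_idempotent(self, retinoblastoma):
        yaml_text = write_document(retinoblastoma, YAML)
        json_text = convert(yaml_text, YAML, JSON)
        assert convert(json_text, JSON, YAML) == yaml_text

    def test_field_order_irrelevant_on_input(self):
        a = read_document('{"id": "x", "subject": {"id": "s"}}', JSON)
        b = read_document('{"subject": {"id": "s"}, "id": "x"}', JSON)
        assert a == b

    def test_timestamp_strings_survive_yaml(self, minimal_phenopacket):
        text = write_document(minimal_phenopacket, YAML)
        again = read_document(text, YAML)
        assert again.meta_data.created == "2022-01-01T00:00:00Z"


class TestErrors:
    def test_missing_required_id_reports_path(self):
        with pytest.raises(HydrationError) as excinfo:
            read_document('{"subject": {"id": "s"}}', JSON)
        assert excinfo.value.path == "/id"

    def test_unknown_field_rejected_by_default(self):
        with pytest.raises(UnknownFieldError) as excinfo:
            read_document('{"id": "x", "subjectt": {}}', JSON)
        assert excinfo.value.path == "/subjectt"

    def test_lenient_mode_warns_and_preserves_unknown_fields(self):
        warnings = []
        doc = read_document(
            '{"id": "x", "customAnnotation": {"a": 1}}', JSON, strict=False, warnings=warnings
        )
        assert [w.rule_id for w in warnings] == ["unknown-field"]
        assert to_jsonable(doc)["customAnnotation"] == {"a": 1}

    def test_type_mismatch_reports_path(self):
        with pytest.raises(HydrationError) as excinfo:
            read_document('{"id": "x", "phenotypicFeatures": {"not": "a list"}}', JSON)
        assert excinfo.value.path == "/phenotypicFeatures"

    def test_unknown_enum_value_is_an_error(self):
        with pytest.raises(HydrationError) as excinfo:
            read_document('{"id": "x", "subject": {"id": "s", "sex": "F"}}', JSON)
        assert "UNKNOWN_SEX" in str(excinfo.value)  # message lists the vocabulary

    @pytest.mark.parametrize("text, fmt", [("{not json", JSON), ("a: [unclosed", YAML), ("", YAML)])
    def test_malformed_text_raises_parse_error(self, text, fmt):
        with pytest.raises(ParseError):
            read_document(text, fmt)


def test_round_trip_identity_over_synthetic_documents():
    """Both text forms must reproduce generator output exactly (200 seeds)."""
    for seed in range(200):
        doc = generate_synthetic(SyntheticConfig(seed=seed))
        assert read_document(write_document(doc, YAML), YAML) == doc
        assert read_document(write_document(doc, JSON), JSON) == doc


def test_packaged_fixture_files_match_the_builder(retinoblastoma):
    from importlib import resources

    data = resources.files("phenokit") / "data"
    assert (data / "retinoblastoma.yaml").read_text() == write_document(retinoblastoma, YAML)
    assert (data / "retinoblastoma.json").read_text() == write_document(retinoblastoma, JSON)
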