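"""The three validator layers, range classification, and profiles."""

import pytest

from phenokit import (
    Biosample,
    Diagnosis,
    GeneDescriptor,
    GenomicInterpretation,
    Individual,
    Interpretation,
    MetaData,
    OntologyClass,
    Phenopacket,
    PhenotypicFeature,
    Profile,
    Quantity,
    RangeClass,
    ReferenceRange,
    Severity,
    TimeElement,
    VitalState,
    VitalStatus,
    classify_against_range,
    load_profile,
    validate,
    validate_crossrefs,
    validate_metadata,
    validate_profile,
    validate_structure,
)
from phenokit.validation import PROFILES
from phenokit.vocabulary import RESOURCES, term

META = MetaData(created="2022-01-01T00:00:00Z")


class TestStructure:
    def test_fixture_is_structurally_valid(self, retinoblastoma):
        assert validate_structure(retinoblastoma) == []

    def test_minimal_phenopacket_is_valid(self, minimal_phenopacket):
        assert validate_structure(minimal_phenopacket) == []

    def test_empty_id_and_missing_metadata(self):
        issues = validate_structure(Phenopacket(id=""))
        assert [(i.rule_id, i.path) for i in issues] == [
            ("required-id", "/id"),
            ("required-metadata", "/metaData"),
        ]

    def test_non_curie_term_flagged_at_its_path(self):
        doc = Phenopacket(
            id="x",
            meta_data=META,
            phenotypic_features=(PhenotypicFeature(type=OntologyClass(id="retinoblastoma")),),
        )
        issues = validate_structure(doc)
        assert len(issues) == 1
        assert issues[0].rule_id == "curie-syntax"
        assert issues[0].path == "/phenotypicFeatures/0/type/id"

    def test_malformed_duration_flagged(self):
        doc = Phenopacket(
            id="x", meta_data=META, subject=Individual(id="s", time_at_last_encounter=TimeElement(age="P6W"))
        )
        assert [i.rule_id for i in validate_structure(doc)] == ["malformed-duration"]

    def test_reference_range_order(self):
        doc = Phenopacket(
            id="x",
            meta_data=META,
            measurements=(
                __import__("phenokit").Measurement(
                    assay=term("LOINC:79893-4"),
                    quantity=Quantity(
                        unit=term("UCUM:mm[Hg]"),
                        value=15.0,
                        reference_range=ReferenceRange(unit=term("UCUM:mm[Hg]"), low=21.0, high=10.0),
                    ),
                ),
            ),
        )
        issues = [i for i in validate_structure(doc) if i.rule_id == "range-order"]
        assert len(issues) == 1 and issues[0].severity is Severity.ERROR

    def test_death_fields_require_deceased_status(self):
        doc = Phenopacket(
            id="x",
            meta_data=META,
            subject=Individual(
                id="s", vital_status=VitalStatus(status=VitalState.ALIVE, survival_time_in_days=20)
            ),
        )
        issues = validate_structure(doc)
        assert [i.rule_id for i in issues] == ["vital-status"]
        # the same fields are legitimate on a deceased individual
        doc2 = Phenopacket(
            id="x",
            meta_data=META,
            subject=Individual(
                id="s", vital_status=VitalStatus(status=VitalState.DECEASED, survival_time_in_days=20)
            ),
        )
        assert validate_structure(doc2) == []

    def test_validators_are_pure_and_stably_ordered(self):
        doc = Phenopacket(
            id="",
            subject=Individual(id="s", time_at_last_encounter=TimeElement(age="bad")),
        )
        assert validate_structure(doc) == validate_structure(doc)
        paths = [i.path for i in validate_structure(doc)]
        assert paths == sorted(paths)


class TestCrossrefs:
    def test_fixture_references_resolve(self, retinoblastoma):
        # first genomic interpretation anchors to the subject, second to the
        # tumor biosample; both must resolve
        assert validate_crossrefs(retinoblastoma) == []

    def test_dangling_reference_is_an_error(self):
        doc = Phenopacket(
            id="x",
            meta_data=META,
            subject=Individual(id="proband A"),
            interpretations=(
                Interpretation(
                    id="i1",
                    diagnosis=Diagnosis(
                        disease=term("NCIT:C7541"),
                        genomic_interpretations=(
                            GenomicInterpretation(
                                subject_or_biosample_id="biosample.99",
                                gene_descriptor=GeneDescriptor(value_id="HGNC:9884", symbol="RB1"),
                            ),
                        ),
                    ),
                ),
            ),
        )
        issues = validate_crossrefs(doc)
        assert len(issues) == 1
        assert issues[0].rule_id == "dangling-subject-or-biosample-id"
        assert "biosample.99" in issues[0].message

    def test_biosample_individual_mismatch(self):
        doc = Phenopacket(
            id="x",
            meta_data=META,
            subject=Individual(id="proband A"),
            biosamples=(Biosample(id="b1", individual_id="someone else"),),
        )
        assert [i.rule_id for i in validate_crossrefs(doc)] == ["biosample-individual-mismatch"]


class TestMetadata:
    def test_fixture_prefixes_all_declared(self, retinoblastoma):
        assert validate_metadata(retinoblastoma) == []

    def test_undeclared_prefix_named_in_error(self):
        doc = Phenopacket(
            id="x",
            meta_data=META,
            phenotypic_features=(PhenotypicFeature(type=term("HP:0007906")),),
        )
        issues = validate_metadata(doc)
        assert len(issues) == 1
        assert issues[0].rule_id == "undeclared-prefix"
        assert "'HP'" in issues[0].message

    def test_unused_resource_is_a_warning(self):
        doc = Phenopacket(id="x", meta_data=MetaData(created="2022-01-01T00:00:00Z",
                                                     resources=(RESOURCES["NCIT"],)))
        issues = validate_metadata(doc)
        assert [(i.rule_id, i.severity) for i in issues] == [("unused-resource", Severity.WARNING)]

    def test_prefix_matching_is_case_sensitive(self):
        lowercase = RESOURCES["HP"].replace(namespace_prefix="hp")
        doc = Phenopacket(
            id="x",
            meta_data=MetaData(created="2022-01-01T00:00:00Z", resources=(lowercase,)),
            phenotypic_features=(PhenotypicFeature(type=term("HP:0007906")),),
        )
        rules = {i.rule_id for i in validate_metadata(doc)}
        assert rules == {"undeclared-prefix", "unused-resource"}


class TestRangeClassification:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (25.0, RangeClass.ABOVE),  # raised intraocular pressure
            (15.0, RangeClass.WITHIN),  # normal pressure in the other eye
            (21.0, RangeClass.WITHIN),  # inclusive upper bound
            (10.0, RangeClass.WITHIN),  # inclusive lower bound
            (9.5, RangeClass.BELOW),
        ],
    )
    def test_against_the_iop_normal_range(self, value, expected):
        quantity = Quantity(
            unit=term("UCUM:mm[Hg]"),
            value=value,
            reference_range=ReferenceRange(unit=term("UCUM:mm[Hg]"), low=10.0, high=21.0),
        )
        assert classify_against_range(quantity) is expected

    def test_no_range(self):
        assert classify_against_range(Quantity(value=25.0)) is RangeClass.NO_RANGE


class TestProfiles:
    def test_fixture_passes_rare_disease_and_cancer_profiles(self, retinoblastoma):
        assert validate_profile(retinoblastoma, PROFILES["rare-disease"]) == []
        assert validate_profile(retinoblastoma, PROFILES["cancer"]) == []

    def test_feature_prefix_restriction(self):
        doc = Phenopacket(
            id="x", meta_data=META, phenotypic_features=(PhenotypicFeature(type=term("NCIT:C35941")),)
        )
        issues = validate_profile(doc, PROFILES["rare-disease"])
        assert [i.rule_id for i in issues] == ["feature-prefix-not-allowed"]

    def test_biosample_requirement(self, minimal_phenopacket):
        issues = validate_profile(minimal_phenopacket, PROFILES["cancer"])
        assert [i.rule_id for i in issues] == ["missing-biosample"]

    def test_subject_age_requirement(self, minimal_phenopacket):
        profile = Profile(name="ages", require_subject_age=True)
        assert [i.rule_id for i in validate_profile(minimal_phenopacket, profile)] == ["missing-subject-age"]

    def test_profile_loaded_from_yaml(self):
        profile = load_profile(
            "name: custom\nrequiredPrefixes:\n  phenotypicFeatures: [HP, NCIT]\nrequireBiosample: true\n"
        )
        assert profile.required_prefixes["phenotypicFeatures"] == ("HP", "NCIT")
        assert profile.require_biosample


def test_aggregate_validate_merges_all_layers(retinoblastoma, minimal_phenopacket):
    assert validate(retinoblastoma) == []
    assert validate(minimal_phenopacket) == []
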