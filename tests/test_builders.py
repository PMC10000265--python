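"""The worked-example fixture, the summarizer, and the synthetic generator."""

import pytest

from phenokit import (
    AcmgPathogenicityClassification,
    DocumentFormat,
    KaryotypicSex,
    Sex,
    SyntheticConfig,
    build_example_family,
    build_retinoblastoma_example,
    generate_synthetic,
    summarize,
    validate,
    write_document,
)
from phenokit.builders import BREAK_RULES
from phenokit.core_model import Severity


class TestRetinoblastomaFixture:
    """The fixture must carry the case report's printed values verbatim."""

    def test_zero_validation_errors(self, retinoblastoma):
        assert validate(retinoblastoma) == []

    def test_subject_demographics(self, retinoblastoma):
        subject = retinoblastoma.subject
        assert subject.id == "proband A"
        assert subject.sex is Sex.FEMALE
        assert subject.karyotypic_sex is KaryotypicSex.XX
        assert subject.time_at_last_encounter.age == "P6M"

    def test_four_features_with_their_onsets(self, retinoblastoma):
        onsets = {f.type.label: f.onset.age for f in retinoblastoma.phenotypic_features}
        assert onsets == {
            "Clinodactyly of the 5th finger": "P3M",
            "Leukocoria": "P4M",
            "Strabismus": "P5M15D",
            "Retinal detachment": "P6M",
        }

    def test_intraocular_pressures_and_reference_range(self, retinoblastoma):
        left, right = retinoblastoma.measurements
        assert left.quantity.value == 25.0
        assert right.quantity.value == 15.0
        for m in (left, right):
            rr = m.quantity.reference_range
            assert (rr.low, rr.high) == (10.0, 21.0)
            assert rr.unit.id == "UCUM:mm[Hg]"

    def test_biosample_histology_and_staging(self, retinoblastoma):
        (biosample,) = retinoblastoma.biosamples
        labels = {f.type.label for f in biosample.phenotypic_features}
        assert labels == {"Flexner-Wintersteiner Rosette Formation", "Apoptosis and Necrosis"}
        assert biosample.pathological_tnm_finding[0].id == "NCIT:C140720"
        assert biosample.procedure.code.label == "Enucleation"
        assert biosample.measurements[0].quantity.value == 14.0  # maximal tumor dimension, mm

    def test_mosaic_deletion_interpretation(self, retinoblastoma):
        gi = retinoblastoma.interpretations[0].diagnosis.genomic_interpretations[0]
        assert gi.subject_or_biosample_id == "proband A"
        cn = gi.variant_interpretation.variation_descriptor.copy_number
        assert cn.sequence_id == "NC_000013.14"
        assert cn.copies == 1
        names = [e.name for e in gi.variant_interpretation.variation_descriptor.extensions]
        assert "mosaicism" in names

    def test_somatic_rb1_variant(self, retinoblastoma):
        gi = retinoblastoma.interpretations[0].diagnosis.genomic_interpretations[1]
        assert gi.subject_or_biosample_id == retinoblastoma.biosamples[0].id
        vi = gi.variant_interpretation
        assert vi.acmg_pathogenicity_classification is AcmgPathogenicityClassification.PATHOGENIC
        descriptor = vi.variation_descriptor
        vcf = descriptor.vcf_record
        assert (vcf.chrom, vcf.pos, vcf.ref, vcf.alt) == ("13", 48941648, "C", "T")
        assert descriptor.gene_context.symbol == "RB1"
        assert descriptor.allelic_state.label == "heterozygous"
        assert ("allele-frequency", "25.0%") in [(e.name, e.value) for e in descriptor.extensions]
        # interbase allele agrees with the 1-based VCF position
        assert descriptor.allele.start == vcf.pos - 1

    def test_disease_and_medical_actions(self, retinoblastoma):
        (disease,) = retinoblastoma.diseases
        assert disease.term.label == "Retinoblastoma"
        assert disease.onset.age == "P4M"
        actions = retinoblastoma.medical_actions
        assert actions[0].treatment.agent.label == "Melphalan"
        assert actions[0].adverse_events[0].label == "Vasospasm"
        regimen = actions[1].therapeutic_regimen
        assert (regimen.start_time.age, regimen.end_time.age) == ("P7M", "P8M")
        assert actions[2].procedure.code.label == "Enucleation"

    def test_fixture_round_trips_byte_identically(self, retinoblastoma):
        for fmt in (DocumentFormat.YAML, DocumentFormat.JSON):
            text = write_document(retinoblastoma, fmt)
            assert write_document(build_retinoblastoma_example(), fmt) == text


class TestSummarize:
    def test_fixture_counts(self, retinoblastoma):
        counts = summarize(retinoblastoma)
        assert counts.medical_actions == 3
        assert counts.genomic_interpretations == 2
        assert counts.as_dict() == {
            "phenotypicFeatures": 4,
            "measurements": 2,
            "biosamples": 1,
            "interpretations": 1,
            "diseases": 1,
            "medicalActions": 3,
            "files": 1,
            "genomicInterpretations": 2,
        }

    def test_minimal_counts_all_zero(self, minimal_phenopacket):
        assert all(v == 0 for v in summarize(minimal_phenopacket).as_dict().values())


class TestSyntheticGenerator:
    def test_same_seed_is_byte_identical(self):
        a = write_document(generate_synthetic(SyntheticConfig(seed=42)))
        b = write_document(generate_synthetic(SyntheticConfig(seed=42)))
        assert a == b
        assert a != write_document(generate_synthetic(SyntheticConfig(seed=43)))

    @pytest.mark.parametrize("seed", range(0, 100))
    def test_valid_mode_yields_no_validator_findings(self, seed):
        assert validate(generate_synthetic(SyntheticConfig(seed=seed))) == []

    @pytest.mark.parametrize("rule", BREAK_RULES)
    @pytest.mark.parametrize("seed", [0, 5])
    def test_break_rule_injects_exactly_that_violation(self, rule, seed):
        doc = generate_synthetic(SyntheticConfig(seed=seed, break_rule=rule))
        issues = validate(doc)
        assert len(issues) == 1
        assert issues[0].rule_id == rule

    def test_dangling_reference_mode_is_an_error(self):
        doc = generate_synthetic(SyntheticConfig(seed=1, break_rule="dangling-subject-or-biosample-id"))
        (issue,) = validate(doc)
        assert issue.severity is Severity.ERROR

    def test_counts_respect_configured_ranges(self):
        config = SyntheticConfig(seed=9, phenotypic_features=(2, 3), measurements=(1, 1), biosamples=(1, 2))
        counts = summarize(generate_synthetic(config))
        assert 2 <= counts.phenotypic_features <= 3
        assert counts.measurements == 1
        assert 1 <= counts.biosamples <= 2

    def test_unknown_break_rule_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic(SyntheticConfig(seed=0, break_rule="no-such-rule"))

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=0, measurements=(3, 1))


def test_example_family_is_a_consistent_trio():
    family = build_example_family()
    ids = {p.individual_id for p in family.pedigree.persons}
    assert family.proband.subject.id in ids
    relative_ids = {r.subject.id for r in family.relatives}
    assert ids == relative_ids | {family.proband.subject.id}
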