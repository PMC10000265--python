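"""Construction helpers, the retinoblastoma worked example, a document
summarizer, and a seeded synthetic-document generator.

The worked example (:func:`build_retinoblastoma_example`) encodes the
published case of a 6-month-old girl with retinoblastoma caused by a de
novo mosaic 13q deletion plus a somatic RB1 point mutation. Every value
that the case report prints (ages, pressures, the variant, the staging
terms) is carried verbatim; values the narrative only implies (exact
calendar dates, genomic deletion breakpoints, the mosaicism percentage,
resource release labels) are representative placeholders and are marked
as such where they are set.

The synthetic generator produces arbitrary valid documents from a seed,
or documents carrying exactly one injected rule violation (``break_rule``)
for validator calibration.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .core_model import (
    AcmgPathogenicityClassification,
    AffectedStatus,
    AgeRange,
    Allele,
    Biosample,
    CopyNumber,
    Diagnosis,
    Disease,
    DoseInterval,
    Expression,
    ExpressionSyntax,
    Extension,
    Family,
    File,
    GeneDescriptor,
    GenomicInterpretation,
    Individual,
    Interpretation,
    InterpretationStatus,
    KaryotypicSex,
    Measurement,
    MedicalAction,
    MetaData,
    MoleculeContext,
    OntologyClass,
    Pedigree,
    Person,
    Phenopacket,
    PhenotypicFeature,
    Procedure,
    ProgressStatus,
    Quantity,
    ReferenceRange,
    RegimenStatus,
    Sex,
    TherapeuticRegimen,
    TimeElement,
    Treatment,
    VariantInterpretation,
    VariationDescriptor,
    VcfRecord,
    VitalState,
    VitalStatus,
)
from .validation import _used_prefixes
from .vocabulary import RESOURCES, term

__all__ = [
    "BREAK_RULES",
    "SummaryCounts",
    "SyntheticConfig",
    "age",
    "auto_metadata",
    "build_example_family",
    "build_retinoblastoma_example",
    "generate_synthetic",
    "generate_synthetic_pedigree",
    "summarize",
]


def age(iso_duration: str) -> TimeElement:
    """Shorthand for a TimeElement carrying an ISO-8601 age."""
    return TimeElement(age=iso_duration)


def auto_metadata(
    packet: Phenopacket,
    created: str,
    created_by: str,
    extra_resources: tuple = (),
) -> Phenopacket:
    """Attach a MetaData block declaring exactly the CURIE prefixes the
    document uses (from the packaged resource registry), in prefix order."""
    prefixes = sorted(_used_prefixes(packet))
    resources = tuple(RESOURCES[p] for p in prefixes if p in RESOURCES) + tuple(extra_resources)
    return replace(
        packet,
        meta_data=MetaData(created=created, created_by=created_by, resources=resources),
    )


# --- the retinoblastoma worked example ---------------------------------------

MM_HG = term("UCUM:mm[Hg]")
_IOP_RANGE = ReferenceRange(unit=MM_HG, low=10.0, high=21.0)


def _iop(assay_curie: str, value: float) -> Measurement:
    return Measurement(
        assay=term(assay_curie),
        quantity=Quantity(unit=MM_HG, value=value, reference_range=_IOP_RANGE),
        time_observed=age("P6M"),
    )


def build_retinoblastoma_example() -> Phenopacket:
    """The complete retinoblastoma case as a typed phenopacket.

    Printed case values: proband "proband A", female, karyotype XX, age
    P6M; clinodactyly (P3M), leukocoria (P4M), strabismus (P5M15D) and
    retinal detachment (P6M); intraocular pressure 25 mm Hg left / 15 mm
    Hg right against the 10–21 mm Hg normal range; enucleated left-eye
    tumor with pT3 staging, Flexner–Wintersteiner rosettes, apoptosis and
    necrosis, 14 mm maximal dimension; a solved interpretation with the
    mosaic 13q deletion (copy number 1 on NC_000013.14) and the somatic
    RB1 c.958C>T (p.Arg320Ter) variant at 13:48941648 C>T, allele
    frequency 25%, heterozygous; intra-arterial melphalan terminated for
    vasospasm, a carboplatin/etoposide/vincristine regimen from age P7M
    to P8M, and enucleation.

    Placeholders (not printed in the case report, chosen as representative
    values): deletion breakpoints, mosaicism percentage, calendar dates,
    dose quantities, file URIs and resource versions.
    """
    subject = Individual(
        id="proband A",
        time_at_last_encounter=age("P6M"),
        sex=Sex.FEMALE,
        karyotypic_sex=KaryotypicSex.XX,
    )

    features = (
        PhenotypicFeature(type=term("HP:0004209"), modifiers=(term("HP:0012834"),), onset=age("P3M")),
        PhenotypicFeature(type=term("HP:0000555"), modifiers=(term("HP:0012835"),), onset=age("P4M")),
        PhenotypicFeature(type=term("HP:0000486"), modifiers=(term("HP:0012835"),), onset=age("P5M15D")),
        PhenotypicFeature(type=term("HP:0000541"), modifiers=(term("HP:0012835"),), onset=age("P6M")),
    )

    measurements = (_iop("LOINC:79893-4", 25.0), _iop("LOINC:79892-6", 15.0))

    biosample_id = "biosample.1"
    biosample = Biosample(
        id=biosample_id,
        sampled_tissue=term("UBERON:0000970"),
        phenotypic_features=(
            PhenotypicFeature(type=term("NCIT:C35941")),
            PhenotypicFeature(type=term("NCIT:C132485")),
        ),
        measurements=(
            Measurement(
                assay=term("LOINC:33728-7"),
                quantity=Quantity(unit=term("UCUM:mm"), value=14.0),
            ),
        ),
        tumor_progression=term("NCIT:C8509"),
        pathological_tnm_finding=(term("NCIT:C140720"),),
        procedure=Procedure(
            code=term("NCIT:C48601"),
            body_site=term("UBERON:0004548"),
            performed=age("P8M14D"),  # "a few weeks" after the regimen; placeholder precision
        ),
        files=(
            File(
                uri="file://data/fileSomaticWgs.vcf.gz",
                individual_to_file_identifiers={biosample_id: "specimen.1"},
                file_attributes={"genomeAssembly": "GRCh38", "fileFormat": "VCF"},
            ),
        ),
    )

    # GenomicInterpretation 1: the de novo mosaic 13q deletion found in
    # germline WGS. Breakpoints and mosaicism percentage are placeholders;
    # the chromosome accession and single remaining copy are as published.
    deletion = GenomicInterpretation(
        subject_or_biosample_id="proband A",
        interpretation_status=InterpretationStatus.CAUSATIVE,
        variant_interpretation=VariantInterpretation(
            acmg_pathogenicity_classification=AcmgPathogenicityClassification.PATHOGENIC,
            variation_descriptor=VariationDescriptor(
                id="variation.descriptor.13q.deletion",
                copy_number=CopyNumber(
                    sequence_id="NC_000013.14",
                    start=25981249,
                    end=61706822,
                    copies=1,
                ),
                molecule_context=MoleculeContext.GENOMIC,
                extensions=(Extension(name="mosaicism", value="40.0%"),),
            ),
        ),
    )

    # GenomicInterpretation 2: the somatic RB1 "second hit" from the tumor
    # sample, in interbase coordinates alongside its 1-based VCF rendering.
    somatic_snv = GenomicInterpretation(
        subject_or_biosample_id=biosample_id,
        interpretation_status=InterpretationStatus.CAUSATIVE,
        variant_interpretation=VariantInterpretation(
            acmg_pathogenicity_classification=AcmgPathogenicityClassification.PATHOGENIC,
            variation_descriptor=VariationDescriptor(
                id="rs121913300",
                allele=Allele(
                    sequence_id="NC_000013.14",
                    start=48941647,
                    end=48941648,
                    state="T",
                ),
                label="RB1 c.958C>T (p.Arg320Ter)",
                gene_context=GeneDescriptor(value_id="HGNC:9884", symbol="RB1"),
                expressions=(
                    Expression(syntax=ExpressionSyntax.HGVS, value="NM_000321.2:c.958C>T"),
                    Expression(syntax=ExpressionSyntax.HGVS, value="NP_000312.2:p.Arg320Ter"),
                ),
                vcf_record=VcfRecord(
                    genome_assembly="GRCh37",
                    chrom="13",
                    pos=48941648,
                    id="rs121913300",
                    ref="C",
                    alt="T",
                ),
                molecule_context=MoleculeContext.GENOMIC,
                allelic_state=term("GENO:0000135"),
                extensions=(Extension(name="allele-frequency", value="25.0%"),),
            ),
        ),
    )

    interpretation = Interpretation(
        id="interpretation.id",
        progress_status=ProgressStatus.SOLVED,
        diagnosis=Diagnosis(
            disease=term("NCIT:C7541"),
            genomic_interpretations=(deletion, somatic_snv),
        ),
    )

    disease = Disease(
        term=term("NCIT:C7541"),
        onset=age("P4M"),  # age of the first sign (leukocoria)
        disease_stage=(
            OntologyClass(id="LOINC:LA24739-7", label="Group E"),
        ),
        clinical_tnm_finding=(term("NCIT:C140678"),),
        primary_site=term("UBERON:0004548"),
    )

    melphalan = MedicalAction(
        treatment=Treatment(
            agent=term("NCIT:C633"),
            route_of_administration=term("NCIT:C38222"),
            dose_intervals=(
                DoseInterval(
                    quantity=Quantity(unit=term("UCUM:mg/kg"), value=0.4),  # placeholder dose
                    interval=age("P6M"),
                ),
            ),
        ),
        treatment_target=term("NCIT:C7541"),
        treatment_intent=term("NCIT:C62220"),
        adverse_events=(term("HP:0025637"),),
        treatment_termination_reason=term("NCIT:C41331"),
    )

    chemo_regimen = MedicalAction(
        therapeutic_regimen=TherapeuticRegimen(
            ontology_class=term("NCIT:C10894"),
            start_time=age("P7M"),
            end_time=age("P8M"),
            regimen_status=RegimenStatus.COMPLETED,
        ),
        treatment_target=term("NCIT:C7541"),
        treatment_intent=term("NCIT:C62220"),
    )

    enucleation = MedicalAction(
        procedure=Procedure(
            code=term("NCIT:C48601"),
            body_site=term("UBERON:0004548"),
            performed=age("P8M14D"),  # placeholder precision, see module docstring
        ),
        treatment_target=term("NCIT:C7541"),
        treatment_intent=term("NCIT:C62220"),
    )

    germline_wgs = File(
        uri="file://data/germlineWgs.vcf.gz",
        individual_to_file_identifiers={"proband A": "sample1"},
        file_attributes={"genomeAssembly": "GRCh38", "fileFormat": "VCF"},
    )

    packet = Phenopacket(
        id="arbitrary.id",
        subject=subject,
        phenotypic_features=features,
        measurements=measurements,
        biosamples=(biosample,),
        interpretations=(interpretation,),
        diseases=(disease,),
        medical_actions=(melphalan, chemo_regimen, enucleation),
        files=(germline_wgs,),
    )
    return auto_metadata(packet, created="2021-05-14T10:35:00Z", created_by="anonymous biocurator")


def build_example_family() -> Family:
    """A trio Family around the retinoblastoma proband (parents are
    minimal, unaffected phenopackets; the pedigree carries the links)."""
    proband = build_retinoblastoma_example()
    meta = MetaData(created="2021-05-14T10:35:00Z", created_by="anonymous biocurator")
    father = Phenopacket(id="family.1.father", subject=Individual(id="father A", sex=Sex.MALE), meta_data=meta)
    mother = Phenopacket(id="family.1.mother", subject=Individual(id="mother A", sex=Sex.FEMALE), meta_data=meta)
    pedigree = Pedigree(
        persons=(
            Person(family_id="family.1", individual_id="father A", sex=Sex.MALE,
                   affected_status=AffectedStatus.UNAFFECTED),
            Person(family_id="family.1", individual_id="mother A", sex=Sex.FEMALE,
                   affected_status=AffectedStatus.UNAFFECTED),
            Person(family_id="family.1", individual_id="proband A", paternal_id="father A",
                   maternal_id="mother A", sex=Sex.FEMALE, affected_status=AffectedStatus.AFFECTED),
        )
    )
    return Family(
        id="family.1",
        proband=proband,
        relatives=(father, mother),
        pedigree=pedigree,
        meta_data=meta,
    )


# --- summarizer --------------------------------------------------------------


@dataclass(frozen=True)
class SummaryCounts:
    """Per-document counts of each top-level list field, plus genomic
    interpretations summed across interpretations."""

    phenotypic_features: int = 0
    measurements: int = 0
    biosamples: int = 0
    interpretations: int = 0
    diseases: int = 0
    medical_actions: int = 0
    files: int = 0
    genomic_interpretations: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "phenotypicFeatures": self.phenotypic_features,
            "measurements": self.measurements,
            "biosamples": self.biosamples,
            "interpretations": self.interpretations,
            "diseases": self.diseases,
            "medicalActions": self.medical_actions,
            "files": self.files,
            "genomicInterpretations": self.genomic_interpretations,
        }


def summarize(doc: Phenopacket) -> SummaryCounts:
    """Exact lengths of every top-level list field."""
    return SummaryCounts(
        phenotypic_features=len(doc.phenotypic_features),
        measurements=len(doc.measurements),
        biosamples=len(doc.biosamples),
        interpretations=len(doc.interpretations),
        diseases=len(doc.diseases),
        medical_actions=len(doc.medical_actions),
        files=len(doc.files),
        genomic_interpretations=sum(
            len(i.diagnosis.genomic_interpretations) if i.diagnosis is not None else 0
            for i in doc.interpretations
        ),
    )


# --- synthetic generator -----------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings: a seed, per-field count ranges (inclusive), and
    an optional rule id to violate exactly once."""

    seed: int = 0
    phenotypic_features: tuple[int, int] = (1, 4)
    measurements: tuple[int, int] = (1, 3)
    biosamples: tuple[int, int] = (0, 2)
    interpretations: tuple[int, int] = (0, 2)
    diseases: tuple[int, int] = (0, 2)
    medical_actions: tuple[int, int] = (0, 2)
    files: tuple[int, int] = (0, 1)
    break_rule: Optional[str] = None

    def __post_init__(self) -> None:
        for name in (
            "phenotypic_features",
            "measurements",
            "biosamples",
            "interpretations",
            "diseases",
            "medical_actions",
            "files",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} range must satisfy 0 <= low <= high, got ({lo}, {hi})")


_FEATURE_POOL = ("HP:0000486", "HP:0000541", "HP:0000555", "HP:0001250", "HP:0001433", "HP:0012587")
_MEASUREMENT_POOL = (
    ("LOINC:79893-4", "UCUM:mm[Hg]", 10.0, 21.0),
    ("LOINC:79892-6", "UCUM:mm[Hg]", 10.0, 21.0),
    ("LOINC:26515-7", "UCUM:10*3/uL", 150.0, 450.0),
)
_TISSUE_POOL = ("UBERON:0000970", "UBERON:0002107", "UBERON:0004548")
_DISEASE_POOL = ("NCIT:C7541", "NCIT:C3058")


def _random_age(rng: random.Random) -> TimeElement:
    years = rng.randrange(0, 80)
    months = rng.randrange(0, 12)
    return age(f"P{years}Y{months}M" if months else f"P{years}Y")


def _count(rng: random.Random, bounds: tuple[int, int], minimum: int = 0) -> int:
    return max(rng.randint(*bounds), minimum)


#: break_rule id → minimum element counts the mutation needs in place.
_BREAK_REQUIREMENTS: dict[str, dict[str, int]] = {
    "required-id": {},
    "required-metadata": {},
    "curie-syntax": {"phenotypic_features": 2},
    "malformed-duration": {},
    "age-range-order": {},
    "range-order": {"measurements": 1},
    "vital-status": {},
    "dangling-subject-or-biosample-id": {"interpretations": 1},
    "biosample-individual-mismatch": {"biosamples": 1},
    "undeclared-prefix": {"phenotypic_features": 1},
    "unused-resource": {},
    "file-identifier-unresolved": {"files": 1},
}


def _break(doc: Phenopacket, rule: str, rng: random.Random) -> Phenopacket:
    if rule == "required-id":
        return replace(doc, id="")
    if rule == "required-metadata":
        return replace(doc, meta_data=None)
    if rule == "curie-syntax":
        broken = replace(doc.phenotypic_features[0], type=OntologyClass(id="strabismus", label="Strabismus"))
        return replace(doc, phenotypic_features=(broken,) + doc.phenotypic_features[1:])
    if rule == "malformed-duration":
        subject = replace(doc.subject, time_at_last_encounter=age("P6W"))
        return replace(doc, subject=subject)
    if rule == "age-range-order":
        subject = replace(
            doc.subject,
            time_at_last_encounter=TimeElement(age_range=AgeRange(start="P6M", end="P3M")),
        )
        return replace(doc, subject=subject)
    if rule == "range-order":
        first = doc.measurements[0]
        rr = first.quantity.reference_range
        swapped = replace(first.quantity, reference_range=replace(rr, low=rr.high, high=rr.low))
        return replace(doc, measurements=(replace(first, quantity=swapped),) + doc.measurements[1:])
    if rule == "vital-status":
        subject = replace(
            doc.subject,
            vital_status=VitalStatus(status=VitalState.ALIVE, survival_time_in_days=30),
        )
        return replace(doc, subject=subject)
    if rule == "dangling-subject-or-biosample-id":
        interp = doc.interpretations[0]
        gi = replace(interp.diagnosis.genomic_interpretations[0], subject_or_biosample_id="no-such-id")
        diagnosis = replace(
            interp.diagnosis,
            genomic_interpretations=(gi,) + interp.diagnosis.genomic_interpretations[1:],
        )
        return replace(
            doc, interpretations=(replace(interp, diagnosis=diagnosis),) + doc.interpretations[1:]
        )
    if rule == "biosample-individual-mismatch":
        biosample = replace(doc.biosamples[0], individual_id=doc.subject.id + "-mismatch")
        return replace(doc, biosamples=(biosample,) + doc.biosamples[1:])
    if rule == "undeclared-prefix":
        meta = doc.meta_data
        kept = tuple(r for r in meta.resources if r.namespace_prefix != "HP")
        return replace(doc, meta_data=replace(meta, resources=kept))
    if rule == "unused-resource":
        meta = doc.meta_data
        return replace(doc, meta_data=replace(meta, resources=meta.resources + (RESOURCES["CHEBI"],)))
    if rule == "file-identifier-unresolved":
        broken = replace(doc.files[0], individual_to_file_identifiers={"ghost-sample": "s1"})
        return replace(doc, files=(broken,) + doc.files[1:])
    raise ValueError(f"unknown break rule {rule!r}; known: {sorted(_BREAK_REQUIREMENTS)}")


#: Public registry of injectable rule violations.
BREAK_RULES: tuple[str, ...] = tuple(sorted(_BREAK_REQUIREMENTS))


def generate_synthetic(config: SyntheticConfig) -> Phenopacket:
    """Deterministically generate one phenopacket from a seed.

    In valid mode the result passes all validators with zero issues; with
    ``break_rule`` set, it fails exactly that rule (one ERROR, or one
    WARNING for the warning-severity rules).
    """
    rng = random.Random(config.seed)
    need = _BREAK_REQUIREMENTS.get(config.break_rule, {}) if config.break_rule else {}
    if config.break_rule and config.break_rule not in _BREAK_REQUIREMENTS:
        raise ValueError(f"unknown break rule {config.break_rule!r}; known: {sorted(_BREAK_REQUIREMENTS)}")

    subject_id = f"individual-{rng.randrange(10**6)}"
    subject = Individual(
        id=subject_id,
        time_at_last_encounter=_random_age(rng),
        sex=rng.choice((Sex.FEMALE, Sex.MALE, Sex.UNKNOWN_SEX)),
    )

    features = tuple(
        PhenotypicFeature(
            type=term(rng.choice(_FEATURE_POOL)),
            excluded=rng.random() < 0.2,
            onset=_random_age(rng) if rng.random() < 0.7 else None,
        )
        for _ in range(_count(rng, config.phenotypic_features, need.get("phenotypic_features", 0)))
    )

    measurements = []
    for _ in range(_count(rng, config.measurements, need.get("measurements", 0))):
        assay, unit, low, high = rng.choice(_MEASUREMENT_POOL)
        measurements.append(
            Measurement(
                assay=term(assay),
                quantity=Quantity(
                    unit=term(unit),
                    value=round(rng.uniform(low * 0.8, high * 1.2), 1),
                    reference_range=ReferenceRange(unit=term(unit), low=low, high=high),
                ),
            )
        )

    biosamples = tuple(
        Biosample(
            id=f"biosample-{i}",
            individual_id=subject_id,
            sampled_tissue=term(rng.choice(_TISSUE_POOL)),
            procedure=Procedure(code=term("NCIT:C48601")),
        )
        for i in range(_count(rng, config.biosamples, need.get("biosamples", 0)))
    )

    interpretations = []
    for i in range(_count(rng, config.interpretations, need.get("interpretations", 0))):
        anchor = rng.choice([subject_id] + [b.id for b in biosamples])
        call = GenomicInterpretation(
            subject_or_biosample_id=anchor,
            interpretation_status=rng.choice(
                (InterpretationStatus.CANDIDATE, InterpretationStatus.CAUSATIVE)
            ),
            gene_descriptor=GeneDescriptor(value_id="HGNC:9884", symbol="RB1"),
        )
        interpretations.append(
            Interpretation(
                id=f"interpretation-{i}",
                progress_status=rng.choice((ProgressStatus.SOLVED, ProgressStatus.IN_PROGRESS)),
                diagnosis=Diagnosis(disease=term(rng.choice(_DISEASE_POOL)), genomic_interpretations=(call,)),
            )
        )

    diseases = tuple(
        Disease(term=term(rng.choice(_DISEASE_POOL)), onset=_random_age(rng))
        for _ in range(_count(rng, config.diseases, need.get("diseases", 0)))
    )

    medical_actions = []
    for _ in range(_count(rng, config.medical_actions, need.get("medical_actions", 0))):
        if rng.random() < 0.5:
            medical_actions.append(
                MedicalAction(procedure=Procedure(code=term("NCIT:C48601"), performed=_random_age(rng)))
            )
        else:
            medical_actions.append(
                MedicalAction(
                    treatment=Treatment(agent=term("NCIT:C633"), route_of_administration=term("NCIT:C38222"))
                )
            )

    files = tuple(
        File(
            uri=f"file://data/sample-{rng.randrange(10**4)}.vcf.gz",
            individual_to_file_identifiers={subject_id: f"sample{rng.randrange(100)}"},
            file_attributes={"genomeAssembly": "GRCh38", "fileFormat": "VCF"},
        )
        for _ in range(_count(rng, config.files, need.get("files", 0)))
    )

    packet = Phenopacket(
        id=f"synthetic-{config.seed}",
        subject=subject,
        phenotypic_features=features,
        measurements=tuple(measurements),
        biosamples=biosamples,
        interpretations=tuple(interpretations),
        diseases=diseases,
        medical_actions=tuple(medical_actions),
        files=files,
    )
    packet = auto_metadata(
        packet, created="2022-01-01T00:00:00Z", created_by="phenokit synthetic generator"
    )
    if config.break_rule:
        packet = _break(packet, config.break_rule, rng)
    return packet


def generate_synthetic_pedigree(seed: int, family_id: Optional[str] = None) -> Pedigree:
    """A random nuclear family: two founders plus 1–4 children."""
    rng = random.Random(seed)
    fam = family_id or f"family-{seed}"
    father = Person(
        family_id=fam,
        individual_id=f"{fam}.father",
        sex=Sex.MALE,
        affected_status=rng.choice((AffectedStatus.UNAFFECTED, AffectedStatus.MISSING)),
    )
    mother = Person(
        family_id=fam,
        individual_id=f"{fam}.mother",
        sex=Sex.FEMALE,
        affected_status=rng.choice((AffectedStatus.UNAFFECTED, AffectedStatus.MISSING)),
    )
    children = tuple(
        Person(
            family_id=fam,
            individual_id=f"{fam}.child{i}",
            paternal_id=father.individual_id,
            maternal_id=mother.individual_id,
            sex=rng.choice((Sex.MALE, Sex.FEMALE, Sex.UNKNOWN_SEX)),
            affected_status=rng.choice(
                (AffectedStatus.AFFECTED, AffectedStatus.UNAFFECTED, AffectedStatus.MISSING)
            ),
        )
        for i in range(rng.randint(1, 4))
    )
    return Pedigree(persons=(father, mother) + children)
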