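"""Typed, immutable records for every Phenopacket Schema v2 message.

The schema is a hierarchy of protobuf-style messages; here each message is
a frozen dataclass. Construction enforces the *hard* contracts of the
schema — ``oneof`` groups (at most / exactly one member populated),
declared enum values only, non-negative coordinates — and raises
:class:`InvariantError` naming the violated rule. Softer, reportable rules
(CURIE grammar, duration grammar, required-but-empty identifiers,
reference-range ordering, vital-status coherence) are deliberately *not*
enforced here: a document carrying such defects must remain representable
so the validator (:mod:`phenokit.validation`) can describe every defect at
its document path instead of dying on the first one.

Conventions:

* list fields are stored as tuples (inputs may be any sequence);
* "not set" is ``None``, never an empty sentinel message;
* enum wire names are the UPPER_SNAKE protobuf names (``moleculeContext``
  uses the lowercase VRSATILE vocabulary).
"""

from __future__ import annotations

import dataclasses
import re
import typing
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Any, Mapping, Optional

__all__ = [
    "AcmgPathogenicityClassification",
    "AffectedStatus",
    "AgeRange",
    "Allele",
    "Biosample",
    "Cohort",
    "CopyNumber",
    "Diagnosis",
    "Disease",
    "DoseInterval",
    "DrugType",
    "Expression",
    "ExpressionSyntax",
    "Extension",
    "ExternalReference",
    "Family",
    "File",
    "GeneDescriptor",
    "GenomicInterpretation",
    "GestationalAge",
    "Individual",
    "Interpretation",
    "InterpretationStatus",
    "InvariantError",
    "KaryotypicSex",
    "Measurement",
    "MedicalAction",
    "Message",
    "MetaData",
    "MoleculeContext",
    "OntologyClass",
    "Pedigree",
    "Person",
    "Phenopacket",
    "PhenotypicFeature",
    "Procedure",
    "ProgressStatus",
    "Quantity",
    "RadiationTherapy",
    "ReferenceRange",
    "RegimenStatus",
    "Resource",
    "Severity",
    "Sex",
    "TherapeuticRegimen",
    "TimeElement",
    "TimeInterval",
    "Treatment",
    "ValidationIssue",
    "VariantInterpretation",
    "VariationDescriptor",
    "VcfRecord",
    "VitalState",
    "VitalStatus",
    "is_curie",
    "split_curie",
]


class InvariantError(ValueError):
    """A construction-time contract violation, with the offending path."""

    def __init__(self, path: str, message: str) -> None:
        self.path = path
        self.message = message
        super().__init__(f"{path}: {message}" if path else message)


# --- CURIE grammar -----------------------------------------------------------
# A CURIE splits at the FIRST colon; the prefix must look like an ontology
# namespace, the local code is opaque but non-empty.

_CURIE_PREFIX_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.-]*$")


def split_curie(identifier: str) -> Optional[tuple[str, str]]:
    """Split ``PREFIX:code`` at the first colon; None if not CURIE-shaped."""
    if not isinstance(identifier, str) or ":" not in identifier:
        return None
    prefix, code = identifier.split(":", 1)
    if not code or not _CURIE_PREFIX_RE.match(prefix):
        return None
    return prefix, code


def is_curie(identifier: str) -> bool:
    return split_curie(identifier) is not None


# --- enums -------------------------------------------------------------------


class Sex(Enum):
    UNKNOWN_SEX = "UNKNOWN_SEX"
    FEMALE = "FEMALE"
    MALE = "MALE"
    OTHER_SEX = "OTHER_SEX"


class KaryotypicSex(Enum):
    UNKNOWN_KARYOTYPE = "UNKNOWN_KARYOTYPE"
    XX = "XX"
    XY = "XY"
    XO = "XO"
    XXY = "XXY"
    XXX = "XXX"
    XXYY = "XXYY"
    XXXY = "XXXY"
    XXXX = "XXXX"
    XYY = "XYY"
    OTHER_KARYOTYPE = "OTHER_KARYOTYPE"


class VitalState(Enum):
    UNKNOWN_STATUS = "UNKNOWN_STATUS"
    ALIVE = "ALIVE"
    DECEASED = "DECEASED"


class AcmgPathogenicityClassification(Enum):
    NOT_PROVIDED = "NOT_PROVIDED"
    BENIGN = "BENIGN"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    UNCERTAIN_SIGNIFICANCE = "UNCERTAIN_SIGNIFICANCE"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    PATHOGENIC = "PATHOGENIC"


class InterpretationStatus(Enum):
    UNKNOWN_STATUS = "UNKNOWN_STATUS"
    REJECTED = "REJECTED"
    CANDIDATE = "CANDIDATE"
    CONTRIBUTORY = "CONTRIBUTORY"
    CAUSATIVE = "CAUSATIVE"


class ProgressStatus(Enum):
    UNKNOWN_PROGRESS = "UNKNOWN_PROGRESS"
    IN_PROGRESS = "IN_PROGRESS"
    COMPLETED = "COMPLETED"
    SOLVED = "SOLVED"
    UNSOLVED = "UNSOLVED"


class ExpressionSyntax(Enum):
    HGVS = "hgvs"
    SPDI = "spdi"
    ISCN = "iscn"


class MoleculeContext(Enum):
    UNSPECIFIED = "unspecified_molecule_context"
    GENOMIC = "genomic"
    TRANSCRIPT = "transcript"
    PROTEIN = "protein"


class DrugType(Enum):
    UNKNOWN_DRUG_TYPE = "UNKNOWN_DRUG_TYPE"
    PRESCRIPTION = "PRESCRIPTION"
    EHR_MEDICATION_LIST = "EHR_MEDICATION_LIST"
    ADMINISTRATION_RELATED_TO_PROCEDURE = "ADMINISTRATION_RELATED_TO_PROCEDURE"


class RegimenStatus(Enum):
    UNKNOWN_STATUS = "UNKNOWN_STATUS"
    STARTED = "STARTED"
    COMPLETED = "COMPLETED"
    DISCONTINUED = "DISCONTINUED"


class AffectedStatus(Enum):
    MISSING = "MISSING"
    UNAFFECTED = "UNAFFECTED"
    AFFECTED = "AFFECTED"


class Severity(Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


# --- message machinery -------------------------------------------------------


@lru_cache(maxsize=None)
def field_hints(cls: type) -> dict[str, Any]:
    """Resolved type hints for a message class (cached)."""
    return typing.get_type_hints(cls)


@lru_cache(maxsize=None)
def _enum_fields(cls: type) -> tuple[tuple[str, type], ...]:
    out = []
    for f in dataclasses.fields(cls):
        hint = field_hints(cls).get(f.name)
        for candidate in _unwrap_optional(hint):
            if isinstance(candidate, type) and issubclass(candidate, Enum):
                out.append((f.name, candidate))
    return tuple(out)


def _unwrap_optional(hint: Any) -> tuple[Any, ...]:
    if typing.get_origin(hint) is typing.Union:
        return tuple(a for a in typing.get_args(hint) if a is not type(None))
    return (hint,)


class Message:
    """Base for all schema messages: tuple-ifies lists, checks oneofs/enums."""

    #: (group name, member field names, required) triples
    _ONEOFS: tuple[tuple[str, tuple[str, ...], bool], ...] = ()

    def __post_init__(self) -> None:
        cls = type(self)
        for f in dataclasses.fields(self):  # type: ignore[arg-type]
            value = getattr(self, f.name)
            if isinstance(value, list):
                object.__setattr__(self, f.name, tuple(value))
        for name, enum_cls in _enum_fields(cls):
            value = getattr(self, name)
            if value is not None and not isinstance(value, enum_cls):
                raise InvariantError(
                    name,
                    f"expected {enum_cls.__name__} member, got {value!r}; "
                    f"allowed: {', '.join(m.value for m in enum_cls)}",
                )
        for group, members, required in cls._ONEOFS:
            populated = [m for m in members if getattr(self, m) is not None]
            if len(populated) > 1:
                raise InvariantError(group, f"at most one of {members} may be set, got {tuple(populated)}")
            if required and not populated:
                raise InvariantError(group, f"exactly one of {members} must be set")
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - default no-op
        pass

    def replace(self, **changes: Any) -> "Message":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)  # type: ignore[type-var]


def _require_non_negative(owner: str, **values: Any) -> None:
    for name, value in values.items():
        if isinstance(value, bool) or not isinstance(value, int):
            raise InvariantError(f"{owner}.{name}", f"must be an integer, got {value!r}")
        if value < 0:
            raise InvariantError(f"{owner}.{name}", f"must be non-negative, got {value}")


# --- ontology & time ---------------------------------------------------------


@dataclass(frozen=True)
class OntologyClass(Message):
    """A CURIE-identified ontology term with a human-readable label.

    The atom of every coded field in the schema. CURIE well-formedness is a
    validator concern, not a construction error.
    """

    id: str
    label: str = ""


@dataclass(frozen=True)
class GestationalAge(Message):
    """Age of a fetus in completed weeks (+ days) of gestation."""

    weeks: int = 0
    days: int = 0

    def _validate(self) -> None:
        _require_non_negative("GestationalAge", weeks=self.weeks, days=self.days)


@dataclass(frozen=True)
class AgeRange(Message):
    """A privacy-preserving age bracket: two ISO-8601 duration strings."""

    start: str = ""
    end: str = ""


@dataclass(frozen=True)
class TimeInterval(Message):
    """Two RFC-3339 instants bounding a period."""

    start: str = ""
    end: str = ""


@dataclass(frozen=True)
class TimeElement(Message):
    """Tagged union over the schema's time representations.

    Exactly one of ``age`` (ISO-8601 duration), ``age_range``,
    ``gestational_age``, ``timestamp`` (RFC-3339), ``interval`` or
    ``ontology_class`` (e.g. an onset term) is populated.
    """

    age: Optional[str] = None
    age_range: Optional[AgeRange] = None
    gestational_age: Optional[GestationalAge] = None
    timestamp: Optional[str] = None
    interval: Optional[TimeInterval] = None
    ontology_class: Optional[OntologyClass] = None

    _ONEOFS = (
        (
            "time",
            ("age", "age_range", "gestational_age", "timestamp", "interval", "ontology_class"),
            True,
        ),
    )


# --- individual --------------------------------------------------------------


@dataclass(frozen=True)
class VitalStatus(Message):
    """Alive/deceased status; death detail fields belong with DECEASED only
    (a validator rule, so defective records stay reportable)."""

    status: VitalState = VitalState.UNKNOWN_STATUS
    time_of_death: Optional[TimeElement] = None
    cause_of_death: Optional[OntologyClass] = None
    survival_time_in_days: Optional[int] = None

    def _validate(self) -> None:
        if self.survival_time_in_days is not None:
            _require_non_negative("VitalStatus", survival_time_in_days=self.survival_time_in_days)


@dataclass(frozen=True)
class Individual(Message):
    """The subject of a phenopacket (patient, proband or control)."""

    id: str = ""
    alternate_ids: tuple[str, ...] = ()
    date_of_birth: Optional[str] = None
    time_at_last_encounter: Optional[TimeElement] = None
    vital_status: Optional[VitalStatus] = None
    sex: Sex = Sex.UNKNOWN_SEX
    gender: Optional[OntologyClass] = None
    karyotypic_sex: KaryotypicSex = KaryotypicSex.UNKNOWN_KARYOTYPE


# --- phenotype & measurement -------------------------------------------------


@dataclass(frozen=True)
class PhenotypicFeature(Message):
    """One phenotypic observation (sign, symptom, lab/imaging finding).

    ``excluded=True`` records that the abnormality was ruled out during
    workup — an assertion of absence, not missing data.
    """

    type: Optional[OntologyClass] = None
    excluded: bool = False
    description: str = ""
    severity: Optional[OntologyClass] = None
    modifiers: tuple[OntologyClass, ...] = ()
    onset: Optional[TimeElement] = None
    resolution: Optional[TimeElement] = None


@dataclass(frozen=True)
class ReferenceRange(Message):
    """The normal interval for a quantity, in the same unit. Bounds are
    inclusive; low ≤ high is a validator rule."""

    unit: Optional[OntologyClass] = None
    low: float = 0.0
    high: float = 0.0


@dataclass(frozen=True)
class Quantity(Message):
    """A value with an ontology-coded unit, optionally with normal range."""

    unit: Optional[OntologyClass] = None
    value: float = 0.0
    reference_range: Optional[ReferenceRange] = None

    def _validate(self) -> None:
        if not isinstance(self.value, (int, float)) or isinstance(self.value, bool):
            raise InvariantError("Quantity.value", f"must be a number, got {self.value!r}")
        if self.value != self.value or self.value in (float("inf"), float("-inf")):
            raise InvariantError("Quantity.value", "must be finite")


@dataclass(frozen=True)
class Procedure(Message):
    """A clinical procedure (e.g. a surgical intervention or a biopsy)."""

    code: Optional[OntologyClass] = None
    body_site: Optional[OntologyClass] = None
    performed: Optional[TimeElement] = None


@dataclass(frozen=True)
class Measurement(Message):
    """A quantitative, ordinal or categorical measurement.

    The value is exactly one of a :class:`Quantity` or an
    :class:`OntologyClass` (for ordinal/categorical results).
    """

    description: str = ""
    assay: Optional[OntologyClass] = None
    quantity: Optional[Quantity] = None
    ontology_class: Optional[OntologyClass] = None
    time_observed: Optional[TimeElement] = None
    procedure: Optional[Procedure] = None

    _ONEOFS = (("value", ("quantity", "ontology_class"), True),)


# --- biosample ---------------------------------------------------------------


@dataclass(frozen=True)
class File(Message):
    """A pointer to a data file (e.g. a VCF from genome sequencing)."""

    uri: str = ""
    individual_to_file_identifiers: Mapping[str, str] = field(default_factory=dict)
    file_attributes: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Biosample(Message):
    """A biological specimen and its examination (histology, measurements,
    pathological TNM staging, attached sequencing files).

    ``id`` anchors cross-references from genomic interpretations.
    """

    id: str = ""
    individual_id: Optional[str] = None
    sampled_tissue: Optional[OntologyClass] = None
    phenotypic_features: tuple[PhenotypicFeature, ...] = ()
    measurements: tuple[Measurement, ...] = ()
    tumor_progression: Optional[OntologyClass] = None
    pathological_tnm_finding: tuple[OntologyClass, ...] = ()
    procedure: Optional[Procedure] = None
    files: tuple[File, ...] = ()


# --- disease -----------------------------------------------------------------


@dataclass(frozen=True)
class Disease(Message):
    """A clinical diagnosis with stage, clinical TNM, onset, primary site."""

    term: Optional[OntologyClass] = None
    excluded: bool = False
    onset: Optional[TimeElement] = None
    disease_stage: tuple[OntologyClass, ...] = ()
    clinical_tnm_finding: tuple[OntologyClass, ...] = ()
    primary_site: Optional[OntologyClass] = None


# --- variation (VRS / VRSATILE subset) ---------------------------------------


@dataclass(frozen=True)
class GeneDescriptor(Message):
    """A gene reference: nomenclature CURIE (e.g. ``HGNC:9884``) + symbol."""

    value_id: str = ""
    symbol: str = ""


@dataclass(frozen=True)
class Allele(Message):
    """A sequence allele in interbase (0-based, half-open) coordinates.

    The coordinate convention matches VRS; it is *not* the 1-based VCF
    convention, and the two are never auto-converted.
    """

    sequence_id: str = ""
    start: int = 0
    end: int = 0
    state: str = ""

    def _validate(self) -> None:
        _require_non_negative("Allele", start=self.start, end=self.end)
        if self.start > self.end:
            raise InvariantError("Allele", f"start ({self.start}) must be <= end ({self.end})")
        if not self.state:
            raise InvariantError("Allele.state", "must be a non-empty nucleotide string")


@dataclass(frozen=True)
class CopyNumber(Message):
    """A copy-number change over an interbase interval (e.g. copies=1 for a
    heterozygous deletion)."""

    sequence_id: str = ""
    start: int = 0
    end: int = 0
    copies: int = 0

    def _validate(self) -> None:
        _require_non_negative("CopyNumber", start=self.start, end=self.end, copies=self.copies)
        if self.start > self.end:
            raise InvariantError("CopyNumber", f"start ({self.start}) must be <= end ({self.end})")


@dataclass(frozen=True)
class VcfRecord(Message):
    """The VCF (1-based) rendering of a variant, kept alongside the
    interbase representation for interoperability."""

    genome_assembly: str = ""
    chrom: str = ""
    pos: int = 1
    id: str = ""
    ref: str = ""
    alt: str = ""

    def _validate(self) -> None:
        if isinstance(self.pos, bool) or not isinstance(self.pos, int) or self.pos < 1:
            raise InvariantError("VcfRecord.pos", f"must be a positive 1-based integer, got {self.pos!r}")
        if not self.ref or not self.alt:
            raise InvariantError("VcfRecord", "ref and alt must be non-empty")


@dataclass(frozen=True)
class Expression(Message):
    """A nomenclature rendering of a variant (HGVS, SPDI or ISCN)."""

    syntax: ExpressionSyntax = ExpressionSyntax.HGVS
    value: str = ""


@dataclass(frozen=True)
class Extension(Message):
    """A free-form name/value annotation (e.g. degree of mosaicism)."""

    name: str = ""
    value: str = ""

    def _validate(self) -> None:
        if not self.name:
            raise InvariantError("Extension.name", "must be non-empty")


@dataclass(frozen=True)
class VariationDescriptor(Message):
    """VRSATILE descriptor: a computable variation (allele or copy number)
    joined with human-readable context (HGVS label, gene, VCF record,
    zygosity, extensions)."""

    id: str = ""
    allele: Optional[Allele] = None
    copy_number: Optional[CopyNumber] = None
    label: str = ""
    gene_context: Optional[GeneDescriptor] = None
    expressions: tuple[Expression, ...] = ()
    vcf_record: Optional[VcfRecord] = None
    molecule_context: MoleculeContext = MoleculeContext.UNSPECIFIED
    allelic_state: Optional[OntologyClass] = None
    extensions: tuple[Extension, ...] = ()

    _ONEOFS = (("variation", ("allele", "copy_number"), False),)


@dataclass(frozen=True)
class VariantInterpretation(Message):
    """A variant plus its ACMG pathogenicity assertion."""

    acmg_pathogenicity_classification: AcmgPathogenicityClassification = (
        AcmgPathogenicityClassification.NOT_PROVIDED
    )
    variation_descriptor: Optional[VariationDescriptor] = None


@dataclass(frozen=True)
class GenomicInterpretation(Message):
    """One genomic finding, tied to the subject or to a biosample by id.

    ``subject_or_biosample_id`` must match the phenopacket subject's id or
    one of its biosample ids — checked by the cross-reference validator.
    """

    subject_or_biosample_id: str = ""
    interpretation_status: InterpretationStatus = InterpretationStatus.UNKNOWN_STATUS
    gene_descriptor: Optional[GeneDescriptor] = None
    variant_interpretation: Optional[VariantInterpretation] = None

    _ONEOFS = (("call", ("gene_descriptor", "variant_interpretation"), True),)


@dataclass(frozen=True)
class Diagnosis(Message):
    """The single disease an interpretation refers to, with its supporting
    genomic findings."""

    disease: Optional[OntologyClass] = None
    genomic_interpretations: tuple[GenomicInterpretation, ...] = ()


@dataclass(frozen=True)
class Interpretation(Message):
    """The clinical interpretation of a genomic investigation."""

    id: str = ""
    progress_status: ProgressStatus = ProgressStatus.UNKNOWN_PROGRESS
    diagnosis: Optional[Diagnosis] = None
    summary: str = ""


# --- medical actions ---------------------------------------------------------


@dataclass(frozen=True)
class DoseInterval(Message):
    """One dosing block: amount, schedule frequency, time interval."""

    quantity: Optional[Quantity] = None
    schedule_frequency: Optional[OntologyClass] = None
    interval: Optional[TimeElement] = None


@dataclass(frozen=True)
class Treatment(Message):
    """Administration of a pharmaceutical agent."""

    agent: Optional[OntologyClass] = None
    route_of_administration: Optional[OntologyClass] = None
    dose_intervals: tuple[DoseInterval, ...] = ()
    drug_type: DrugType = DrugType.UNKNOWN_DRUG_TYPE


@dataclass(frozen=True)
class ExternalReference(Message):
    """A pointer into an external registry or publication."""

    id: str = ""
    reference: str = ""
    description: str = ""


@dataclass(frozen=True)
class TherapeuticRegimen(Message):
    """A named multi-agent treatment protocol and its execution status."""

    ontology_class: Optional[OntologyClass] = None
    external_reference: Optional[ExternalReference] = None
    start_time: Optional[TimeElement] = None
    end_time: Optional[TimeElement] = None
    regimen_status: RegimenStatus = RegimenStatus.UNKNOWN_STATUS

    _ONEOFS = (("identifier", ("ontology_class", "external_reference"), True),)


@dataclass(frozen=True)
class RadiationTherapy(Message):
    """Radiation treatment: modality, target site, total dose (cGy) and
    fraction count. Included for schema completeness; the worked example
    does not exercise it."""

    modality: Optional[OntologyClass] = None
    body_site: Optional[OntologyClass] = None
    dosage: int = 1
    fractions: int = 1

    def _validate(self) -> None:
        for name, value in (("dosage", self.dosage), ("fractions", self.fractions)):
            if isinstance(value, bool) or not isinstance(value, int) or value < 1:
                raise InvariantError(f"RadiationTherapy.{name}", f"must be a positive integer, got {value!r}")


@dataclass(frozen=True)
class MedicalAction(Message):
    """One action taken for clinical management; exactly one of procedure,
    treatment, radiation therapy or therapeutic regimen."""

    procedure: Optional[Procedure] = None
    treatment: Optional[Treatment] = None
    radiation_therapy: Optional[RadiationTherapy] = None
    therapeutic_regimen: Optional[TherapeuticRegimen] = None
    treatment_target: Optional[OntologyClass] = None
    treatment_intent: Optional[OntologyClass] = None
    response_to_treatment: Optional[OntologyClass] = None
    adverse_events: tuple[OntologyClass, ...] = ()
    treatment_termination_reason: Optional[OntologyClass] = None

    _ONEOFS = (
        ("action", ("procedure", "treatment", "radiation_therapy", "therapeutic_regimen"), True),
    )


# --- metadata ----------------------------------------------------------------


@dataclass(frozen=True)
class Resource(Message):
    """One ontology/terminology used in the document, with its version and
    the namespace prefix it contributes (e.g. ``HP``)."""

    id: str = ""
    name: str = ""
    url: str = ""
    version: str = ""
    namespace_prefix: str = ""
    iri_prefix: str = ""


@dataclass(frozen=True)
class MetaData(Message):
    """Provenance: creation time/curator, the resources behind every CURIE
    prefix in the document, and the schema version."""

    created: Optional[str] = None
    created_by: str = ""
    submitted_by: str = ""
    resources: tuple[Resource, ...] = ()
    phenopacket_schema_version: str = "2.0"
    external_references: tuple[ExternalReference, ...] = ()


# --- top-level documents -----------------------------------------------------


@dataclass(frozen=True)
class Phenopacket(Message):
    """The top-level case document: required ``id`` and ``meta_data``, eight
    optional content fields."""

    id: str
    subject: Optional[Individual] = None
    phenotypic_features: tuple[PhenotypicFeature, ...] = ()
    measurements: tuple[Measurement, ...] = ()
    biosamples: tuple[Biosample, ...] = ()
    interpretations: tuple[Interpretation, ...] = ()
    diseases: tuple[Disease, ...] = ()
    medical_actions: tuple[MedicalAction, ...] = ()
    files: tuple[File, ...] = ()
    meta_data: Optional[MetaData] = None


@dataclass(frozen=True)
class Person(Message):
    """One row of a PED pedigree."""

    family_id: str = ""
    individual_id: str = ""
    paternal_id: str = "0"
    maternal_id: str = "0"
    sex: Sex = Sex.UNKNOWN_SEX
    affected_status: AffectedStatus = AffectedStatus.MISSING


@dataclass(frozen=True)
class Pedigree(Message):
    """A PED-compatible pedigree: the family relationships of each sample."""

    persons: tuple[Person, ...] = ()


@dataclass(frozen=True)
class Family(Message):
    """A proband phenopacket, phenopackets for relatives, and the pedigree
    tying them together."""

    id: str
    proband: Optional[Phenopacket] = None
    relatives: tuple[Phenopacket, ...] = ()
    pedigree: Optional[Pedigree] = None
    files: tuple[File, ...] = ()
    meta_data: Optional[MetaData] = None


@dataclass(frozen=True)
class Cohort(Message):
    """A group of phenopackets related in some phenotypic or genotypic
    aspect."""

    id: str
    description: str = ""
    members: tuple[Phenopacket, ...] = ()
    files: tuple[File, ...] = ()
    meta_data: Optional[MetaData] = None


# --- validator finding -------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue(Message):
    """One validator finding: severity, rule id, document path, message."""

    severity: Severity = Severity.ERROR
    rule_id: str = ""
    path: str = ""
    message: str = ""

    def _validate(self) -> None:
        if not self.rule_id or not self.message:
            raise InvariantError("ValidationIssue", "rule_id and message must be non-empty")

    def __str__(self) -> str:
        return f"{self.severity.value} [{self.rule_id}] {self.path or '/'}: {self.message}"
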