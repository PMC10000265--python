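"""Structural, cross-reference and metadata validation of phenopackets.

Three independent layers, each a pure function from a hydrated document to
a list of :class:`ValidationIssue` (never exceptions — a well-formed but
invalid document is data to report on, not an error to die on):

* :func:`validate_structure` — required fields, CURIE grammar, duration
  and timestamp grammar, range ordering, vital-status coherence;
* :func:`validate_crossrefs` — every ``subjectOrBiosampleId`` must resolve
  to the subject or a biosample; biosample/individual and file identifier
  links are checked likewise;
* :func:`validate_metadata` — every CURIE prefix used anywhere in the
  document needs a declared :class:`Resource` (case-sensitive match on
  ``namespacePrefix``); a declared but unused resource is a warning.

A :class:`Profile` layers consortium-specific constraints on top (allowed
term prefixes per field, biosample required, subject age required).

Issue lists are sorted by document path, so equal documents always produce
identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

import yaml

from . import time_elements as te
from .core_model import (
    AgeRange,
    Biosample,
    File,
    GeneDescriptor,
    Individual,
    MetaData,
    Message,
    OntologyClass,
    Phenopacket,
    Quantity,
    ReferenceRange,
    Severity,
    TimeElement,
    TimeInterval,
    ValidationIssue,
    VitalState,
    VitalStatus,
    is_curie,
    split_curie,
)
from .serialization import _wire_names_cached

__all__ = [
    "PROFILES",
    "Profile",
    "RangeClass",
    "classify_against_range",
    "format_issues_text",
    "issues_to_json_lines",
    "iter_messages",
    "load_profile",
    "validate",
    "validate_crossrefs",
    "validate_metadata",
    "validate_profile",
    "validate_structure",
]


# --- generic document walk ---------------------------------------------------


def iter_messages(doc: Message, path: str = "") -> Iterator[tuple[str, Message]]:
    """Depth-first walk yielding (document path, message) for every message."""
    yield path, doc
    cls = type(doc)
    wires = _wire_names_cached(cls)
    for f in dataclasses.fields(doc):  # type: ignore[arg-type]
        value = getattr(doc, f.name)
        sub_path = f"{path}/{wires[f.name]}"
        if isinstance(value, Message):
            yield from iter_messages(value, sub_path)
        elif isinstance(value, tuple):
            for i, item in enumerate(value):
                if isinstance(item, Message):
                    yield from iter_messages(item, f"{sub_path}/{i}")


def _sorted(issues: Sequence[ValidationIssue]) -> list[ValidationIssue]:
    return sorted(issues, key=lambda i: (i.path, i.rule_id, i.severity.value, i.message))


def _error(rule: str, path: str, message: str) -> ValidationIssue:
    return ValidationIssue(severity=Severity.ERROR, rule_id=rule, path=path, message=message)


def _warning(rule: str, path: str, message: str) -> ValidationIssue:
    return ValidationIssue(severity=Severity.WARNING, rule_id=rule, path=path, message=message)


# --- layer 1: structure ------------------------------------------------------


def _check_duration(text: str, path: str, issues: list) -> None:
    try:
        te.parse_duration(text)
    except te.DurationError as exc:
        issues.append(_error("malformed-duration", path, exc.reason + f" in {text!r}"))


def _check_timestamp(text: str, path: str, issues: list) -> None:
    try:
        te.parse_timestamp(text)
    except te.TimestampError as exc:
        issues.append(_error("malformed-timestamp", path, exc.reason + f" in {text!r}"))


def validate_structure(doc: Phenopacket) -> list[ValidationIssue]:
    """Check required fields and the grammar of every coded/time value."""
    issues: list[ValidationIssue] = []
    if not doc.id:
        issues.append(_error("required-id", "/id", "phenopacket id must be a non-empty string"))
    if doc.meta_data is None:
        issues.append(_error("required-metadata", "/metaData", "metaData is required"))
    if doc.subject is not None and not doc.subject.id:
        issues.append(_error("required-id", "/subject/id", "the subject of a phenopacket needs a non-empty id"))
    for i, biosample in enumerate(doc.biosamples):
        if not biosample.id:
            issues.append(
                _error(
                    "required-id",
                    f"/biosamples/{i}/id",
                    "biosample id must be non-empty (it anchors cross-references)",
                )
            )
    for path, msg in iter_messages(doc):
        if isinstance(msg, OntologyClass) and not is_curie(msg.id):
            issues.append(
                _error(
                    "curie-syntax",
                    f"{path}/id",
                    f"{msg.id!r} is not a CURIE (expected PREFIX:code with prefix [A-Za-z][A-Za-z0-9_.-]*)",
                )
            )
        elif isinstance(msg, GeneDescriptor) and msg.value_id and not is_curie(msg.value_id):
            issues.append(
                _error("curie-syntax", f"{path}/valueId", f"{msg.value_id!r} is not a CURIE gene identifier")
            )
        elif isinstance(msg, TimeElement):
            if msg.age is not None:
                _check_duration(msg.age, f"{path}/age", issues)
        elif isinstance(msg, AgeRange):
            bounds = []
            for bound in ("start", "end"):
                try:
                    bounds.append(te.parse_duration(getattr(msg, bound)))
                except te.DurationError as exc:
                    issues.append(_error("malformed-duration", f"{path}/{bound}", exc.reason))
            if len(bounds) == 2 and te.compare_durations(bounds[0], bounds[1]) is te.Ordering.GREATER:
                issues.append(
                    _error("age-range-order", path, f"ageRange start {msg.start!r} exceeds end {msg.end!r}")
                )
        elif isinstance(msg, TimeInterval):
            instants = []
            for bound in ("start", "end"):
                try:
                    instants.append(te.parse_timestamp(getattr(msg, bound)))
                except te.TimestampError as exc:
                    issues.append(_error("malformed-timestamp", f"{path}/{bound}", exc.reason))
            if len(instants) == 2 and instants[0] > instants[1]:
                issues.append(
                    _error("interval-order", path, f"interval start {msg.start!r} exceeds end {msg.end!r}")
                )
        elif isinstance(msg, Individual) and msg.date_of_birth is not None:
            _check_timestamp(msg.date_of_birth, f"{path}/dateOfBirth", issues)
        elif isinstance(msg, MetaData):
            if msg.created is not None:
                _check_timestamp(msg.created, f"{path}/created", issues)
            else:
                issues.append(_error("required-created", f"{path}/created", "metaData.created is required"))
        elif isinstance(msg, ReferenceRange) and msg.low > msg.high:
            issues.append(
                _error("range-order", path, f"referenceRange low ({msg.low}) exceeds high ({msg.high})")
            )
        elif isinstance(msg, VitalStatus) and msg.status is not VitalState.DECEASED:
            for wire, value in (
                ("timeOfDeath", msg.time_of_death),
                ("causeOfDeath", msg.cause_of_death),
                ("survivalTimeInDays", msg.survival_time_in_days),
            ):
                if value is not None:
                    issues.append(
                        _error(
                            "vital-status",
                            f"{path}/{wire}",
                            f"{wire} may only be set when status is DECEASED (status is {msg.status.value})",
                        )
                    )
    return _sorted(issues)


# --- layer 2: cross-references -----------------------------------------------


def validate_crossrefs(doc: Phenopacket) -> list[ValidationIssue]:
    """Check that identifier references resolve within the document."""
    issues: list[ValidationIssue] = []
    subject_id = doc.subject.id if doc.subject is not None else None
    biosample_ids = {b.id for b in doc.biosamples if b.id}
    known = ({subject_id} if subject_id else set()) | biosample_ids

    for i, interp in enumerate(doc.interpretations):
        if interp.diagnosis is None:
            continue
        for j, gi in enumerate(interp.diagnosis.genomic_interpretations):
            ref = gi.subject_or_biosample_id
            if ref not in known:
                issues.append(
                    _error(
                        "dangling-subject-or-biosample-id",
                        f"/interpretations/{i}/diagnosis/genomicInterpretations/{j}/subjectOrBiosampleId",
                        f"{ref!r} matches neither the subject id nor any biosample id",
                    )
                )
    for i, biosample in enumerate(doc.biosamples):
        if biosample.individual_id is not None and subject_id and biosample.individual_id != subject_id:
            issues.append(
                _error(
                    "biosample-individual-mismatch",
                    f"/biosamples/{i}/individualId",
                    f"biosample individualId {biosample.individual_id!r} differs from subject id {subject_id!r}",
                )
            )

    def check_file(file: File, path: str) -> None:
        for key in sorted(file.individual_to_file_identifiers):
            if key not in known:
                issues.append(
                    _warning(
                        "file-identifier-unresolved",
                        f"{path}/individualToFileIdentifiers",
                        f"identifier {key!r} resolves to no subject or biosample id",
                    )
                )

    for i, file in enumerate(doc.files):
        check_file(file, f"/files/{i}")
    for i, biosample in enumerate(doc.biosamples):
        for j, file in enumerate(biosample.files):
            check_file(file, f"/biosamples/{i}/files/{j}")
    return _sorted(issues)


# --- layer 3: metadata completeness ------------------------------------------


def _used_prefixes(doc: Phenopacket) -> dict[str, str]:
    """CURIE prefixes used anywhere in the document → path of first use."""
    first_use: dict[str, str] = {}
    for path, msg in iter_messages(doc):
        identifier = None
        if isinstance(msg, OntologyClass):
            identifier, sub = msg.id, "id"
        elif isinstance(msg, GeneDescriptor) and msg.value_id:
            identifier, sub = msg.value_id, "valueId"
        if identifier is None:
            continue
        parts = split_curie(identifier)
        if parts is not None:
            first_use.setdefault(parts[0], f"{path}/{sub}")
    return first_use


def validate_metadata(doc: Phenopacket) -> list[ValidationIssue]:
    """Every used CURIE prefix must be declared as a Resource; unused
    declared resources are warnings.

    With no metaData at all, completeness is not assessable: the missing
    block is reported once by the structural layer rather than once per
    prefix here.
    """
    if doc.meta_data is None:
        return []
    issues: list[ValidationIssue] = []
    used = _used_prefixes(doc)
    resources = doc.meta_data.resources
    declared = {r.namespace_prefix for r in resources if r.namespace_prefix}
    for prefix in sorted(used):
        if prefix not in declared:
            issues.append(
                _error(
                    "undeclared-prefix",
                    used[prefix],
                    f"prefix {prefix!r} is used but no Resource declares it in metaData",
                )
            )
    for i, resource in enumerate(resources):
        if resource.namespace_prefix and resource.namespace_prefix not in used:
            issues.append(
                _warning(
                    "unused-resource",
                    f"/metaData/resources/{i}",
                    f"resource {resource.id!r} (prefix {resource.namespace_prefix!r}) is declared but never used",
                )
            )
    return _sorted(issues)


# --- reference-range classification ------------------------------------------


class RangeClass(Enum):
    BELOW = "BELOW"
    WITHIN = "WITHIN"
    ABOVE = "ABOVE"
    NO_RANGE = "NO_RANGE"


def classify_against_range(quantity: Quantity) -> RangeClass:
    """Place a measured value against its reference range (inclusive bounds).

    25 mm Hg against the normal intraocular pressure range of 10–21 mm Hg
    classifies as ABOVE; 15 and the boundary value 21 are WITHIN.
    """
    rr = quantity.reference_range
    if rr is None:
        return RangeClass.NO_RANGE
    if quantity.value < rr.low:
        return RangeClass.BELOW
    if quantity.value > rr.high:
        return RangeClass.ABOVE
    return RangeClass.WITHIN


# --- profiles ----------------------------------------------------------------


@dataclass(frozen=True)
class Profile:
    """Consortium-specific constraints layered over the base validators.

    ``required_prefixes`` maps a top-level field name (``phenotypicFeatures``
    or ``diseases``) to the CURIE prefixes its terms may use.
    """

    name: str
    required_prefixes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    require_biosample: bool = False
    require_subject_age: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("profile name must be non-empty")
        object.__setattr__(
            self,
            "required_prefixes",
            {k: tuple(v) for k, v in dict(self.required_prefixes).items()},
        )


#: A rare-disease consortium profile (HPO terms for features) and a cancer
#: profile (a tumor biosample is mandatory), as canonical examples.
PROFILES: dict[str, Profile] = {
    "rare-disease": Profile(name="rare-disease", required_prefixes={"phenotypicFeatures": ("HP",)}),
    "cancer": Profile(name="cancer", require_biosample=True),
}


def load_profile(text: str) -> Profile:
    """Build a profile from a YAML/JSON mapping (name, requiredPrefixes,
    requireBiosample, requireSubjectAge)."""
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or not data.get("name"):
        raise ValueError("profile document must be a mapping with a non-empty 'name'")
    return Profile(
        name=data["name"],
        required_prefixes={k: tuple(v) for k, v in data.get("requiredPrefixes", {}).items()},
        require_biosample=bool(data.get("requireBiosample", False)),
        require_subject_age=bool(data.get("requireSubjectAge", False)),
    )


def validate_profile(doc: Phenopacket, profile: Profile) -> list[ValidationIssue]:
    """Check a document against a profile's constraints."""
    issues: list[ValidationIssue] = []
    allowed_feature = profile.required_prefixes.get("phenotypicFeatures")
    if allowed_feature:
        for i, feature in enumerate(doc.phenotypic_features):
            if feature.type is None:
                continue
            parts = split_curie(feature.type.id)
            if parts is None or parts[0] not in allowed_feature:
                issues.append(
                    _error(
                        "feature-prefix-not-allowed",
                        f"/phenotypicFeatures/{i}/type/id",
                        f"profile {profile.name!r} allows prefixes {allowed_feature} for features, got {feature.type.id!r}",
                    )
                )
    allowed_disease = profile.required_prefixes.get("diseases")
    if allowed_disease:
        for i, disease in enumerate(doc.diseases):
            if disease.term is None:
                continue
            parts = split_curie(disease.term.id)
            if parts is None or parts[0] not in allowed_disease:
                issues.append(
                    _error(
                        "disease-prefix-not-allowed",
                        f"/diseases/{i}/term/id",
                        f"profile {profile.name!r} allows prefixes {allowed_disease} for diseases, got {disease.term.id!r}",
                    )
                )
    if profile.require_biosample and not doc.biosamples:
        issues.append(
            _error(
                "missing-biosample",
                "/biosamples",
                f"profile {profile.name!r} requires at least one biosample",
            )
        )
    if profile.require_subject_age and (doc.subject is None or doc.subject.time_at_last_encounter is None):
        issues.append(
            _error(
                "missing-subject-age",
                "/subject/timeAtLastEncounter",
                f"profile {profile.name!r} requires the subject's age at last encounter",
            )
        )
    return _sorted(issues)


# --- aggregate + reporting ---------------------------------------------------


def validate(doc: Phenopacket, profile: Optional[Profile] = None) -> list[ValidationIssue]:
    """Run all three layers (plus an optional profile) and merge the report."""
    issues = validate_structure(doc) + validate_crossrefs(doc) + validate_metadata(doc)
    if profile is not None:
        issues += validate_profile(doc, profile)
    return _sorted(issues)


def issues_to_json_lines(issues: Sequence[ValidationIssue]) -> str:
    """One JSON object per line, machine-consumable."""
    return "".join(
        json.dumps(
            {
                "severity": issue.severity.value,
                "ruleId": issue.rule_id,
                "path": issue.path,
                "message": issue.message,
            },
            ensure_ascii=False,
        )
        + "\n"
        for issue in issues
    )


def format_issues_text(issues: Sequence[ValidationIssue], source: str = "") -> str:
    """Human-readable report, one line per issue."""
    prefix = f"{source}: " if source else ""
    if not issues:
        return f"{prefix}OK (no issues)\n"
    return "".join(f"{prefix}{issue}\n" for issue in issues)
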