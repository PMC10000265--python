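"""Conversion between Pedigree/Family messages and 6-column PED text.

The pre-makeped linkage PED format carries one person per line:

    familyId  individualId  paternalId  maternalId  sex  affectedStatus

with ``0`` for a founder's parent ids, sex coded 1=male / 2=female /
0=unknown, and affected status 2=affected / 1=unaffected / 0 or -9 =
missing. Output uses single tabs and ``0`` for missing status
(configurable to ``-9``); input tolerates runs of tabs or spaces, ``#``
comment lines, and extra columns (ignored with a warning).
"""

from __future__ import annotations

from typing import Optional

from .core_model import (
    AffectedStatus,
    Family,
    Pedigree,
    Person,
    Severity,
    Sex,
    ValidationIssue,
)

__all__ = ["PedParseError", "family_to_ped", "ped_to_pedigree", "pedigree_to_ped"]


class PedParseError(ValueError):
    """Malformed PED text, naming the offending line number."""

    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"PED line {line_number}: {message}")


_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN_SEX: "0", Sex.OTHER_SEX: "0"}
_CODE_TO_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN_SEX}
_AFFECTED_TO_CODE = {AffectedStatus.AFFECTED: "2", AffectedStatus.UNAFFECTED: "1"}
_CODE_TO_AFFECTED = {
    "2": AffectedStatus.AFFECTED,
    "1": AffectedStatus.UNAFFECTED,
    "0": AffectedStatus.MISSING,
    "-9": AffectedStatus.MISSING,
}


def pedigree_to_ped(pedigree: Pedigree, family_id: str, *, missing_code: str = "0") -> str:
    """Render a pedigree as PED text, one tab-separated line per person in
    input order. ``missing_code`` selects the dialect for MISSING status
    ("0" or "-9")."""
    if missing_code not in ("0", "-9"):
        raise ValueError(f"missing_code must be '0' or '-9', got {missing_code!r}")
    lines = []
    for person in pedigree.persons:
        affected = _AFFECTED_TO_CODE.get(person.affected_status, missing_code)
        lines.append(
            "\t".join(
                (
                    family_id,
                    person.individual_id,
                    person.paternal_id or "0",
                    person.maternal_id or "0",
                    _SEX_TO_CODE[person.sex],
                    affected,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def ped_to_pedigree(text: str, warnings: Optional[list] = None) -> Pedigree:
    """Parse PED text into a Pedigree.

    Raises :class:`PedParseError` (with the line number) for lines with
    fewer than six columns or unrecognized sex/affected codes. Columns
    beyond six are ignored; a WARNING issue is appended to ``warnings``
    per such line if a list is supplied.
    """
    persons = []
    for number, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        columns = line.split()
        if len(columns) < 6:
            raise PedParseError(number, f"expected at least 6 columns, got {len(columns)}")
        if len(columns) > 6 and warnings is not None:
            warnings.append(
                ValidationIssue(
                    severity=Severity.WARNING,
                    rule_id="ped-extra-columns",
                    path=f"line {number}",
                    message=f"{len(columns) - 6} column(s) beyond the sixth ignored",
                )
            )
        family_id, individual_id, paternal_id, maternal_id, sex_code, affected_code = columns[:6]
        if not individual_id or individual_id == "0":
            raise PedParseError(number, f"individual id must be non-empty and not '0', got {individual_id!r}")
        if sex_code not in _CODE_TO_SEX:
            raise PedParseError(number, f"unrecognized sex code {sex_code!r} (expected 0, 1 or 2)")
        if affected_code not in _CODE_TO_AFFECTED:
            raise PedParseError(
                number, f"unrecognized affected-status code {affected_code!r} (expected 2, 1, 0 or -9)"
            )
        persons.append(
            Person(
                family_id=family_id,
                individual_id=individual_id,
                paternal_id=paternal_id,
                maternal_id=maternal_id,
                sex=_CODE_TO_SEX[sex_code],
                affected_status=_CODE_TO_AFFECTED[affected_code],
            )
        )
    return Pedigree(persons=tuple(persons))


def family_to_ped(family: Family) -> tuple[str, list[ValidationIssue]]:
    """Render a Family's pedigree as PED text under the family's id.

    Also checks that every pedigree person has a phenopacket among the
    proband and relatives, returning a WARNING issue per person without
    one (the text is produced regardless).
    """
    issues: list[ValidationIssue] = []
    if family.pedigree is None:
        return "", [
            ValidationIssue(
                severity=Severity.ERROR,
                rule_id="missing-pedigree",
                path="/pedigree",
                message="family has no pedigree to export",
            )
        ]
    packet_subjects = set()
    for packet in (family.proband, *family.relatives):
        if packet is not None and packet.subject is not None and packet.subject.id:
            packet_subjects.add(packet.subject.id)
    for i, person in enumerate(family.pedigree.persons):
        if person.individual_id not in packet_subjects:
            issues.append(
                ValidationIssue(
                    severity=Severity.WARNING,
                    rule_id="pedigree-person-without-phenopacket",
                    path=f"/pedigree/persons/{i}",
                    message=f"pedigree person {person.individual_id!r} has no phenopacket in the family",
                )
            )
    return pedigree_to_ped(family.pedigree, family.id), issues
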