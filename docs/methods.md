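# Methods

## The data model

The Phenopacket Schema v2 is a hierarchy of protobuf-style messages; a
phenopacket has two required fields (`id`, `metaData`) and eight optional
content fields (subject, phenotypicFeatures, measurements, biosamples,
interpretations, diseases, medicalActions, files). phenokit represents
each message as a frozen dataclass and draws a deliberate line between
two kinds of contract:

* **Hard contracts**, enforced at construction and re-checked by
  `dataclasses.replace`: `oneof` groups (a `TimeElement` carries exactly
  one of age / age range / gestational age / timestamp / interval /
  ontology term; a `MedicalAction` exactly one action; a
  `VariationDescriptor` at most one of allele / copy number), enum
  fields accepting only declared members, non-negative interbase
  coordinates with `start ≤ end`, positive 1-based VCF positions.
  Violating these makes an object meaningless, so it cannot exist.
* **Reportable rules**, deliberately *not* enforced at construction:
  CURIE grammar, duration/timestamp grammar, required-but-empty
  identifiers, missing `metaData`, reference-range ordering,
  vital-status coherence. A document that breaks several of these must
  remain representable so the validator can report every defect at its
  document path in one pass, instead of dying at the first constructor.
  This split is what lets the same rule set serve both construction-time
  safety and document-level quality reporting.

Coordinate conventions coexist without conversion: `Allele`/`CopyNumber`
are interbase (0-based, half-open) following VRS; `VcfRecord.pos` is
1-based. Both renderings of the worked example's somatic variant are
stored side by side, and a test asserts `allele.start == vcf.pos - 1`.

"Not set" is always `None`; empty sentinel messages are never created.
A corollary on the wire: a present-but-all-default submessage emits as
`{}` and is therefore dropped, i.e. treated as unset on re-read.

## Serialization

The wire form follows the protobuf JSON mapping: lowerCamelCase keys,
omission of unset optionals, empty lists/maps, empty strings, `false`,
zero numbers and first-member ("default") enum values; enum values as
their wire names; map keys sorted. Output is deterministic — equal
documents produce byte-identical text — which the tests rely on for
round-trip and fixture-file checks. Floats whose value is integral are
emitted as integers (protobuf JSON prints `25`, not `25.0`); hydration
of a float-typed field accepts either, so value equality is preserved.

YAML required two dialect adjustments: the loader drops YAML 1.1
implicit timestamp resolution so `2021-05-14T10:35:00Z` stays a string,
and the dumper quotes any string that a standard resolver would turn
into a non-string scalar, so phenokit YAML is safe for third-party
loaders too.

Unknown input fields are an error by default, naming the path (this
fails loudly on schema-dialect drift). Lenient mode records each unknown
as a WARNING issue and stashes the raw value on the message so it
re-emits verbatim.

Timestamps are canonicalized to RFC-3339 UTC `Z` form with sub-second
digits preserved (trailing zeros trimmed). Naive instants are rejected:
a wire timestamp is an absolute point in time.

## Age durations and their ordering

Ages are ISO-8601 date durations over years/months/days only. Weeks and
time-of-day components are rejected: no clinical age in this schema's
usage needs them, and excluding them keeps the ordering total and
calendar-free. The ordering compares `(12·years + months, days)`
lexicographically: `P1Y` equals `P12M` (exact by definition), but
`P30D < P1M` because converting days to months would require choosing a
calendar. The zero duration canonicalizes to `P0D` (ISO-8601 requires at
least one component). The encoder and parser are exact inverses on
canonical strings, property-tested over a derandomized component grid.

## Validation

Three pure layers, each returning issues sorted by document path (so
reports are reproducible), plus profiles:

| layer | rules |
| --- | --- |
| structure | `required-id`, `required-metadata`, `required-created`, `curie-syntax`, `malformed-duration`, `malformed-timestamp`, `age-range-order`, `interval-order`, `range-order`, `vital-status` |
| cross-references | `dangling-subject-or-biosample-id`, `biosample-individual-mismatch`, `file-identifier-unresolved` (warning) |
| metadata | `undeclared-prefix`, `unused-resource` (warning) |

Decisions with genuine alternatives:

* **Reference-range bounds are inclusive.** The normal intraocular
  pressure range is given as 10–21 mm Hg and 15 is called normal; the
  boundary case is unstated, and inclusivity is the conservative
  clinical reading (a measurement *at* the limit of normal is normal).
* **Prefix matching is case-sensitive** against
  `Resource.namespacePrefix`, mirroring exact-string identifier systems.
* **An unused declared resource is a WARNING**, not an error: it is
  harmless clutter, but worth surfacing because it usually signals a
  stale metadata block.
* **With `metaData` absent entirely, the metadata layer stays silent**:
  completeness is not assessable, and the structural layer already
  reports the missing block once; repeating one error per used prefix
  would be noise proportional to document size.
* CURIEs split at the **first** colon with prefix grammar
  `[A-Za-z][A-Za-z0-9_.-]*`; local codes are opaque (term existence
  against ontology releases is out of scope).
* Severities are fixed per rule so CI behavior is reproducible; multiple
  diseases/interpretations are allowed without comment.

Profiles express consortium conventions: allowed CURIE prefixes per
top-level field (applied to phenotypic features and diseases), a
required biosample, a required subject age. Two built-ins —
`rare-disease` (features must be HP) and `cancer` (biosample required) —
are canonical examples; arbitrary profiles load from YAML/JSON.

## The worked example

`build_retinoblastoma_example()` encodes the published retinoblastoma
case. Every value the case report prints is carried verbatim: proband id
"proband A", female, karyotype XX, age P6M; the four features and their
onsets (P3M, P4M, P5M15D, P6M); intraocular pressures 25/15 mm Hg with
the 10–21 mm Hg range; the enucleated left-eye tumor with pT3 staging
(NCIT:C140720), Flexner–Wintersteiner rosettes, apoptosis/necrosis and
the 14 mm maximal dimension; the mosaic 13q deletion as a CopyNumber on
NC_000013.14 with 1 copy; the somatic *RB1* c.958C>T (p.Arg320Ter) at
13:48941648 C>T with 25% allele frequency, heterozygous, pathogenic by
ACMG; melphalan terminated for vasospasm, the
carboplatin/etoposide/vincristine regimen from age P7M to P8M, and the
enucleation procedure.

Values the narrative implies but does not print are representative
placeholders, marked as such at the point of use and excluded from the
acceptance extraction: deletion breakpoints, the mosaicism percentage
(40%), the melphalan dose (0.4 mg/kg), calendar dates, file URIs,
resource release versions. Two timing choices are the package's own:
disease onset is encoded as the age of the first sign (leukocoria, P4M),
and the enucleation — "a few weeks" after the regimen ended at P8M — is
encoded P8M14D because the age grammar deliberately excludes week
components. The packaged `data/retinoblastoma.{yaml,json}` files are
generated by the builder (code is the single source of truth; a test
asserts byte equality).

## The synthetic generator

`generate_synthetic(SyntheticConfig(seed, ...))` emulates small clinical
case documents: a subject with an age at last encounter, 1–4 HPO-coded
features (with ~70% onset coverage and ~20% excluded findings), 1–3
quantitative measurements with reference ranges, 0–2 biosamples,
interpretations anchored to the subject or a biosample, diseases,
medical actions and files, with a metadata block declaring exactly the
prefixes in use. Counts are uniform over configurable inclusive ranges;
terms come from a packaged mini-vocabulary (HP/NCIT/UBERON/LOINC/UCUM/
GENO/HGNC), so metadata completeness is genuinely exercised. Output is
deterministic per seed down to the byte.

`break_rule` injects exactly one violation of a named validator rule
(twelve modes, from `required-id` to `file-identifier-unresolved`),
first raising element minimums so the mutation has something to mutate.
Valid mode produces zero issues of any severity — that strictness is
what makes "exactly the injected violation is reported" a meaningful
calibration.

What the generator does **not** emulate: longitudinal visit structure,
correlated phenotypes, realistic term co-occurrence, dose regimens,
free-text descriptions, or malformed-but-parseable foreign dialects.
Passing the round-trip and calibration properties therefore shows the
machinery is lossless and the rules are individually detectable — not
that real-world hospital exports will be clean.

## PED interoperability

Output is strict: single tabs, sex coded 1/2/0, affected status 2/1 and
MISSING as `0` (switchable to `-9`, the other common dialect); persons
in input order. Input is tolerant: runs of tabs/spaces, `#` comments,
`-9`, and extra columns (ignored with a warning). `OTHER_SEX` has no PED
code and is written as 0 — the one documented lossy mapping; within the
codes PED can express, the mapping is a bijection, and round-trip
identity holds on generator pedigrees. `family_to_ped` additionally
warns for each pedigree person with no phenopacket among proband and
relatives.

## Problem sizes and runtime

The acceptance script and test suite use 200 synthetic documents for
serialization round-trips, 100 random pedigrees for PED round-trips, and
5 seeds per injectable violation — sizes at which every property is
exercised across all generator branches while the whole suite stays
interactive (seconds, not minutes). The worked-example
build–serialize–reparse–extract cycle completes in well under a second.

## Known limitations

* Ontology terms are opaque CURIEs: no existence, obsolescence or
  hierarchy checks against ontology releases.
* The binary protobuf wire format, RDF and SQL renderings are not
  implemented; JSON and YAML are the interchange forms.
* `RadiationTherapy` and the gestational-age time variant are modeled
  minimally and are not exercised by the worked example.
* Date arithmetic between birth date and encounter timestamps is
  intentionally absent (deriving precise ages from shared documents is a
  privacy hazard).
* The GA4GH Pedigree standard (beyond PED compatibility), Beacon
  integration and downstream prioritization tooling are out of scope.
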