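# phenokit

A self-contained Python implementation of the GA4GH **Phenopacket Schema
v2** — the standard for exchanging structured disease and phenotype
information about one individual: demographic data, ontology-coded
phenotypic features, clinical measurements with reference ranges,
biosamples with histology and TNM staging, genomic interpretations
(VRSATILE variation/gene descriptors down to alleles, copy numbers and
VCF records), diseases, medical actions, files and provenance metadata.

It is written for people who build or consume phenopackets in rare-disease
and cancer genomics pipelines: curators assembling case reports, tool
authors who need a typed model with honest validation, and consortia that
want to enforce local conventions (e.g. "phenotypic features must be HPO
terms", "every document needs a tumor biosample") on incoming documents.

What the package provides:

* **Typed model** (`phenokit.core_model`) — every schema message as an
  immutable dataclass; `oneof` groups, declared enum vocabularies and
  coordinate contracts (interbase for alleles/copy numbers, 1-based for
  VCF records — never auto-converted) are enforced at construction.
* **Serialization** (`phenokit.serialization`) — lossless, deterministic
  JSON and YAML using the protobuf JSON mapping (lowerCamelCase keys,
  default-value omission, UPPER_SNAKE enum names); strict unknown-field
  rejection with a lenient mode that preserves unknowns for re-emission.
* **Validation** (`phenokit.validation`) — three pure layers returning
  issue lists, never exceptions: structural rules (required id/metaData,
  CURIE grammar `PREFIX:code`, ISO-8601/RFC-3339 grammar, range and
  vital-status coherence), cross-references (`subjectOrBiosampleId` must
  resolve to the subject or a biosample), and metadata completeness
  (every CURIE prefix used anywhere must have a declared `Resource`).
  Plus reference-range classification (BELOW/WITHIN/ABOVE, inclusive
  bounds) and configurable consortium profiles.
* **Age utilities** (`phenokit.time_elements`) — canonical ISO-8601 age
  durations (`P42Y7M13D`), parsing with precise errors, and a
  calendar-free ordering (1 y ≡ 12 mo; days never promote to months).
* **PED interop** (`phenokit.ped_interop`) — round-trip conversion
  between `Family`/`Pedigree` messages and 6-column linkage PED text.
* **Builders** (`phenokit.builders`) — fluent helpers, a seeded synthetic
  document generator (valid mode, or exactly one injected rule violation
  for validator calibration), and the published retinoblastoma case
  report as an executable fixture.
* **CLI** (`phenokit`) — `validate`, `convert`, `summarize`, `example`,
  `generate`, `ped`, with stable exit codes (0 clean, 1 validation
  errors, 2 I/O or parse failure).

## Worked example

The package ships the published case of a 6-month-old girl with
retinoblastoma caused by a de novo mosaic 13q deletion plus a somatic
*RB1* second hit, as a builder (`build_retinoblastoma_example`) and as
packaged YAML/JSON (`phenokit/data/retinoblastoma.{yaml,json}`):

```python
>>> import phenokit as pk
>>> doc = pk.build_retinoblastoma_example()
>>> len(pk.validate(doc))          # structure + crossrefs + metadata
0
>>> pk.summarize(doc).as_dict()
{'phenotypicFeatures': 4, 'measurements': 2, 'biosamples': 1,
 'interpretations': 1, 'diseases': 1, 'medicalActions': 3, 'files': 1,
 'genomicInterpretations': 2}
>>> left = doc.measurements[0]     # intraocular pressure, affected eye
>>> left.quantity.value, pk.classify_against_range(left.quantity).value
(25.0, 'ABOVE')
```

The four phenotypic features carry their onsets (clinodactyly P3M,
leukocoria P4M, strabismus P5M15D, retinal detachment P6M); the left-eye
pressure of 25 mm Hg classifies ABOVE the 10–21 mm Hg normal range while
the right eye's 15 mm Hg is WITHIN it; the solved interpretation holds
the mosaic 13q deletion (copy number 1 on NC_000013.14) and the somatic
*RB1* c.958C>T variant (13:48941648 C>T, heterozygous, allele frequency
25%). The same document is available from the shell:

```sh
phenokit example --format yaml | phenokit validate --format yaml -   # exit 0
```

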