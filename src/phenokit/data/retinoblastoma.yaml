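id: arbitrary.id
subject:
  id: proband A
  timeAtLastEncounter:
    age: P6M
  sex: FEMALE
  karyotypicSex: XX
phenotypicFeatures:
- type:
    id: HP:0004209
    label: Clinodactyly of the 5th finger
  modifiers:
  - id: HP:0012834
    label: Right
  onset:
    age: P3M
- type:
    id: HP:0000555
    label: Leukocoria
  modifiers:
  - id: HP:0012835
    label: Left
  onset:
    age: P4M
- type:
    id: HP:0000486
    label: Strabismus
  modifiers:
  - id: HP:0012835
    label: Left
  onset:
    age: P5M15D
- type:
    id: HP:0000541
    label: Retinal detachment
  modifiers:
  - id: HP:0012835
    label: Left
  onset:
    age: P6M
measurements:
- assay:
    id: LOINC:79893-4
    label: Left eye Intraocular pressure
  quantity:
    unit:
      id: UCUM:mm[Hg]
      label: millimetres of mercury
    value: 25
    referenceRange:
      unit:
        id: UCUM:mm[Hg]
        label: millimetres of mercury
      low: 10
      high: 21
  timeObserved:
    age: P6M
- assay:
    id: LOINC:79892-6
    label: Right eye Intraocular pressure
  quantity:
    unit:
      id: UCUM:mm[Hg]
      label: millimetres of mercury
    value: 15
    referenceRange:
      unit:
        id: UCUM:mm[Hg]
        label: millimetres of mercury
      low: 10
      high: 21
  timeObserved:
    age: P6M
biosamples:
- id: biosample.1
  sampledTissue:
    id: UBERON:0000970
    label: eye
  phenotypicFeatures:
  - type:
      id: NCIT:C35941
      label: Flexner-Wintersteiner Rosette Formation
  - type:
      id: NCIT:C132485
      label: Apoptosis and Necrosis
  measurements:
  - assay:
      id: LOINC:33728-7
      label: Size.maximal dimension
    quantity:
      unit:
        id: UCUM:mm
        label: millimeter
      value: 14
  tumorProgression:
    id: NCIT:C8509
    label: Primary Neoplasm
  pathologicalTnmFinding:
  - id: NCIT:C140720
    label: Retinoblastoma pT3 TNM Finding v8
  procedure:
    code:
      id: NCIT:C48601
      label: Enucleation
    bodySite:
      id: UBERON:0004548
      label: left eye
    performed:
      age: P8M14D
  files:
  - uri: file://data/fileSomaticWgs.vcf.gz
    individualToFileIdentifiers:
      biosample.1: specimen.1
    fileAttributes:
      fileFormat: VCF
      genomeAssembly: GRCh38
interpretations:
- id: interpretation.id
  progressStatus: SOLVED
  diagnosis:
    disease:
      id: NCIT:C7541
      label: Retinoblastoma
    genomicInterpretations:
    - subjectOrBiosampleId: proband A
      interpretationStatus: CAUSATIVE
      variantInterpretation:
        acmgPathogenicityClassification: PATHOGENIC
        variationDescriptor:
          id: variation.descriptor.13q.deletion
          copyNumber:
            sequenceId: NC_000013.14
            start: 25981249
            end: 61706822
            copies: 1
          moleculeContext: genomic
          extensions:
          - name: mosaicism
            value: 40.0%
    - subjectOrBiosampleId: biosample.1
      interpretationStatus: CAUSATIVE
      variantInterpretation:
        acmgPathogenicityClassification: PATHOGENIC
        variationDescriptor:
          id: rs121913300
          allele:
            sequenceId: NC_000013.14
            start: 48941647
            end: 48941648
            state: T
          label: RB1 c.958C>T (p.Arg320Ter)
          geneContext:
            valueId: HGNC:9884
            symbol: RB1
          expressions:
          - value: NM_000321.2:c.958C>T
          - value: NP_000312.2:p.Arg320Ter
          vcfRecord:
            genomeAssembly: GRCh37
            chrom: '13'
            pos: 48941648
            id: rs121913300
            ref: C
            alt: T
          moleculeContext: genomic
          allelicState:
            id: GENO:0000135
            label: heterozygous
          extensions:
          - name: allele-frequency
            value: 25.0%
diseases:
- term:
    id: NCIT:C7541
    label: Retinoblastoma
  onset:
    age: P4M
  diseaseStage:
  - id: LOINC:LA24739-7
    label: Group E
  clinicalTnmFinding:
  - id: NCIT:C140678
    label: Retinoblastoma cM0 TNM Finding v8
  primarySite:
    id: UBERON:0004548
    label: left eye
medicalActions:
- treatment:
    agent:
      id: NCIT:C633
      label: Melphalan
    routeOfAdministration:
      id: NCIT:C38222
      label: Intraarterial Route of Administration
    doseIntervals:
    - quantity:
        unit:
          id: UCUM:mg/kg
          label: milligram per kilogram
        value: 0.4
      interval:
        age: P6M
  treatmentTarget:
    id: NCIT:C7541
    label: Retinoblastoma
  treatmentIntent:
    id: NCIT:C62220
    label: Cure
  adverseEvents:
  - id: HP:0025637
    label: Vasospasm
  treatmentTerminationReason:
    id: NCIT:C41331
    label: Adverse Event
- therapeuticRegimen:
    ontologyClass:
      id: NCIT:C10894
      label: Carboplatin/Etoposide/Vincristine
    startTime:
      age: P7M
    endTime:
      age: P8M
    regimenStatus: COMPLETED
  treatmentTarget:
    id: NCIT:C7541
    label: Retinoblastoma
  treatmentIntent:
    id: NCIT:C62220
    label: Cure
- procedure:
    code:
      id: NCIT:C48601
      label: Enucleation
    bodySite:
      id: UBERON:0004548
      label: left eye
    performed:
      age: P8M14D
  treatmentTarget:
    id: NCIT:C7541
    label: Retinoblastoma
  treatmentIntent:
    id: NCIT:C62220
    label: Cure
files:
- uri: file://data/germlineWgs.vcf.gz
  individualToFileIdentifiers:
    proband A: sample1
  fileAttributes:
    fileFormat: VCF
    genomeAssembly: GRCh38
metaData:
  created: '2021-05-14T10:35:00Z'
  createdBy: anonymous biocurator
  resources:
  - id: geno
    name: Genotype Ontology
    url: http://purl.obolibrary.org/obo/geno.owl
    version: '2022-03-05'
    namespacePrefix: GENO
    iriPrefix: http://purl.obolibrary.org/obo/GENO_
  - id: hgnc
    name: HUGO Gene Nomenclature Committee
    url: https://www.genenames.org
    version: '2022-06-01'
    namespacePrefix: HGNC
    iriPrefix: https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/
  - id: hp
    name: human phenotype ontology
    url: http://purl.obolibrary.org/obo/hp.owl
    version: '2022-06-11'
    namespacePrefix: HP
    iriPrefix: http://purl.obolibrary.org/obo/HP_
  - id: loinc
    name: Logical Observation Identifiers Names and Codes
    url: https://loinc.org
    version: '2.72'
    namespacePrefix: LOINC
    iriPrefix: https://loinc.org/
  - id: ncit
    name: NCI Thesaurus
    url: http://purl.obolibrary.org/obo/ncit.owl
    version: 22.03d
    namespacePrefix: NCIT
    iriPrefix: http://purl.obolibrary.org/obo/NCIT_
  - id: uberon
    name: Uber-anatomy ontology
    url: http://purl.obolibrary.org/obo/uberon.owl
    version: '2022-04-18'
    namespacePrefix: UBERON
    iriPrefix: http://purl.obolibrary.org/obo/UBERON_
  - id: ucum
    name: Unified Code for Units of Measure
    url: https://units-of-measure.org
    version: '2.1'
    namespacePrefix: UCUM
    iriPrefix: https://units-of-measure.org/
  phenopacketSchemaVersion: '2.0'
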