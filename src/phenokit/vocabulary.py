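"""A packaged mini-vocabulary of ontology terms and resource declarations.

Terms are opaque CURIE + label pairs drawn from the ontologies a clinical
phenopacket typically uses (HPO for phenotypes, NCIT for oncology
concepts, UBERON for anatomy, LOINC for assays, UCUM for units, GENO for
zygosity, HGNC for genes). They exist so the synthetic generator and the
worked example can exercise metadata completeness without resolving real
ontology releases; no hierarchy or term existence is implied.
"""

from __future__ import annotations

from .core_model import OntologyClass, Resource

__all__ = ["RESOURCES", "TERMS", "resource_for_prefix", "term"]


#: CURIE → label. Sorted groups by namespace for readability.
TERMS: dict[str, str] = {
    # HPO phenotypic abnormalities
    "HP:0000486": "Strabismus",
    "HP:0000541": "Retinal detachment",
    "HP:0000555": "Leukocoria",
    "HP:0001250": "Seizure",
    "HP:0001433": "Hepatosplenomegaly",
    "HP:0004209": "Clinodactyly of the 5th finger",
    "HP:0007906": "Ocular hypertension",
    "HP:0011460": "Embryonal onset",
    "HP:0012587": "Macroscopic hematuria",
    "HP:0025637": "Vasospasm",
    "HP:0032320": "Affected",
    # HPO modifiers
    "HP:0012834": "Right",
    "HP:0012835": "Left",
    "HP:0012828": "Severe",
    # NCIT oncology concepts
    "NCIT:C7541": "Retinoblastoma",
    "NCIT:C39853": "Retinoblastoma",
    "NCIT:C48601": "Enucleation",
    "NCIT:C140720": "Retinoblastoma pT3 TNM Finding v8",
    "NCIT:C140678": "Retinoblastoma cM0 TNM Finding v8",
    "NCIT:C35941": "Flexner-Wintersteiner Rosette Formation",
    "NCIT:C132485": "Apoptosis and Necrosis",
    "NCIT:C8509": "Primary Neoplasm",
    "NCIT:C633": "Melphalan",
    "NCIT:C38222": "Intraarterial Route of Administration",
    "NCIT:C62220": "Cure",
    "NCIT:C41331": "Adverse Event",
    "NCIT:C10894": "Carboplatin/Etoposide/Vincristine",
    "NCIT:C28554": "Dead",
    "NCIT:C3058": "Glioblastoma",
    # UBERON anatomy
    "UBERON:0004548": "left eye",
    "UBERON:0004549": "right eye",
    "UBERON:0000970": "eye",
    "UBERON:0002107": "liver",
    # LOINC assays
    "LOINC:79893-4": "Left eye Intraocular pressure",
    "LOINC:79892-6": "Right eye Intraocular pressure",
    "LOINC:33728-7": "Size.maximal dimension",
    "LOINC:26515-7": "Platelets [#/volume] in Blood",
    # UCUM units
    "UCUM:mm[Hg]": "millimetres of mercury",
    "UCUM:mm": "millimeter",
    "UCUM:mg/kg": "milligram per kilogram",
    "UCUM:10*3/uL": "thousand per microliter",
    # GENO zygosity
    "GENO:0000135": "heterozygous",
    "GENO:0000136": "homozygous",
}


#: prefix → Resource declaration (versions are pinned, representative
#: release labels; term resolution against releases is out of scope).
RESOURCES: dict[str, Resource] = {
    "HP": Resource(
        id="hp",
        name="human phenotype ontology",
        url="http://purl.obolibrary.org/obo/hp.owl",
        version="2022-06-11",
        namespace_prefix="HP",
        iri_prefix="http://purl.obolibrary.org/obo/HP_",
    ),
    "NCIT": Resource(
        id="ncit",
        name="NCI Thesaurus",
        url="http://purl.obolibrary.org/obo/ncit.owl",
        version="22.03d",
        namespace_prefix="NCIT",
        iri_prefix="http://purl.obolibrary.org/obo/NCIT_",
    ),
    "UBERON": Resource(
        id="uberon",
        name="Uber-anatomy ontology",
        url="http://purl.obolibrary.org/obo/uberon.owl",
        version="2022-04-18",
        namespace_prefix="UBERON",
        iri_prefix="http://purl.obolibrary.org/obo/UBERON_",
    ),
    "LOINC": Resource(
        id="loinc",
        name="Logical Observation Identifiers Names and Codes",
        url="https://loinc.org",
        version="2.72",
        namespace_prefix="LOINC",
        iri_prefix="https://loinc.org/",
    ),
    "UCUM": Resource(
        id="ucum",
        name="Unified Code for Units of Measure",
        url="https://units-of-measure.org",
        version="2.1",
        namespace_prefix="UCUM",
        iri_prefix="https://units-of-measure.org/",
    ),
    "GENO": Resource(
        id="geno",
        name="Genotype Ontology",
        url="http://purl.obolibrary.org/obo/geno.owl",
        version="2022-03-05",
        namespace_prefix="GENO",
        iri_prefix="http://purl.obolibrary.org/obo/GENO_",
    ),
    "HGNC": Resource(
        id="hgnc",
        name="HUGO Gene Nomenclature Committee",
        url="https://www.genenames.org",
        version="2022-06-01",
        namespace_prefix="HGNC",
        iri_prefix="https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/",
    ),
    "MONDO": Resource(
        id="mondo",
        name="Mondo Disease Ontology",
        url="http://purl.obolibrary.org/obo/mondo.owl",
        version="2022-05-02",
        namespace_prefix="MONDO",
        iri_prefix="http://purl.obolibrary.org/obo/MONDO_",
    ),
    "CHEBI": Resource(
        id="chebi",
        name="Chemical Entities of Biological Interest",
        url="http://purl.obolibrary.org/obo/chebi.owl",
        version="2022-05-30",
        namespace_prefix="CHEBI",
        iri_prefix="http://purl.obolibrary.org/obo/CHEBI_",
    ),
}


def term(curie: str) -> OntologyClass:
    """Look up a packaged term as an OntologyClass (KeyError if absent)."""
    return OntologyClass(id=curie, label=TERMS[curie])


def resource_for_prefix(prefix: str) -> Resource:
    """The packaged Resource declaration for a CURIE prefix."""
    return RESOURCES[prefix]
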