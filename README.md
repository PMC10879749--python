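# clinannot

Toolkit for enriching ClinVar XML releases with harmonized disease-ontology
terms and functional consequence annotations.

ClinVar is the central public archive of human variants with asserted
clinical significance, but its releases are heterogeneous: trait names are
free text cross-referenced to several terminologies (MedGen, OMIM,
Orphanet, MONDO), and complex variants — repeat expansions in particular —
are described through HGVS notation rather than precise coordinates.
Aggregation platforms and genome browsers that ingest ClinVar need every
trait mapped to one target ontology (EFO by default) and every variant
assigned an Ensembl gene and a Sequence Ontology (SO) consequence term.
`clinannot` does both, around a curation protocol that keeps a
version-controlled repository of human-reviewed trait mappings growing
release over release.

## What it does

* **Release I/O** — streaming parser/writer for the RCV
  (`ClinVarSet`/`ReferenceClinVarAssertion`) XML dialect. Reading is
  memory-bounded per record; writing preserves every original element and
  injects annotations as namespaced child elements, so
  parse → write → parse is lossless. Tabular export with a configurable
  column vocabulary is also available.
* **Trait mapping** — exact matching (after conservative text
  normalization) of trait names against ontology labels and typed synonyms,
  plus breadth-first closure over a cross-reference table
  (`MedGen → MONDO → EFO` style chains). The decision tiers: previously
  curated mapping → unique exact label → unique exact-scope synonym →
  curation spreadsheet. Any multiple-term ambiguity goes to a human.
  Curated spreadsheets import back into the mappings repository
  (idempotent, audit-preserving merges), and curator verdicts that need new
  ontology terms become a feedback report for the ontology maintainers.
* **Consequence annotation** — variants are separated by class: repeat
  expansions (recognized from an HGVS grammar subset that handles uncertain
  positions `(a_b)` and variable repeat counts `CAG[40_55]`, `CGG(55_200)`),
  simple variants, precise structural events, and unsupported. Repeats are
  classified as `trinucleotide_repeat_expansion` vs
  `short_tandem_repeat_expansion` from the repeat-unit length, with the
  gene assigned by body overlap. Simple variants go through a codon-aware
  local engine (splice sites, UTRs, missense/synonymous/stop/start calls,
  frameshift vs in-frame indels) over a GFF3 transcript set and a reference
  FASTA; the same interface admits a remote effect-predictor backend at
  production scale.
* **Pipeline + evaluation** — a single pass orchestrates
  parse → map → annotate → write, reports coverage metrics, and can
  evaluate concordance between its annotations and the terms the source
  itself provides.
* **Fixture generator** — a seeded generator emits structurally faithful
  toy inputs (release XML, OBO ontology, xref TSV, GFF3 + FASTA with
  consistent multi-exon ORFs on both strands, repeat HGVS strings) plus a
  ground-truth table, so everything above is testable offline.

## Worked example

Generate a 20-record toy release and annotate it:

```bash
clinannot make-fixtures --out demo --seed 4 --n-records 20
clinannot annotate \
    --xml demo/release.xml --ontology demo/ontology.obo \
    --xref-table demo/xrefs.tsv --repository demo/repository.tsv \
    --gff3 demo/genes.gff3 --fasta demo/genome.fa \
    --accession-map demo/accession_map.tsv \
    --out demo/annotated.xml
```

prints the run metrics:

```json
{
  "annotation_errors": 0,
  "class_counts": {
    "repeat_expansion": 4,
    "simple": 12,
    "structural_precise": 2,
    "unsupported": 2
  },
  "complex_variants_processed": 6,
  "measures_total": 20,
  "measures_with_consequence": 18,
  "measures_with_gene": 18,
  "records_total": 20,
  "traits_distinct": 18,
  "traits_distinct_mapped": 13,
  "traits_mapped_current": 15,
  "traits_total": 20
}
```

Of the 20 (record, trait) pairs, 15 mapped automatically to a current
ontology term (`traits_mapped_current`); the rest are queued for curation
(`clinannot export-curation` writes the spreadsheet). All 20 measures got
exactly one variant class; the 2 `unsupported` ones (protein-level HGVS
only) receive no consequence, hence 18/20 with gene and consequence. The
canonical record in every fixture maps the trait "Relapsing remitting
multiple sclerosis" to EFO:0003929 and calls the A→G variant a missense
change — the annotation block injected into `annotated.xml`:

```xml
<ca:Annotations xmlns:ca="http://clinannot.org/annotations/1.0">
  <ca:TraitAnnotation trait="Relapsing remitting multiple sclerosis"
      uri="http://www.ebi.ac.uk/efo/EFO_0003929"
      label="Relapsing remitting multiple sclerosis"
      confidence="AUTO_EXACT_LABEL" provenance="label"/>
  <ca:Consequence measure="100000" so_term="missense_variant"
      so_accession="SO:0001583" provenance="local"
      gene="ENSG00000000001" gene_symbol="FGENE1"
      transcript="ENST00000000001"/>
</ca:Annotations>
```

The other subcommands (`map-traits`, `export-curation`, `import-curation`,
`merge-mappings`, `consequences`, `evaluate`) expose the individual stages;
all flags can also come from a flat `key: value` config file.

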