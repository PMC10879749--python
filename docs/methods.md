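# Methods

This note documents the procedures `clinannot` implements, the parameters
that matter, the design choices made where the design was genuinely open,
and what the test suite does and does not demonstrate.

## Release model

The package implements the RCV release dialect only: root `ReleaseSet`,
one `ClinVarSet` per record, fields read from
`ReferenceClinVarAssertion/ClinVarAccession@Acc`, `MeasureSet/Measure`
(type, `SequenceLocation`, HGVS attributes, gene relationships) and
`TraitSet/Trait` (preferred/alternate names, xrefs). All coordinates are
1-based fully closed, exactly as in `SequenceLocation`; no internal
conversion is ever serialized. Records are treated as trees we decorate,
not projections we re-serialize: the parser keeps each record's original
element, the writer emits it verbatim and appends an `Annotations` block in
a dedicated namespace. Consequently unknown future elements survive a
round trip, and parse → write → parse is field-identical. "Byte-identical"
round trips are asserted after XML canonicalization with insignificant
whitespace stripped (the writer re-indents records; preserving the
original indentation bytes carries no information). Encoding is UTF-8 in
both directions; gzip is sniffed on read and chosen by `.gz` suffix on
write.

Records that associate one trait set with multiple measures are annotated
with one consequence block entry per measure; richer per-association
serialization is a known limitation.

## Trait mapping

Trait text is normalized conservatively before matching: Unicode NFC,
casefold, whitespace runs collapsed to one space, and the characters
`.,;:'"` stripped from the string ends only. Nothing inside the string is
altered, so genuinely distinct disease names never merge; the function is
idempotent.

Matching is exact-after-normalization against ontology labels and typed
synonyms. There is deliberately no fuzzy or lexical-similarity scoring in
the core: that role belongs to hosted text-to-term services, which appear
here only as interface stubs (`clinannot.remote`) so the offline core stays
deterministic. Cross-reference resolution is a breadth-first closure over
an undirected identifier graph loaded from a 4-column TSV
(`source_db, source_id, target_curie, mapping_type`); hop counts are BFS
shortest paths. The default `max_hops` is 2, enough to cross one
intermediate ontology (e.g. MedGen → MONDO → EFO).

The decision procedure, in order:

1. active repository entry whose term is still current → automatic
   (`AUTO_PREVIOUS`);
2. repository entry whose term went obsolete → curation, with the
   `replaced_by` replacement ranked first;
3. a single lexically matched term via its label → automatic
   (`AUTO_EXACT_LABEL`);
4. a single lexically matched term via an exact-scope synonym → automatic
   (`AUTO_EXACT_SYNONYM`);
5. anything else with candidates (multiple terms, other-scope synonyms,
   xref-only hits) → curation, candidates ranked by match kind, hop count,
   then CURIE;
6. no candidates → unmapped.

The high-confidence tier is therefore "exactly one term matched lexically,
by label or exact synonym": any multiple-term ambiguity goes to a human
even when all matches are exact. This is the conservative reading of an
automatic/manual split that is otherwise underdetermined. Matches reached
only through a record's database xrefs never auto-accept and never block a
lexical match — they rank as curation candidates. Obsolete terms with a
`replaced_by` pointing at a current term are followed exactly one step;
longer chains go to curation.

The curation spreadsheet is a TSV sorted by descending record frequency
(triage order) with up to 5 candidate columns (`curie|label|match_kind|hops`)
and three curator columns. The curator vocabulary is closed:
`DONE` produces a mapping, `IMPORT`/`NEW` route to the ontology feedback
report, `SKIP`/`UNSURE` defer. Import validation rejects — never silently
drops — rows whose chosen term is unknown or obsolete.

The mappings repository is a 6-column TSV (trait text, CURIE, label,
status, active flag, timestamp), sorted for stable diffs, chosen over a
database so the mapping history version-controls cleanly. Merges upsert by
(trait text, term): a new mapping for a known trait marks the old entry
inactive but retains it for audit; merging the same batch twice is a
no-op. Trait identity is normalized text, not source trait ids, so
mappings transfer across records sharing a name. After a merge the
repository can be revalidated against the loaded ontology: active entries
whose terms went obsolete are deactivated into a re-curation queue, so no
active entry ever points at a non-current term. Timestamps are
caller-supplied (the CLI passes today's date; the library defaults to a
fixed sentinel) so library output is byte-deterministic.

## Variant classification and consequences

The HGVS parser covers the grammar subset that matters for clinical
releases: `accession:kind.location edit` with `g/c/m/n` coordinates,
uncertain positions `(a_b)` and `?`, UTR coordinates (`-n`, `*n`), and the
edits substitution, del/dup/ins/delins and repeats in three forms —
`UNIT[n]`, `UNIT[n_m]` and `UNIT(n_m)`. Parsing either succeeds completely
or fails with the unconsumed suffix; there are no partial results.
`unparse` inverts the parser on the whole subset (property-tested).

Classes, in precedence order:

* **repeat_expansion** — any HGVS expression parses as a repeat, or the
  source types the measure as a repeat event (`Microsatellite`,
  `Tandem duplication`) and a duplication with an explicit unit can be
  normalized into repeat form;
* **simple** — precise span with both alleles, longest allele under the
  structural threshold;
* **structural_precise** — precise span at or above the threshold with a
  del/dup/ins/delins edit kind (from HGVS or the source type vocabulary);
* **unsupported** — everything else; a value, not an error.

The structural length threshold defaults to 50 bp, the community
convention for the SV boundary; it is configurable.

Repeat expansions are typed from the repeat-unit length. The default
`mod3` policy calls any reading-frame-preserving unit (length divisible by
three, hexanucleotide units included) `trinucleotide_repeat_expansion`,
the rest `short_tandem_repeat_expansion`; the stricter `eq3` policy
(exactly three bases) is available behind `--trinucleotide-rule` because
either reading of "length of the repeating element" is defensible.
Unknown units fall back to the short-tandem class with a low-confidence
flag. Gene assignment for repeat and structural variants is gene-body
overlap only (min exon start to max exon stop) — no nearest-gene fallback;
an imprecise location `(a_b)` is resolved to its outer bounds for the
overlap test.

Simple variants go through the local codon-aware engine: per overlapping
transcript, intronic positions within 2 bp of an exon boundary are
donor/acceptor calls (strand-aware), within 3–8 bp `splice_region_variant`
(mirroring common annotator defaults; both windows configurable), else
`intron_variant`; exonic non-coding positions split into UTR (by strand)
or `non_coding_transcript_exon_variant`; coding SNVs translate the
reference and alternate codon under the standard genetic code
(reverse-complemented on minus-strand transcripts) into
synonymous/missense/stop_gained/stop_lost, with any disruption of the
first codon called `start_lost`; coding indels are `frameshift_variant`
when the length change is not a multiple of three, else in-frame
insertion/deletion. A declared reference allele that disagrees with the
FASTA is a per-variant error record — the variant is skipped, the run
continues. Positions outside every transcript yield a gene-less
`intergenic_variant` annotation (the one term that legitimately carries no
gene). Equal-length multi-base substitutions in coding sequence are
reported as `missense_variant`, a documented simplification.

Multiple transcript calls reduce to one per (measure, gene) by a packaged
severity ranking seeded from the Ensembl consequence ordering; ties break
to the lexicographically smaller transcript id. SO names and accessions
come from a packaged two-column vocabulary table. Precisely located
structural events get gene-body overlap plus a coarse SO term from the
edit kind (deletion/duplication/insertion/indel) — at production scale
these would go to a remote effect predictor, and the backend interface
documents the batching (≤200 variants), exponential-backoff and fail-soft
contract such a client must honour.

## Concordance evaluation

Coverage denominators follow two conventions and both are reported:
distinct (record, trait) pairs and distinct normalized trait names for
traits; distinct measures for genes and consequences. Concordance against
source-provided annotations is computed over a shared key universe,
partitioned into both-present / only-ours / only-source / neither, with
the fraction reported over both-present pairs. Trait terms count as
equivalent when identical or connected within `max_hops` in the xref graph
— the hop-based equivalence is a declared stand-in for a full ontology-
alignment methodology and is surfaced as a parameter rather than fixed.
Genes are equivalent when identical or linked by the HGNC↔Ensembl table
(a small packaged seed table; supply a full one for real comparisons).
Consequence terms are equivalent when identical or paired in the packaged
equivalence list, which currently relates the specific repeat subtypes to
a generic repeat term and in-frame indel calls to their coarse structural
counterparts.

## Fixture generator

The generator emulates the structure of the real inputs at toy scale:
multi-exon genes (2–3 exons, introns 30–80 bp, UTRs 8–15 bp) whose CDS is
built as ATG + 30–70 non-stop codons + stop before being placed on either
strand of a random genome (~12 kb per chromosome, ≤100 kb total so
exhaustive sweeps stay fast); an OBO vocabulary with exact synonyms, two
obsolete terms (with and without replacement) and MedGen xrefs; a
cross-reference TSV including a two-hop chain; repeat HGVS strings cycling
unit lengths 1–6 across all three count forms plus an imprecise-location
form; and trait/variant category mixes applied exactly (largest-remainder
apportionment, then a seeded shuffle). Default mixes — 55/20/15/10 %
exact-label / exact-synonym / xref-only / unmappable traits and
60/20/10/10 % simple / repeat / structural / unsupported variants — were
chosen once to exercise every decision path with realistic dominance of
the simple cases, and are configurable. Every file derives from one
seeded stream; identical seeds give byte-identical outputs. One canonical
record (trait "Relapsing remitting multiple sclerosis" → EFO:0003929, an
A→G missense variant) is embedded by construction: a lysine codon is
forced into the first gene and the variant placed on its first base.

The ground-truth table records each trait's expected mapping status and
term and each measure's expected class, genes and SO term. Trait and
class truths are fixed by construction; the expected SO terms for simple
variants are computed at generation time with the package's own engine, so
truth-table recovery demonstrates pipeline wiring (classification,
routing, gene assignment, reduction), while the engine itself is validated
separately against an independent brute-force oracle that mutates the
genome and translates complete CDS sequences with Biopython.

What passing on fixtures does not show: robustness to the full
heterogeneity of real releases (unusual measure types, multi-trait
records at scale, malformed HGVS diversity), statistical realism of trait
frequencies, or agreement with a production effect predictor beyond the
documented term set.

## Problem sizes and numerical choices

The default test matrix uses 20–40-record releases (10,000 for the
round-trip check), a ~2.4 kb oracle transcript swept exhaustively on both
strands, 1,000 randomized matcher fixtures, and five seeds for truth
recovery; the acceptance script uses 400 records. All orderings are
total (stable sorts by rank, hop, CURIE, transcript id, position) so
identical inputs produce byte-identical outputs everywhere.

## Known limitations

No VCV/VCF/SCV input; no protein-level HGVS; no haplotype-aware or
phased consequence calling; no CNV dosage interpretation; no live
ontology/effect-predictor services anywhere in the test path; curation
itself is a human step — the package only generates and consumes its
artifacts.
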