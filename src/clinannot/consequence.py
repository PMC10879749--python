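"""Variant classification, gene assignment and functional consequences.

Variants are first separated by type: repeat expansions (recognized from
HGVS notation or the source variant-type vocabulary), simple variants (SNVs
and short indels with precise alleles), precisely located structural events,
and everything else (unsupported).  Each class is then annotated by the
matching backend:

* ``repeat_rule`` — classifies the expansion as a trinucleotide or short
  tandem repeat from the length of the repeat unit, and assigns the gene by
  body overlap;
* ``local`` — a codon-aware consequence engine over a GFF3 transcript set
  and a reference FASTA, covering the standard splice / UTR / coding SNV /
  indel decision tree (the role a remote effect predictor plays at
  production scale);
* ``structural`` — gene by body overlap plus a coarse term from the edit
  kind.

All Sequence Ontology names/accessions come from the packaged vocabulary
table; the severity ranking used to reduce multiple transcript consequences
to one per gene is packaged data seeded from the Ensembl ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

from intervaltree import IntervalTree

from .clinvar_io import GenomicSpan, VariantMeasure
from .hgvs import HgvsVariant, try_parse_hgvs

__all__ = [
    "VariantClass",
    "ConsequenceAnnotation",
    "TranscriptModel",
    "GeneIndex",
    "RepeatClassification",
    "ConfigurationError",
    "classify_variant",
    "classify_repeat",
    "genes_overlapping",
    "predict_consequences",
    "most_severe",
    "load_transcripts_gff3",
    "so_accession",
    "load_severity_rank",
    "load_so_equivalence",
    "load_gene_id_map",
    "STRUCTURAL_LENGTH_THRESHOLD",
]

VARIANT_CLASSES = ("simple", "structural_precise", "repeat_expansion", "unsupported")

#: community convention for the SV size boundary, in bp; configurable
STRUCTURAL_LENGTH_THRESHOLD = 50

#: source variant-type strings that indicate a repeat event
REPEAT_VARIANT_TYPES = frozenset({"Microsatellite", "Tandem duplication"})

_STRUCTURAL_KINDS = frozenset({"deletion", "duplication", "insertion", "delins"})
_STRUCTURAL_TYPE_MAP = {
    "deletion": "deletion",
    "duplication": "duplication",
    "tandem duplication": "duplication",
    "insertion": "insertion",
    "indel": "delins",
    "copy number loss": "deletion",
    "copy number gain": "duplication",
}
_STRUCTURAL_SO = {
    "deletion": "deletion",
    "duplication": "duplication",
    "insertion": "insertion",
    "delins": "indel",
}


class ConfigurationError(ValueError):
    pass


def _read_data(name: str) -> list[list[str]]:
    text = resources.files("clinannot.data").joinpath(name).read_text("utf-8")
    return [line.split("\t") for line in text.splitlines() if line.strip()]


def _so_table() -> dict[str, str]:
    return {row[0]: row[1] for row in _read_data("so_terms.tsv")[1:]}


_SO_TABLE = _so_table()


def so_accession(term_name: str) -> str:
    try:
        return _SO_TABLE[term_name]
    except KeyError:
        raise ConfigurationError(
            f"{term_name!r} not in the packaged SO vocabulary"
        ) from None


def load_severity_rank() -> list[str]:
    """Ordered SO term names, most severe first."""
    return [row[0] for row in _read_data("severity_rank.tsv")[1:]]


def load_so_equivalence() -> set[frozenset]:
    """Unordered SO term-name pairs treated as equivalent in evaluation."""
    return {frozenset(row[:2]) for row in _read_data("so_equivalence.tsv")[1:]}


def load_gene_id_map(source=None) -> dict[str, str]:
    """HGNC id → Ensembl stable gene id; packaged seed table by default."""
    rows = (
        _read_data("hgnc_ensembl.tsv")[1:]
        if source is None
        else [
            line.split("\t")
            for line in Path(source).read_text("utf-8").splitlines()[1:]
            if line.strip()
        ]
    )
    return {row[0]: row[1] for row in rows}


@dataclass(frozen=True)
class ConsequenceAnnotation:
    measure_id: str
    gene_id: str  # empty only for intergenic_variant
    so_term_name: str
    so_accession: str
    backend: str  # local | repeat_rule | structural | remote
    gene_symbol: Optional[str] = None
    transcript_id: Optional[str] = None

    def __post_init__(self):
        if self.so_term_name in _SO_TABLE and _SO_TABLE[self.so_term_name] != self.so_accession:
            raise ValueError(
                f"{self.so_term_name} should be {_SO_TABLE[self.so_term_name]}, "
                f"got {self.so_accession}"
            )
        if not self.gene_id and self.so_term_name != "intergenic_variant":
            raise ValueError(f"{self.so_term_name} annotation requires a gene_id")


# ---------------------------------------------------------------------------
# variant class separation


def _repeat_hgvs(measure: VariantMeasure) -> Optional[HgvsVariant]:
    """The parsed repeat expression behind a measure, if any.

    Measures typed as repeat events in the source vocabulary but written as
    a duplication of an explicit unit are normalized into repeat form.
    """
    parsed = [p for e in measure.hgvs_expressions if (p := try_parse_hgvs(e))]
    for p in parsed:
        if p.edit_kind == "repeat":
            return p
    if measure.variant_type in REPEAT_VARIANT_TYPES:
        for p in parsed:
            if p.edit_kind == "duplication" and p.ref:
                return HgvsVariant(
                    accession=p.accession,
                    coordinate_kind=p.coordinate_kind,
                    start=p.start,
                    end=p.end,
                    edit_kind="repeat",
                    repeat_unit=p.ref,
                    repeat_count=(2, 2),
                )
    return None


def _edit_kind(measure: VariantMeasure) -> Optional[str]:
    for e in measure.hgvs_expressions:
        p = try_parse_hgvs(e)
        if p is not None and p.edit_kind in _STRUCTURAL_KINDS:
            return p.edit_kind
    return _STRUCTURAL_TYPE_MAP.get(measure.variant_type.lower())


def classify_variant(
    measure: VariantMeasure,
    structural_length_threshold: int = STRUCTURAL_LENGTH_THRESHOLD,
) -> str:
    """Assign exactly one variant class to a measure (total function).

    Precedence: repeat_expansion > simple > structural_precise >
    unsupported.  ``unsupported`` is a value, not an error — it routes the
    measure past annotation, never aborts.
    """
    if _repeat_hgvs(measure) is not None:
        return "repeat_expansion"
    span = measure.preferred_span()
    if (
        span is not None
        and span.ref is not None
        and span.alt is not None
        and max(len(span.ref), len(span.alt)) < structural_length_threshold
    ):
        return "simple"
    if (
        span is not None
        and span.length >= structural_length_threshold
        and _edit_kind(measure) in _STRUCTURAL_KINDS
    ):
        return "structural_precise"
    return "unsupported"


# ---------------------------------------------------------------------------
# repeat expansions


class RepeatClassification(NamedTuple):
    so_term_name: str
    so_accession: str
    low_confidence: bool


def classify_repeat(parsed: HgvsVariant, rule: str = "mod3") -> RepeatClassification:
    """Trinucleotide vs short-tandem repeat expansion, from the unit length.

    ``mod3`` treats any reading-frame-preserving unit (length divisible by
    three, e.g. hexanucleotide GGGGCC) as trinucleotide-type; ``eq3``
    restricts that to units of exactly three bases.  Unknown units fall back
    to the generic short tandem class, flagged low-confidence.
    """
    if parsed.edit_kind != "repeat":
        raise ValueError("classify_repeat requires a repeat-edit variant")
    if rule not in ("mod3", "eq3"):
        raise ConfigurationError(f"unknown trinucleotide rule {rule!r}")
    unit = parsed.repeat_unit
    if unit is None:
        name = "short_tandem_repeat_expansion"
        return RepeatClassification(name, so_accession(name), True)
    trinucleotide = (len(unit) % 3 == 0) if rule == "mod3" else (len(unit) == 3)
    name = (
        "trinucleotide_repeat_expansion"
        if trinucleotide
        else "short_tandem_repeat_expansion"
    )
    return RepeatClassification(name, so_accession(name), False)


# ---------------------------------------------------------------------------
# transcript models and gene index


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # + or -
    exons: tuple[tuple[int, int], ...]  # 1-based closed, sorted by start
    cds_start: Optional[int] = None  # genomic bounds, inclusive
    cds_end: Optional[int] = None
    gene_symbol: Optional[str] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if end < start:
                raise ValueError(f"exon ({start},{end}) has end < start")
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if not any(
                s <= self.cds_start <= e for s, e in self.exons
            ) or not any(s <= self.cds_end <= e for s, e in self.exons):
                raise ValueError("CDS bounds must lie within the exon union")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of the CDS, in transcription (5'→3') order."""
        positions = [
            p
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end) + 1)
        ]
        return positions[::-1] if self.strand == "-" else positions


class GeneIndex:
    """Interval index of gene bodies (min exon start → max exon stop)."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts = list(transcripts)
        self._by_gene: dict[str, list[TranscriptModel]] = {}
        bodies: dict[str, tuple[str, int, int]] = {}
        for t in self.transcripts:
            self._by_gene.setdefault(t.gene_id, []).append(t)
            chrom, lo, hi = bodies.get(t.gene_id, (t.chrom, t.start, t.end))
            bodies[t.gene_id] = (chrom, min(lo, t.start), max(hi, t.end))
        self._trees: dict[str, IntervalTree] = {}
        self._bodies = bodies
        for gene_id, (chrom, lo, hi) in bodies.items():
            self._trees.setdefault(chrom, IntervalTree()).addi(lo, hi + 1, gene_id)

    def genes_overlapping(self, chrom: str, start: int, stop: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, stop + 1)
        return [
            iv.data for iv in sorted(hits, key=lambda iv: (iv.begin, iv.data))
        ]

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return sorted(self._by_gene.get(gene_id, []), key=lambda t: t.transcript_id)

    def gene_body(self, gene_id: str) -> tuple[str, int, int]:
        return self._bodies[gene_id]

    def gene_symbol(self, gene_id: str) -> Optional[str]:
        for t in self._by_gene.get(gene_id, []):
            if t.gene_symbol:
                return t.gene_symbol
        return None


def genes_overlapping(span: GenomicSpan, gene_index: GeneIndex) -> list[str]:
    """Genes whose body intersects the span, in (position, id) order."""
    return gene_index.genes_overlapping(span.chrom, span.start, span.stop)


def load_transcripts_gff3(gff3_path) -> GeneIndex:
    """Build a :class:`GeneIndex` from a GFF3 gene/mRNA/exon/CDS annotation."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts = []
    for gene in db.features_of_type("gene"):
        symbol = gene.attributes.get("Name", [None])[0]
        for tx in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(tx, featuretype="exon"))
            )
            cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
            cds_start = min(s for s, _ in cds) if cds else None
            cds_end = max(e for _, e in cds) if cds else None
            transcripts.append(
                TranscriptModel(
                    gene_id=gene.id,
                    transcript_id=tx.id,
                    chrom=gene.seqid,
                    strand=tx.strand,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    gene_symbol=symbol,
                )
            )
    return GeneIndex(transcripts)


# ---------------------------------------------------------------------------
# the local consequence backend

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(reference, chrom: str, start: int, stop: int) -> str:
    """1-based closed fetch from a dict of sequences or a FASTA accessor."""
    if isinstance(reference, dict):
        return reference[chrom][start - 1 : stop].upper()
    return str(reference[chrom][start - 1 : stop]).upper()


@dataclass(frozen=True)
class VariantError:
    measure_id: str
    reason: str


def _intron_term(
    pos: int, left_exon_end: int, right_exon_start: int, strand: str,
    splice_site: int, splice_region: int,
) -> str:
    d_left = pos - left_exon_end  # 1 = first intronic base after the left exon
    d_right = right_exon_start - pos
    if strand == "+":
        donor_d, acceptor_d = d_left, d_right
    else:
        donor_d, acceptor_d = d_right, d_left
    if donor_d <= splice_site:
        return "splice_donor_variant"
    if acceptor_d <= splice_site:
        return "splice_acceptor_variant"
    if min(d_left, d_right) <= splice_region:
        return "splice_region_variant"
    return "intron_variant"


def _coding_snv_term(t: TranscriptModel, pos: int, alt: str, reference) -> str:
    cds_positions = t.cds_genomic_positions()
    cds_index = cds_positions.index(pos)
    codon_index = cds_index // 3
    offset = cds_index % 3
    codon_pos = cds_positions[codon_index * 3 : codon_index * 3 + 3]
    if len(codon_pos) < 3:  # CDS not a multiple of 3; treat as generic coding
        return "missense_variant"
    # cds_positions are in transcription order already; on the minus strand
    # the transcript base at each position is the complement of the genomic one
    bases = [_fetch(reference, t.chrom, p, p) for p in codon_pos]
    alt_bases = list(bases)
    alt_bases[offset] = alt
    if t.strand == "-":
        ref_codon = "".join(b.translate(_COMPLEMENT) for b in bases)
        alt_codon = "".join(b.translate(_COMPLEMENT) for b in alt_bases)
    else:
        ref_codon = "".join(bases)
        alt_codon = "".join(alt_bases)
    ref_aa = CODON_TABLE.get(ref_codon, "X")
    alt_aa = CODON_TABLE.get(alt_codon, "X")
    if codon_index == 0 and alt_codon != "ATG":
        return "start_lost"
    if ref_aa == alt_aa:
        return "synonymous_variant"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense_variant"


def _transcript_term(
    t: TranscriptModel,
    span: GenomicSpan,
    reference,
    splice_site: int,
    splice_region: int,
) -> str:
    pos = span.start
    is_snv = len(span.ref) == 1 and len(span.alt) == 1
    exon_idx = None
    for i, (s, e) in enumerate(t.exons):
        if s <= pos <= e:
            exon_idx = i
            break
    if exon_idx is None:
        # intronic: find the flanking exons
        for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
            if e1 < pos < s2:
                return _intron_term(pos, e1, s2, t.strand, splice_site, splice_region)
        # within gene body but outside this transcript's span
        return "intergenic_variant"
    if not t.coding:
        return "non_coding_transcript_exon_variant"
    if pos < t.cds_start:
        return "5_prime_UTR_variant" if t.strand == "+" else "3_prime_UTR_variant"
    if pos > t.cds_end:
        return "3_prime_UTR_variant" if t.strand == "+" else "5_prime_UTR_variant"
    if is_snv:
        return _coding_snv_term(t, pos, span.alt, reference)
    change = abs(len(span.ref) - len(span.alt))
    if change % 3 != 0:
        return "frameshift_variant"
    if change == 0:
        return "missense_variant"  # same-length multi-base substitution
    if len(span.alt) > len(span.ref):
        return "inframe_insertion"
    return "inframe_deletion"


def predict_consequences(
    variants: Sequence[tuple[str, GenomicSpan]],
    transcripts: GeneIndex,
    reference,
    splice_site: int = 2,
    splice_region: int = 8,
) -> tuple[list[ConsequenceAnnotation], list[VariantError]]:
    """Local consequence backend for simple variants.

    One annotation per (variant, overlapping transcript); positions outside
    every transcript yield a single gene-less ``intergenic_variant``
    annotation.  Variants whose declared reference allele disagrees with the
    reference sequence are reported as errors and skipped — the run
    continues.
    """
    annotations: list[ConsequenceAnnotation] = []
    errors: list[VariantError] = []
    for measure_id, span in variants:
        if span.ref is None or span.alt is None:
            errors.append(VariantError(measure_id, "span lacks ref/alt alleles"))
            continue
        try:
            observed = _fetch(reference, span.chrom, span.start, span.stop)
        except KeyError:
            errors.append(VariantError(measure_id, f"unknown chromosome {span.chrom}"))
            continue
        if observed != span.ref:
            errors.append(
                VariantError(
                    measure_id,
                    f"reference mismatch at {span.chrom}:{span.start} "
                    f"(expected {span.ref}, found {observed})",
                )
            )
            continue
        emitted = False
        for gene_id in transcripts.genes_overlapping(span.chrom, span.start, span.stop):
            for t in transcripts.transcripts_of(gene_id):
                if not (t.start <= span.start <= t.end):
                    continue
                term = _transcript_term(t, span, reference, splice_site, splice_region)
                if term == "intergenic_variant":
                    continue
                annotations.append(
                    ConsequenceAnnotation(
                        measure_id=measure_id,
                        gene_id=gene_id,
                        so_term_name=term,
                        so_accession=so_accession(term),
                        backend="local",
                        gene_symbol=t.gene_symbol,
                        transcript_id=t.transcript_id,
                    )
                )
                emitted = True
        if not emitted:
            annotations.append(
                ConsequenceAnnotation(
                    measure_id=measure_id,
                    gene_id="",
                    so_term_name="intergenic_variant",
                    so_accession=so_accession("intergenic_variant"),
                    backend="local",
                )
            )
    return annotations, errors


def most_severe(
    annotations: Iterable[ConsequenceAnnotation],
    severity_rank: Optional[Sequence[str]] = None,
) -> list[ConsequenceAnnotation]:
    """Reduce to one annotation per (measure, gene): the most severe term.

    Ties across transcripts break to the lexicographically smaller
    transcript id; output is sorted by (measure, gene).
    """
    rank = list(severity_rank) if severity_rank is not None else load_severity_rank()
    order = {name: i for i, name in enumerate(rank)}
    best: dict[tuple[str, str], ConsequenceAnnotation] = {}
    for a in annotations:
        if a.so_term_name not in order:
            raise ConfigurationError(
                f"{a.so_term_name!r} missing from the severity rank table"
            )
        key = (a.measure_id, a.gene_id)
        prior = best.get(key)
        if prior is None:
            best[key] = a
            continue
        a_key = (order[a.so_term_name], a.transcript_id or "")
        p_key = (order[prior.so_term_name], prior.transcript_id or "")
        if a_key < p_key:
            best[key] = a
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# repeat / structural annotation glue


def span_from_hgvs(parsed: HgvsVariant, chrom: str, assembly: str = "") -> Optional[GenomicSpan]:
    """Outer-bounds genomic span of a (possibly imprecise) parsed variant."""
    lo = parsed.start.outer_low
    hi = (parsed.end or parsed.start).outer_high
    if lo is None or hi is None or lo < 1 or hi < lo:
        return None
    return GenomicSpan(assembly=assembly, chrom=chrom, start=lo, stop=hi)


def annotate_repeat(
    measure: VariantMeasure,
    gene_index: GeneIndex,
    rule: str = "mod3",
    accession_chrom: Optional[dict] = None,
) -> list[ConsequenceAnnotation]:
    """Repeat-rule backend: unit-length classification + gene-body overlap.

    The gene is found from the measure's precise span when present, else
    from the outer bounds of the imprecise HGVS location (requires an
    ``accession → chromosome`` mapping for the HGVS accession).
    """
    parsed = _repeat_hgvs(measure)
    if parsed is None:
        return []
    cls = classify_repeat(parsed, rule)
    span = measure.preferred_span()
    if span is None:
        chrom = (accession_chrom or {}).get(parsed.accession)
        if chrom is not None:
            span = span_from_hgvs(parsed, chrom)
    if span is None:
        return []
    return [
        ConsequenceAnnotation(
            measure_id=measure.measure_id,
            gene_id=g,
            so_term_name=cls.so_term_name,
            so_accession=cls.so_accession,
            backend="repeat_rule",
            gene_symbol=gene_index.gene_symbol(g),
        )
        for g in genes_overlapping(span, gene_index)
    ]


def annotate_structural(
    measure: VariantMeasure, gene_index: GeneIndex
) -> list[ConsequenceAnnotation]:
    """Structural backend: gene-body overlap + coarse term from edit kind."""
    kind = _edit_kind(measure)
    span = measure.preferred_span()
    if kind is None or span is None:
        return []
    term = _STRUCTURAL_SO[kind]
    return [
        ConsequenceAnnotation(
            measure_id=measure.measure_id,
            gene_id=g,
            so_term_name=term,
            so_accession=so_accession(term),
            backend="structural",
            gene_symbol=gene_index.gene_symbol(g),
        )
        for g in genes_overlapping(span, gene_index)
    ]
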