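"""Deterministic toy-scale fixture generator with a ground-truth table.

Real inputs to this toolkit — a ClinVar release, a disease ontology, a
cross-reference table, an Ensembl annotation and a reference genome — are
multi-gigabyte, version-pinned downloads.  This module emits structurally
faithful miniatures of all of them, plus a truth table recording what every
generated trait and measure should map to, so every pipeline stage is
testable offline and end-to-end runs can be checked exactly.

Everything derives from one seeded pseudo-random stream: identical seeds
give byte-identical files.  The generator aims for structural realism
(multi-exon genes on both strands with consistent CDS, repeat expansions in
the HGVS forms ClinVar actually uses, trait names hitting every matching
tier) — not for statistical realism of trait frequencies.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .clinvar_io import (
    ClinVarRecord,
    GenomicSpan,
    TraitRecord,
    VariantMeasure,
    write_annotated_xml,
)
from .consequence import (
    CODON_TABLE,
    GeneIndex,
    TranscriptModel,
    classify_repeat,
    genes_overlapping,
    most_severe,
    predict_consequences,
    reverse_complement,
)
from .hgvs import parse_hgvs

__all__ = [
    "FixtureSpec",
    "FixtureSpecError",
    "FixtureSet",
    "TraitTruth",
    "MeasureTruth",
    "generate_fixture_set",
]

_BASES = "ACGT"
_NONSTOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_STOP_CODONS = ("TAA", "TAG", "TGA")

DEMO_TRAIT = "Relapsing remitting multiple sclerosis"
DEMO_CURIE = "EFO:0003929"

TRAIT_CATEGORIES = ("exact_label", "exact_synonym", "xref_only", "unmappable")
VARIANT_CATEGORIES = ("simple", "repeat", "structural", "unsupported")


class FixtureSpecError(ValueError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 0
    n_records: int = 50
    trait_vocabulary_size: int = 20
    fraction_exact_label: float = 0.55
    fraction_exact_synonym: float = 0.20
    fraction_xref_only: float = 0.15
    fraction_unmappable: float = 0.10
    fraction_simple: float = 0.60
    fraction_repeat: float = 0.20
    fraction_structural: float = 0.10
    fraction_unsupported: float = 0.10
    n_genes: int = 6
    n_chroms: int = 2
    chrom_length: int = 12000
    structural_length_threshold: int = 50
    include_demo_record: bool = True

    def validate(self) -> None:
        trait_sum = (
            self.fraction_exact_label
            + self.fraction_exact_synonym
            + self.fraction_xref_only
            + self.fraction_unmappable
        )
        var_sum = (
            self.fraction_simple
            + self.fraction_repeat
            + self.fraction_structural
            + self.fraction_unsupported
        )
        if abs(trait_sum - 1.0) > 1e-9:
            raise FixtureSpecError(f"trait fractions sum to {trait_sum}, not 1")
        if abs(var_sum - 1.0) > 1e-9:
            raise FixtureSpecError(f"variant fractions sum to {var_sum}, not 1")
        for name in (
            "fraction_exact_label", "fraction_exact_synonym", "fraction_xref_only",
            "fraction_unmappable", "fraction_simple", "fraction_repeat",
            "fraction_structural", "fraction_unsupported",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise FixtureSpecError(f"{name} outside [0, 1]")
        if self.n_records < 1 or self.trait_vocabulary_size < 1 or self.n_chroms < 1:
            raise FixtureSpecError("counts must be positive")
        if self.n_genes < 1 and (
            self.fraction_simple > 0
            or self.fraction_repeat > 0
            or self.fraction_structural > 0
        ):
            raise FixtureSpecError("gene-anchored variant fractions require n_genes >= 1")


@dataclass(frozen=True)
class TraitTruth:
    rcv: str
    trait_text: str
    expected_status: str  # automatic | requires_curation | unmapped
    expected_curie: str  # "" when no term is expected


@dataclass(frozen=True)
class MeasureTruth:
    rcv: str
    measure_id: str
    expected_class: str
    expected_genes: tuple[str, ...]
    expected_so_term: str  # "" when no consequence is expected


@dataclass
class FixtureSet:
    out_dir: Path
    spec: FixtureSpec
    release_xml: Path
    ontology: Path
    xref_table: Path
    repository: Path
    genome_fasta: Path
    genes_gff3: Path
    accession_map: Path
    gene_map: Path
    source_annotations: Path
    manifest: Path
    trait_truth: list[TraitTruth] = field(default_factory=list)
    measure_truth: list[MeasureTruth] = field(default_factory=list)
    genome: dict = field(default_factory=dict)  # chrom -> sequence
    gene_index: Optional[GeneIndex] = None


# ---------------------------------------------------------------------------
# gene construction


@dataclass
class _Gene:
    model: TranscriptModel
    hgnc_id: str
    accession: str
    demo_position: Optional[int] = None  # 1-based chromosome position, ref A


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _build_gene(
    rng: random.Random, idx: int, chrom: str, strand: str, demo: bool
) -> tuple[str, list[tuple[int, int]], tuple[int, int], Optional[int]]:
    """Construct one gene in sense orientation and flip if needed.

    Returns (segment sequence in chromosome orientation, exon intervals as
    0-based closed segment-local offsets, CDS bounds likewise, demo SNV
    offset or None).
    """
    u5 = rng.randint(8, 15)
    u3 = rng.randint(8, 15)
    n_internal = rng.randint(30, 70)
    codons = [rng.choice(_NONSTOP_CODONS) for _ in range(n_internal)]
    if demo:
        codons[5] = "AAA"  # K; A>G at its first base gives E: missense
    cds = "ATG" + "".join(codons) + rng.choice(_STOP_CODONS)
    tx = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
    L = len(tx)

    n_exons = rng.randint(2, 3)
    while True:
        cuts = sorted(rng.sample(range(10, L - 10), n_exons - 1))
        bounds = [0] + cuts + [L]
        if all(bounds[i + 1] - bounds[i] >= 10 for i in range(n_exons)):
            break
    exon_tx = [(bounds[i], bounds[i + 1] - 1) for i in range(n_exons)]
    introns = [rng.randint(30, 80) for _ in range(n_exons - 1)]

    def tx_to_sense(off: int) -> int:
        for i, (a, b) in enumerate(exon_tx):
            if a <= off <= b:
                return off + sum(introns[:i])
        raise AssertionError(off)

    pieces = []
    for i, (a, b) in enumerate(exon_tx):
        pieces.append(tx[a : b + 1])
        if i < n_exons - 1:
            pieces.append(_random_seq(rng, introns[i]))
    sense = "".join(pieces)
    S = len(sense)
    exon_sense = [(tx_to_sense(a), tx_to_sense(b)) for a, b in exon_tx]
    cds_sense = (tx_to_sense(u5), tx_to_sense(u5 + len(cds) - 1))
    demo_sense = tx_to_sense(u5 + 3 * 6) if demo else None

    if strand == "+":
        return sense, exon_sense, cds_sense, demo_sense
    segment = reverse_complement(sense)
    exon_seg = sorted((S - 1 - b, S - 1 - a) for a, b in exon_sense)
    cds_seg = (S - 1 - cds_sense[1], S - 1 - cds_sense[0])
    return segment, exon_seg, cds_seg, None


def _build_genome(spec: FixtureSpec, rng: random.Random):
    chroms = [str(i + 1) for i in range(spec.n_chroms)]
    accessions = {c: f"NC_9{int(c):06d}.1" for c in chroms}
    sequences: dict[str, list[str]] = {c: [] for c in chroms}
    cursors = {c: 0 for c in chroms}
    genes: list[_Gene] = []
    for i in range(spec.n_genes):
        chrom = chroms[i % len(chroms)]
        strand = "+" if (i == 0 or rng.random() < 0.5) else "-"
        demo = i == 0 and spec.include_demo_record
        segment, exons_seg, cds_seg, demo_seg = _build_gene(
            rng, i, chrom, strand, demo
        )
        gap = _random_seq(rng, rng.randint(200, 400))
        sequences[chrom].append(gap)
        g0 = cursors[chrom] + len(gap)
        sequences[chrom].append(segment)
        cursors[chrom] = g0 + len(segment)
        model = TranscriptModel(
            gene_id=f"ENSG{i + 1:011d}",
            transcript_id=f"ENST{i + 1:011d}",
            chrom=chrom,
            strand=strand,
            exons=tuple((g0 + a + 1, g0 + b + 1) for a, b in exons_seg),
            cds_start=g0 + cds_seg[0] + 1,
            cds_end=g0 + cds_seg[1] + 1,
            gene_symbol=f"FGENE{i + 1}",
        )
        genes.append(
            _Gene(
                model=model,
                hgnc_id=f"HGNC:9{i + 1:04d}",
                accession=accessions[chrom],
                demo_position=(g0 + demo_seg + 1) if demo_seg is not None else None,
            )
        )
    genome = {}
    for c in chroms:
        seq = "".join(sequences[c])
        if len(seq) < spec.chrom_length:
            seq += _random_seq(rng, spec.chrom_length - len(seq))
        genome[c] = seq
    return genome, genes, accessions


# ---------------------------------------------------------------------------
# ontology / traits


@dataclass
class _Term:
    curie: str
    label: str
    synonym: str
    medgen: str
    obsolete: bool = False
    replaced_by: Optional[str] = None


def _build_vocabulary(spec: FixtureSpec) -> list[_Term]:
    terms = [
        _Term(
            curie=f"EFO:07{i:05d}",
            label=f"Fixture disease {i:03d}",
            synonym=f"Fixture disease {i:03d} syndrome",
            medgen=f"C9{i:05d}",
        )
        for i in range(spec.trait_vocabulary_size)
    ]
    # two obsolete terms, one with a current replacement, one without
    terms.append(
        _Term(
            curie="EFO:0800000",
            label="Retired fixture disease",
            synonym="Retired fixture disease syndrome",
            medgen="C8800000",
            obsolete=True,
            replaced_by=terms[0].curie,
        )
    )
    terms.append(
        _Term(
            curie="EFO:0800001",
            label="Abandoned fixture disease",
            synonym="Abandoned fixture disease syndrome",
            medgen="C8800001",
            obsolete=True,
        )
    )
    return terms


def _write_obo(path: Path, terms: list[_Term], include_demo: bool) -> None:
    lines = ["format-version: 1.4", "ontology: fixture-efo", ""]
    def stanza(curie, label, synonym=None, obsolete=False, replaced_by=None,
               medgen=None):
        lines.append("[Term]")
        lines.append(f"id: {curie}")
        lines.append(f"name: {label}")
        if synonym:
            lines.append(f'synonym: "{synonym}" EXACT []')
        if medgen:
            lines.append(f"xref: MedGen:{medgen}")
        if obsolete:
            lines.append("is_obsolete: true")
        if replaced_by:
            lines.append(f"replaced_by: {replaced_by}")
        lines.append("")

    if include_demo:
        stanza(DEMO_CURIE, DEMO_TRAIT)
    for t in terms:
        stanza(t.curie, t.label, t.synonym, t.obsolete, t.replaced_by, t.medgen)
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# generation


def _exact_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment so category counts sum to n exactly."""
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_fixture_set(spec: FixtureSpec, out_dir) -> FixtureSet:
    """Emit the full toy input set plus its ground truth into `out_dir`."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    genome, genes, accessions = _build_genome(spec, rng)
    gene_index = GeneIndex([g.model for g in genes])
    terms = _build_vocabulary(spec)
    current_terms = [t for t in terms if not t.obsolete]

    fixture = FixtureSet(
        out_dir=out_dir,
        spec=spec,
        release_xml=out_dir / "release.xml",
        ontology=out_dir / "ontology.obo",
        xref_table=out_dir / "xrefs.tsv",
        repository=out_dir / "repository.tsv",
        genome_fasta=out_dir / "genome.fa",
        genes_gff3=out_dir / "genes.gff3",
        accession_map=out_dir / "accession_map.tsv",
        gene_map=out_dir / "gene_map.tsv",
        source_annotations=out_dir / "source_annotations.tsv",
        manifest=out_dir / "manifest.jsonl",
        genome=genome,
        gene_index=gene_index,
    )

    # --- category assignment, exact by construction
    trait_counts = _exact_counts(
        spec.n_records,
        [
            spec.fraction_exact_label,
            spec.fraction_exact_synonym,
            spec.fraction_xref_only,
            spec.fraction_unmappable,
        ],
    )
    var_counts = _exact_counts(
        spec.n_records,
        [
            spec.fraction_simple,
            spec.fraction_repeat,
            spec.fraction_structural,
            spec.fraction_unsupported,
        ],
    )
    trait_cats = [
        c for c, n in zip(TRAIT_CATEGORIES, trait_counts) for _ in range(n)
    ]
    var_cats = [
        c for c, n in zip(VARIANT_CATEGORIES, var_counts) for _ in range(n)
    ]
    rng.shuffle(trait_cats)
    rng.shuffle(var_cats)

    demo = spec.include_demo_record
    if demo:
        if "exact_label" not in trait_cats or "simple" not in var_cats:
            raise FixtureSpecError(
                "demo record needs an exact_label trait slot and a simple "
                "variant slot; disable include_demo_record for this mix"
            )
        i = trait_cats.index("exact_label")
        trait_cats[0], trait_cats[i] = trait_cats[i], trait_cats[0]
        j = var_cats.index("simple")
        var_cats[0], var_cats[j] = var_cats[j], var_cats[0]

    records: list[ClinVarRecord] = []
    source_rows: list[tuple[str, str, str]] = []  # (kind, key, value)
    unit_lengths = [1, 2, 3, 4, 5, 6]
    repeat_form = 0
    simple_count = 0

    for i in range(spec.n_records):
        rcv = f"RCV{i + 1:09d}.1"
        is_demo = demo and i == 0

        # ---- trait
        tcat = trait_cats[i]
        if is_demo:
            trait = TraitRecord(preferred_name=DEMO_TRAIT)
            fixture.trait_truth.append(
                TraitTruth(rcv, DEMO_TRAIT, "automatic", DEMO_CURIE)
            )
            source_rows.append(("trait", f"{rcv}|{DEMO_TRAIT}", DEMO_CURIE))
        elif tcat == "exact_label":
            term = rng.choice(current_terms)
            trait = TraitRecord(
                preferred_name=term.label, xrefs=(("MedGen", term.medgen),)
            )
            fixture.trait_truth.append(
                TraitTruth(rcv, term.label, "automatic", term.curie)
            )
            source_rows.append(("trait", f"{rcv}|{term.label}", term.curie))
        elif tcat == "exact_synonym":
            term = rng.choice(current_terms)
            trait = TraitRecord(
                preferred_name=term.synonym, xrefs=(("MedGen", term.medgen),)
            )
            fixture.trait_truth.append(
                TraitTruth(rcv, term.synonym, "automatic", term.curie)
            )
            source_rows.append(("trait", f"{rcv}|{term.synonym}", term.curie))
        elif tcat == "xref_only":
            term = rng.choice(current_terms)
            text = f"Unlisted condition {i:03d}"
            trait = TraitRecord(
                preferred_name=text, xrefs=(("MedGen", term.medgen),)
            )
            fixture.trait_truth.append(
                TraitTruth(rcv, text, "requires_curation", term.curie)
            )
            source_rows.append(("trait", f"{rcv}|{text}", ""))
        else:  # unmappable
            text = f"Mystery ailment {i:03d}"
            trait = TraitRecord(preferred_name=text)
            fixture.trait_truth.append(TraitTruth(rcv, text, "unmapped", ""))
            source_rows.append(("trait", f"{rcv}|{text}", ""))

        # ---- variant
        vcat = var_cats[i]
        measure_id = str(100000 + i)
        gene = genes[rng.randrange(len(genes))] if genes else None
        if vcat == "simple":
            if is_demo:
                gene = genes[0]
                pos = genes[0].demo_position
                ref, alt = "A", "G"
            else:
                gene = genes[simple_count % len(genes)]
                t = gene.model
                if simple_count % 7 == 3:  # occasional 1-bp deletion
                    pos = rng.randint(t.start, t.end - 1)
                    ref = genome[t.chrom][pos - 1 : pos + 1]
                    alt = ref[0]
                else:
                    pos = rng.randint(t.start, t.end)
                    ref = genome[t.chrom][pos - 1]
                    alt = rng.choice([b for b in _BASES if b != ref])
            simple_count += 1
            span = GenomicSpan(
                assembly="GRCh38",
                chrom=gene.model.chrom,
                start=pos,
                stop=pos + len(ref) - 1,
                ref=ref,
                alt=alt,
            )
            measure = VariantMeasure(
                measure_id=measure_id,
                variant_type="single nucleotide variant"
                if len(ref) == len(alt) == 1
                else "Deletion",
                spans=(span,),
                gene_symbols=(gene.model.gene_symbol,),
                hgnc_ids=(gene.hgnc_id,),
            )
            anns, errs = predict_consequences(
                [(measure_id, span)], gene_index, genome
            )
            assert not errs, errs
            reduced = most_severe(anns)
            genes_hit = tuple(sorted({a.gene_id for a in reduced if a.gene_id}))
            so = ",".join(sorted({a.so_term_name for a in reduced}))
            fixture.measure_truth.append(
                MeasureTruth(rcv, measure_id, "simple", genes_hit, so)
            )
            source_rows.append(("gene", f"{rcv}|{measure_id}", gene.hgnc_id))
            source_rows.append(("consequence", f"{rcv}|{measure_id}", so))
        elif vcat == "repeat":
            t = gene.model
            unit_len = unit_lengths[repeat_form % len(unit_lengths)]
            unit = _random_seq(rng, unit_len)
            pos = rng.randint(t.start, t.end)
            n = rng.randint(20, 60)
            m = n + rng.randint(5, 40)
            form = repeat_form % 4
            repeat_form += 1
            if form == 0:
                expr = f"{gene.accession}:g.{pos}{unit}[{n}]"
            elif form == 1:
                expr = f"{gene.accession}:g.{pos}{unit}[{n}_{m}]"
            elif form == 2:
                expr = f"{gene.accession}:g.{pos}{unit}({n}_{m})"
            else:  # imprecise location
                expr = f"{gene.accession}:g.({pos}_{min(pos + 50, t.end)}){unit}[{n}]"
            measure = VariantMeasure(
                measure_id=measure_id,
                variant_type="Microsatellite",
                hgvs_expressions=(expr,),
                gene_symbols=(t.gene_symbol,),
                hgnc_ids=(gene.hgnc_id,),
            )
            cls = classify_repeat(parse_hgvs(expr))
            span = GenomicSpan(
                assembly="GRCh38", chrom=t.chrom, start=pos,
                stop=min(pos + 50, t.end) if form == 3 else pos,
            )
            genes_hit = tuple(genes_overlapping(span, gene_index))
            fixture.measure_truth.append(
                MeasureTruth(
                    rcv, measure_id, "repeat_expansion", genes_hit, cls.so_term_name
                )
            )
            source_rows.append(("gene", f"{rcv}|{measure_id}", gene.hgnc_id))
            source_rows.append(
                ("consequence", f"{rcv}|{measure_id}", "repeat_expansion")
            )
        elif vcat == "structural":
            t = gene.model
            length = rng.randint(
                spec.structural_length_threshold + 10,
                spec.structural_length_threshold + 150,
            )
            start = rng.randint(t.start, max(t.start, t.end - length))
            span = GenomicSpan(
                assembly="GRCh38", chrom=t.chrom, start=start,
                stop=start + length - 1,
            )
            measure = VariantMeasure(
                measure_id=measure_id,
                variant_type="Deletion",
                spans=(span,),
                gene_symbols=(t.gene_symbol,),
                hgnc_ids=(gene.hgnc_id,),
            )
            genes_hit = tuple(genes_overlapping(span, gene_index))
            fixture.measure_truth.append(
                MeasureTruth(rcv, measure_id, "structural_precise", genes_hit, "deletion")
            )
            source_rows.append(("gene", f"{rcv}|{measure_id}", gene.hgnc_id))
            source_rows.append(("consequence", f"{rcv}|{measure_id}", ""))
        else:  # unsupported
            measure = VariantMeasure(
                measure_id=measure_id,
                variant_type="Variation",
                hgvs_expressions=(f"NP_{i:06d}.1:p.Ala123Thr",),
            )
            fixture.measure_truth.append(
                MeasureTruth(rcv, measure_id, "unsupported", (), "")
            )
            source_rows.append(("gene", f"{rcv}|{measure_id}", ""))
            source_rows.append(("consequence", f"{rcv}|{measure_id}", ""))

        records.append(
            ClinVarRecord(
                rcv_accession=rcv,
                measures=(measure,),
                traits=(trait,),
                clinical_significance=rng.choice(
                    ["Pathogenic", "Likely pathogenic", "Uncertain significance", "Benign"]
                ),
                review_status="criteria provided, single submitter",
            )
        )

    # --- write everything
    write_annotated_xml(records, fixture.release_xml)
    _write_obo(fixture.ontology, terms, include_demo=demo)

    xref_lines = ["source_db\tsource_id\ttarget_curie\tmapping_type"]
    for t in terms:
        if not t.obsolete:
            xref_lines.append(f"MedGen\t{t.medgen}\t{t.curie}\texact")
    # a two-hop chain through an intermediate ontology
    xref_lines.append("MedGen\tC7700000\tMONDO:0099001\texact")
    xref_lines.append(f"MONDO\t0099001\t{terms[0].curie}\texact")
    fixture.xref_table.write_text("\n".join(xref_lines) + "\n", encoding="utf-8")

    fixture.repository.write_text(
        "trait_text\tcurie\tlabel\tstatus\tactive\ttimestamp\n", encoding="utf-8"
    )

    with open(fixture.genome_fasta, "w", encoding="utf-8") as fh:
        for chrom in sorted(genome, key=int):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")

    _write_gff3(fixture.genes_gff3, genes, genome)

    fixture.accession_map.write_text(
        "accession\tchrom\n"
        + "".join(f"{acc}\t{c}\n" for c, acc in sorted(accessions.items(), key=lambda x: int(x[0]))),
        encoding="utf-8",
    )
    fixture.gene_map.write_text(
        "hgnc_id\tensembl_gene_id\tgene_symbol\n"
        + "".join(
            f"{g.hgnc_id}\t{g.model.gene_id}\t{g.model.gene_symbol}\n" for g in genes
        ),
        encoding="utf-8",
    )
    fixture.source_annotations.write_text(
        "kind\tkey\tvalue\n"
        + "".join(f"{k}\t{key}\t{v}\n" for k, key, v in source_rows),
        encoding="utf-8",
    )

    _write_truth(fixture)

    with open(fixture.manifest, "w", encoding="utf-8") as fh:
        entries = [
            {"artifact": "release_xml", "path": fixture.release_xml.name},
            {"artifact": "ontology", "path": fixture.ontology.name},
            {"artifact": "xref_table", "path": fixture.xref_table.name},
            {"artifact": "repository", "path": fixture.repository.name},
            {"artifact": "genome_fasta", "path": fixture.genome_fasta.name},
            {"artifact": "genes_gff3", "path": fixture.genes_gff3.name},
            {"artifact": "accession_map", "path": fixture.accession_map.name},
            {"artifact": "gene_map", "path": fixture.gene_map.name},
            {"artifact": "source_annotations", "path": fixture.source_annotations.name},
            {"artifact": "truth_traits", "path": "truth_traits.tsv"},
            {"artifact": "truth_measures", "path": "truth_measures.tsv"},
            {"artifact": "seed", "value": spec.seed},
            {"artifact": "n_records", "value": spec.n_records},
        ]
        for e in entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")

    # self-consistency: every coding transcript translates to a stop-terminated protein
    for g in genes:
        protein = _translate_model(g.model, genome)
        assert protein.endswith("*") and "*" not in protein[:-1], (
            f"{g.model.gene_id} CDS is not a clean ORF"
        )
    return fixture


def _translate_model(t: TranscriptModel, genome: dict) -> str:
    positions = t.cds_genomic_positions()
    bases = "".join(genome[t.chrom][p - 1] for p in positions)
    if t.strand == "-":
        bases = "".join(b.translate(str.maketrans("ACGTN", "TGCAN")) for b in bases)
    return "".join(
        CODON_TABLE.get(bases[i : i + 3], "X") for i in range(0, len(bases) - 2, 3)
    )


def _write_gff3(path: Path, genes: list[_Gene], genome: dict) -> None:
    lines = ["##gff-version 3"]
    for chrom in sorted(genome, key=int):
        lines.append(f"##sequence-region {chrom} 1 {len(genome[chrom])}")
    for g in genes:
        t = g.model
        attrs = f"ID={t.gene_id};Name={t.gene_symbol}"
        lines.append(
            f"{t.chrom}\tfixture\tgene\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{t.chrom}\tfixture\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
            f"ID={t.transcript_id};Parent={t.gene_id}"
        )
        for n, (s, e) in enumerate(t.exons, 1):
            lines.append(
                f"{t.chrom}\tfixture\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id}.exon{n};Parent={t.transcript_id}"
            )
        cds_pieces = [
            (max(s, t.cds_start), min(e, t.cds_end))
            for s, e in t.exons
            if e >= t.cds_start and s <= t.cds_end
        ]
        ordered = cds_pieces if t.strand == "+" else cds_pieces[::-1]
        running = 0
        phased = []
        for s, e in ordered:
            phased.append((s, e, (3 - running % 3) % 3))
            running += e - s + 1
        for s, e, phase in sorted(phased):
            lines.append(
                f"{t.chrom}\tfixture\tCDS\t{s}\t{e}\t.\t{t.strand}\t{phase}\t"
                f"ID=cds_{t.transcript_id};Parent={t.transcript_id}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_truth(fixture: FixtureSet) -> None:
    with open(fixture.out_dir / "truth_traits.tsv", "w", encoding="utf-8") as fh:
        fh.write("rcv\ttrait_text\texpected_status\texpected_curie\n")
        for t in fixture.trait_truth:
            fh.write(f"{t.rcv}\t{t.trait_text}\t{t.expected_status}\t{t.expected_curie}\n")
    with open(fixture.out_dir / "truth_measures.tsv", "w", encoding="utf-8") as fh:
        fh.write("rcv\tmeasure_id\texpected_class\texpected_genes\texpected_so_term\n")
        for m in fixture.measure_truth:
            fh.write(
                f"{m.rcv}\t{m.measure_id}\t{m.expected_class}\t"
                f"{','.join(m.expected_genes)}\t{m.expected_so_term}\n"
            )
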