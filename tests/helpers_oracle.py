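"""Independent brute-force consequence oracle used by the unit and
acceptance tests.

Deliberately shares no code with the package's engine: region logic is a
plain linear scan over exon intervals, and coding calls come from mutating
the genome and translating the complete CDS with Biopython, then comparing
the two proteins.
"""

import random

from Bio.Seq import Seq

from clinannot.consequence import GeneIndex, TranscriptModel, predict_consequences
from clinannot.clinvar_io import GenomicSpan

SPLICE_SITE = 2
SPLICE_REGION = 8


def oracle_term(t: TranscriptModel, genome: dict, pos: int, alt: str):
    """Expected SO term for an SNV at `pos` with alternate `alt`, or None
    when the position lies outside the transcript entirely."""
    exons = t.exons
    if not (t.start <= pos <= t.end):
        return None
    if not any(s <= pos <= e for s, e in exons):
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < pos < s2:
                d_left, d_right = pos - e1, s2 - pos
                donor = d_left if t.strand == "+" else d_right
                acceptor = d_right if t.strand == "+" else d_left
                if donor <= SPLICE_SITE:
                    return "splice_donor_variant"
                if acceptor <= SPLICE_SITE:
                    return "splice_acceptor_variant"
                if min(d_left, d_right) <= SPLICE_REGION:
                    return "splice_region_variant"
                return "intron_variant"
        raise AssertionError("unreachable")
    if not t.coding:
        return "non_coding_transcript_exon_variant"
    if pos < t.cds_start:
        return "5_prime_UTR_variant" if t.strand == "+" else "3_prime_UTR_variant"
    if pos > t.cds_end:
        return "3_prime_UTR_variant" if t.strand == "+" else "5_prime_UTR_variant"

    def cds_of(sequences: dict) -> Seq:
        parts = [
            sequences[t.chrom][max(s, t.cds_start) - 1 : min(e, t.cds_end)]
            for s, e in exons
            if e >= t.cds_start and s <= t.cds_end
        ]
        seq = Seq("".join(parts))
        return seq.reverse_complement() if t.strand == "-" else seq

    chrom_seq = genome[t.chrom]
    mutated = dict(genome)
    mutated[t.chrom] = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]
    ref_cds, alt_cds = cds_of(genome), cds_of(mutated)
    ref_protein = str(ref_cds.translate())
    alt_protein = str(alt_cds.translate())

    ascending = [
        p
        for s, e in exons
        for p in range(max(s, t.cds_start), min(e, t.cds_end) + 1)
    ]
    idx = ascending.index(pos)
    if t.strand == "-":
        idx = len(ascending) - 1 - idx
    codon_i = idx // 3
    if codon_i == 0 and str(alt_cds[0:3]) != "ATG":
        return "start_lost"
    ref_aa, alt_aa = ref_protein[codon_i], alt_protein[codon_i]
    if ref_aa == alt_aa:
        return "synonymous_variant"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense_variant"


def make_oracle_transcript(seed: int, strand: str, chrom_len: int = 2400):
    """A multi-exon coding transcript over a random genome, transcription-
    order start codon forced to ATG, CDS length a multiple of three."""
    rng = random.Random(seed)
    seq = list("".join(rng.choice("ACGT") for _ in range(chrom_len)))
    exons = ((151, 650), (801, 1500), (1701, 2100))
    cds_start, cds_end = 301, 1850
    # CDS length across exons: (650-301+1) + (1500-801+1) + (1850-1701+1) = 1200
    positions = [
        p
        for s, e in exons
        for p in range(max(s, cds_start), min(e, cds_end) + 1)
    ]
    ordered = positions if strand == "+" else positions[::-1]
    start_codon = "ATG" if strand == "+" else "ATG"
    for offset, base in enumerate(start_codon):
        p = ordered[offset]
        seq[p - 1] = base if strand == "+" else {"A": "T", "T": "A", "G": "C", "C": "G"}[base]
    genome = {"1": "".join(seq)}
    model = TranscriptModel(
        gene_id="ENSG00000000777",
        transcript_id="ENST00000000777",
        chrom="1",
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        gene_symbol="ORACLE1",
    )
    return model, genome


def engine_term(model: TranscriptModel, genome: dict, pos: int, alt: str):
    """SO term the package engine assigns (None for gene-less intergenic)."""
    ref = genome[model.chrom][pos - 1]
    span = GenomicSpan("GRCh38", model.chrom, pos, pos, ref=ref, alt=alt)
    anns, errors = predict_consequences(
        [("m", span)], GeneIndex([model]), genome
    )
    assert not errors
    assert len(anns) == 1
    return anns[0].so_term_name if anns[0].gene_id else None


def exhaustive_compare(model: TranscriptModel, genome: dict, start: int, stop: int):
    """Compare engine and oracle for every position × substitution in
    [start, stop]; returns the number of comparisons performed."""
    n = 0
    chrom_seq = genome[model.chrom]
    for pos in range(start, stop + 1):
        ref = chrom_seq[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            expected = oracle_term(model, genome, pos, alt)
            got = engine_term(model, genome, pos, alt)
            assert got == expected, (pos, ref, alt, got, expected)
            n += 1
    return n
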