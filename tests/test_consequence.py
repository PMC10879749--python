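"""Variant classes, repeat rule, gene overlap, and the local engine."""

import pytest

from helpers_oracle import engine_term, exhaustive_compare, make_oracle_transcript
from clinannot.clinvar_io import GenomicSpan, VariantMeasure
from clinannot.consequence import (
    ConfigurationError,
    ConsequenceAnnotation,
    GeneIndex,
    TranscriptModel,
    annotate_repeat,
    classify_repeat,
    classify_variant,
    genes_overlapping,
    load_severity_rank,
    most_severe,
    predict_consequences,
    reverse_complement,
    so_accession,
)
from clinannot.hgvs import parse_hgvs


def measure(**kwargs):
    defaults = dict(measure_id="m1", variant_type="single nucleotide variant")
    defaults.update(kwargs)
    return VariantMeasure(**defaults)


class TestClassifyVariant:
    def test_precise_snv_is_simple(self):
        m = measure(spans=(GenomicSpan("GRCh38", "12", 54283899, 54283899, "A", "G"),))
        assert classify_variant(m) == "simple"

    def test_repeat_hgvs_wins_over_everything(self):
        m = measure(
            variant_type="Microsatellite",
            spans=(GenomicSpan("GRCh38", "4", 3074877, 3074877, "G", "A"),),
            hgvs_expressions=("NC_000004.12:g.3074877GCA[28]",),
        )
        assert classify_variant(m) == "repeat_expansion"

    def test_large_precise_deletion_is_structural(self):
        m = measure(
            variant_type="Deletion",
            spans=(GenomicSpan("GRCh38", "1", 1000, 101000),),
        )
        assert classify_variant(m, structural_length_threshold=50) == "structural_precise"

    def test_unparsable_only_hgvs_is_unsupported(self):
        m = measure(variant_type="Variation", hgvs_expressions=("NP_1.1:p.Ala1Thr",))
        assert classify_variant(m) == "unsupported"

    def test_totality_every_measure_gets_one_class(self):
        measures = [
            measure(spans=(GenomicSpan("GRCh38", "1", 5, 5, "A", "T"),)),
            measure(hgvs_expressions=("NC_000001.11:g.5CAG[40]",)),
            measure(variant_type="Deletion", spans=(GenomicSpan("GRCh38", "1", 5, 500),)),
            measure(hgvs_expressions=("junk",)),
        ]
        classes = [classify_variant(m) for m in measures]
        assert all(
            c in ("simple", "structural_precise", "repeat_expansion", "unsupported")
            for c in classes
        )
        assert len(classes) == 4


class TestClassifyRepeat:
    @pytest.mark.parametrize("unit_len", range(1, 13))
    @pytest.mark.parametrize("rule", ["mod3", "eq3"])
    def test_unit_length_rule_exhaustive(self, unit_len, rule):
        parsed = parse_hgvs(f"NC_000001.11:g.100{'A' * unit_len}[40]")
        result = classify_repeat(parsed, rule=rule)
        trinucleotide = (unit_len % 3 == 0) if rule == "mod3" else (unit_len == 3)
        expected = (
            "trinucleotide_repeat_expansion"
            if trinucleotide
            else "short_tandem_repeat_expansion"
        )
        assert result.so_term_name == expected
        assert result.so_accession == so_accession(expected)
        assert not result.low_confidence

    def test_hexanucleotide_unit_depends_on_rule(self):
        parsed = parse_hgvs("NC_000009.12:g.27573529GGGGCC[400]")
        assert classify_repeat(parsed, "mod3").so_term_name == "trinucleotide_repeat_expansion"
        assert classify_repeat(parsed, "eq3").so_term_name == "short_tandem_repeat_expansion"

    def test_unknown_unit_low_confidence(self):
        parsed = parse_hgvs("NC_000001.11:g.100(55_200)")
        result = classify_repeat(parsed)
        assert result.so_term_name == "short_tandem_repeat_expansion"
        assert result.low_confidence

    def test_non_repeat_precondition(self):
        parsed = parse_hgvs("NC_000001.11:g.100A>G")
        with pytest.raises(ValueError):
            classify_repeat(parsed)


def two_gene_index():
    g1 = TranscriptModel(
        gene_id="G1", transcript_id="T1", chrom="1", strand="+",
        exons=((100, 200), (300, 400)),
    )
    g2 = TranscriptModel(
        gene_id="G2", transcript_id="T2", chrom="1", strand="-",
        exons=((450, 600),),
    )
    return GeneIndex([g1, g2])


class TestGenesOverlapping:
    def test_span_inside_gene_body(self):
        span = GenomicSpan("GRCh38", "1", 250, 260)  # intronic but in body
        assert genes_overlapping(span, two_gene_index()) == ["G1"]

    def test_bridging_span_positional_order(self):
        span = GenomicSpan("GRCh38", "1", 350, 500)
        assert genes_overlapping(span, two_gene_index()) == ["G1", "G2"]

    def test_intergenic_span_empty(self):
        assert genes_overlapping(GenomicSpan("GRCh38", "1", 410, 440), two_gene_index()) == []

    def test_unknown_chromosome_empty(self):
        assert genes_overlapping(GenomicSpan("GRCh38", "99", 1, 10), two_gene_index()) == []

    def test_matches_brute_force_scan(self):
        index = two_gene_index()
        bodies = {"G1": (100, 400), "G2": (450, 600)}
        for start in range(80, 620, 7):
            span = GenomicSpan("GRCh38", "1", start, start + 30)
            expected = sorted(
                (lo, g) for g, (lo, hi) in bodies.items()
                if lo <= span.stop and hi >= span.start
            )
            assert genes_overlapping(span, index) == [g for _, g in expected]


class TestLocalEngine:
    def test_known_cases_plus_strand(self):
        model, genome = make_oracle_transcript(seed=11, strand="+")
        # position 2 of the start codon always destroys it
        assert engine_term(model, genome, model.cds_start + 1, "C") == "start_lost"
        # first intron donor site
        donor_pos = model.exons[0][1] + 1
        assert engine_term(model, genome, donor_pos, _other(genome, donor_pos)) == (
            "splice_donor_variant"
        )
        # deep intron
        deep = (model.exons[0][1] + model.exons[1][0]) // 2
        assert engine_term(model, genome, deep, _other(genome, deep)) == "intron_variant"
        # upstream of CDS in exon 1
        utr = model.cds_start - 20
        assert engine_term(model, genome, utr, _other(genome, utr)) == "5_prime_UTR_variant"

    def test_exhaustive_sample_against_oracle_both_strands(self):
        # the full-transcript sweep runs in the acceptance suite; here a
        # representative window over each strand keeps the unit suite quick
        for strand in "+-":
            model, genome = make_oracle_transcript(seed=5, strand=strand)
            exhaustive_compare(model, genome, 290, 360)
            exhaustive_compare(model, genome, 640, 680)

    def test_reference_mismatch_skips_variant_not_run(self):
        model, genome = make_oracle_transcript(seed=3, strand="+")
        pos = model.cds_start + 30
        wrong = _other(genome, pos)
        span = GenomicSpan("GRCh38", "1", pos, pos, ref=wrong, alt="A" if wrong != "A" else "C")
        good_pos = model.cds_start + 33
        good = GenomicSpan(
            "GRCh38", "1", good_pos, good_pos,
            ref=genome["1"][good_pos - 1], alt=_other(genome, good_pos),
        )
        anns, errors = predict_consequences(
            [("bad", span), ("good", good)], GeneIndex([model]), genome
        )
        assert [e.measure_id for e in errors] == ["bad"]
        assert {a.measure_id for a in anns} == {"good"}

    def test_strand_symmetry_of_terms(self):
        """Mirroring the genome and flipping the strand preserves SO terms."""
        model, genome = make_oracle_transcript(seed=21, strand="+")
        L = len(genome["1"])
        mirrored_genome = {"1": reverse_complement(genome["1"])}
        mirrored = TranscriptModel(
            gene_id=model.gene_id, transcript_id=model.transcript_id,
            chrom="1", strand="-",
            exons=tuple(sorted((L + 1 - e, L + 1 - s) for s, e in model.exons)),
            cds_start=L + 1 - model.cds_end, cds_end=L + 1 - model.cds_start,
            gene_symbol=model.gene_symbol,
        )
        for pos in range(model.start, model.end + 1, 13):
            ref = genome["1"][pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                direct = engine_term(model, genome, pos, alt)
                mirrored_term = engine_term(
                    mirrored, mirrored_genome, L + 1 - pos, reverse_complement(alt)
                )
                assert direct == mirrored_term, (pos, alt)


def _other(genome, pos):
    ref = genome["1"][pos - 1]
    return "A" if ref != "A" else "G"


class TestMostSevere:
    def _ann(self, term, transcript="T1", gene="G1"):
        return ConsequenceAnnotation(
            measure_id="m1", gene_id=gene, so_term_name=term,
            so_accession=so_accession(term), backend="local",
            transcript_id=transcript,
        )

    def test_most_severe_kept(self):
        result = most_severe([self._ann("synonymous_variant"), self._ann("missense_variant", "T2")])
        assert [a.so_term_name for a in result] == ["missense_variant"]

    def test_single_annotation_unchanged(self):
        ann = self._ann("intron_variant")
        assert most_severe([ann]) == [ann]

    def test_tie_breaks_to_lower_transcript_id(self):
        result = most_severe(
            [self._ann("missense_variant", "T9"), self._ann("missense_variant", "T2")]
        )
        assert result[0].transcript_id == "T2"

    def test_unknown_term_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            most_severe([self._ann("missense_variant")], severity_rank=["stop_gained"])

    def test_rank_table_covers_all_emittable_terms(self):
        rank = set(load_severity_rank())
        emitted = {
            "missense_variant", "synonymous_variant", "stop_gained", "stop_lost",
            "start_lost", "frameshift_variant", "inframe_insertion",
            "inframe_deletion", "splice_donor_variant", "splice_acceptor_variant",
            "splice_region_variant", "intron_variant", "5_prime_UTR_variant",
            "3_prime_UTR_variant", "non_coding_transcript_exon_variant",
            "intergenic_variant", "trinucleotide_repeat_expansion",
            "short_tandem_repeat_expansion", "deletion", "duplication",
            "insertion", "indel",
        }
        assert emitted <= rank


class TestRepeatAnnotation:
    def test_imprecise_location_resolved_to_outer_bounds(self):
        index = two_gene_index()
        m = measure(
            variant_type="Microsatellite",
            hgvs_expressions=("NC_900001.1:g.(250_320)CAG[40]",),
        )
        anns = annotate_repeat(m, index, accession_chrom={"NC_900001.1": "1"})
        assert [a.gene_id for a in anns] == ["G1"]
        assert anns[0].so_term_name == "trinucleotide_repeat_expansion"
        assert anns[0].backend == "repeat_rule"
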