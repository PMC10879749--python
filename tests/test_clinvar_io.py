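"""Reader/writer contracts for the release-XML dialect."""

import gzip
import io

import pytest

from clinannot.clinvar_io import (
    AnnotatedRecord,
    ClinVarParseError,
    ClinVarRecord,
    ColumnSpecError,
    GenomicSpan,
    TraitRecord,
    VariantMeasure,
    canonical_xml,
    record_to_rows,
    stream_records,
    write_annotated_xml,
)
from clinannot.trait_mapping import TraitMapping

THREE_RECORD_XML = b"""<?xml version="1.0" encoding="UTF-8"?>
<ReleaseSet>
  <ClinVarSet>
    <ReferenceClinVarAssertion>
      <ClinVarAccession Acc="RCV000000001.2" Type="RCV"/>
      <ClinicalSignificance>
        <ReviewStatus>criteria provided, single submitter</ReviewStatus>
        <Description>Pathogenic</Description>
      </ClinicalSignificance>
      <MeasureSet Type="Variant">
        <Measure Type="single nucleotide variant" ID="15041">
          <AttributeSet>
            <Attribute Type="HGVS, genomic, top level">NC_000012.12:g.54283899A&gt;G</Attribute>
          </AttributeSet>
          <SequenceLocation Assembly="GRCh38" Chr="12" start="54283899" stop="54283899" referenceAllele="A" alternateAllele="G"/>
          <MeasureRelationship Type="within single gene">
            <Symbol><ElementValue Type="Preferred">HNRNPA1</ElementValue></Symbol>
            <XRef DB="HGNC" ID="HGNC:4035"/>
          </MeasureRelationship>
          <UnknownFutureElement attr="kept"/>
        </Measure>
      </MeasureSet>
      <TraitSet Type="Disease">
        <Trait Type="Disease">
          <Name><ElementValue Type="Preferred">Relapsing remitting multiple sclerosis</ElementValue></Name>
          <Name><ElementValue Type="Alternate">RRMS</ElementValue></Name>
          <XRef DB="MedGen" ID="C0751967"/>
        </Trait>
      </TraitSet>
    </ReferenceClinVarAssertion>
  </ClinVarSet>
  <ClinVarSet>
    <ReferenceClinVarAssertion>
      <ClinVarAccession Acc="RCV000000002.1" Type="RCV"/>
      <MeasureSet Type="Variant">
        <Measure Type="Deletion" ID="15042">
          <SequenceLocation Assembly="GRCh38" Chr="1" start="100" stop="250"/>
        </Measure>
      </MeasureSet>
      <TraitSet Type="Disease">
        <Trait Type="Disease">
          <Name><ElementValue Type="Preferred">Some disease</ElementValue></Name>
        </Trait>
      </TraitSet>
    </ReferenceClinVarAssertion>
  </ClinVarSet>
  <ClinVarSet>
    <ReferenceClinVarAssertion>
      <ClinVarAccession Acc="RCV000000003.1" Type="RCV"/>
      <MeasureSet Type="Variant">
        <Measure Type="Microsatellite" ID="15043">
          <AttributeSet>
            <Attribute Type="HGVS, genomic, top level">NC_000004.12:g.3074877GCA[28]</Attribute>
          </AttributeSet>
        </Measure>
      </MeasureSet>
      <TraitSet Type="Disease">
        <Trait Type="Disease"/>
      </TraitSet>
    </ReferenceClinVarAssertion>
  </ClinVarSet>
</ReleaseSet>
"""


class TestStreamRecords:
    def test_document_order_and_count(self):
        records = list(stream_records(io.BytesIO(THREE_RECORD_XML)))
        assert [r.rcv_accession for r in records] == [
            "RCV000000001.2",
            "RCV000000002.1",
            "RCV000000003.1",
        ]

    def test_field_extraction_matches_raw_xml(self):
        record = next(stream_records(io.BytesIO(THREE_RECORD_XML)))
        measure = record.measures[0]
        assert measure.measure_id == "15041"
        assert measure.hgnc_ids == ("HGNC:4035",)
        assert measure.gene_symbols == ("HNRNPA1",)
        assert measure.hgvs_expressions == ("NC_000012.12:g.54283899A>G",)
        assert measure.spans[0] == GenomicSpan(
            "GRCh38", "12", 54283899, 54283899, "A", "G"
        )
        trait = record.traits[0]
        assert trait.preferred_name == "Relapsing remitting multiple sclerosis"
        assert trait.alternate_names == ("RRMS",)
        assert ("MedGen", "C0751967") in trait.xrefs
        assert record.clinical_significance == "Pathogenic"

    def test_empty_release_yields_nothing(self):
        assert list(stream_records(io.BytesIO(b"<ReleaseSet/>"))) == []

    def test_record_without_parsable_trait_flagged_not_dropped(self):
        records = list(stream_records(io.BytesIO(THREE_RECORD_XML)))
        assert records[2].traits == ()
        assert "empty-trait" in records[2].warnings

    def test_malformed_xml_is_fatal(self):
        with pytest.raises(ClinVarParseError):
            list(stream_records(io.BytesIO(b"<ReleaseSet><ClinVarSet>")))

    def test_gzip_input_sniffed(self, tmp_path):
        path = tmp_path / "release.xml.gz"
        path.write_bytes(gzip.compress(THREE_RECORD_XML))
        assert len(list(stream_records(path))) == 3

    def test_elements_detached_during_streaming(self):
        gen = stream_records(io.BytesIO(THREE_RECORD_XML))
        first = next(gen)
        next(gen)
        # once the consumer advances, earlier subtrees are out of the document
        assert first.source_element.getparent() is None


class TestRoundTrip:
    def test_parse_write_parse_field_identical(self, tmp_path):
        records = list(stream_records(io.BytesIO(THREE_RECORD_XML)))
        out = tmp_path / "roundtrip.xml"
        assert write_annotated_xml(records, out) == 3
        assert list(stream_records(out)) == records

    def test_canonicalized_bytes_equal_without_annotations(self, tmp_path):
        records = list(stream_records(io.BytesIO(THREE_RECORD_XML)))
        out = tmp_path / "roundtrip.xml"
        write_annotated_xml(records, out)
        assert canonical_xml(THREE_RECORD_XML) == canonical_xml(out)

    def test_unknown_elements_preserved_verbatim(self, tmp_path):
        records = list(stream_records(io.BytesIO(THREE_RECORD_XML)))
        out = tmp_path / "roundtrip.xml"
        write_annotated_xml(records, out)
        assert b"UnknownFutureElement" in out.read_bytes()

    def test_zero_records_valid_empty_root(self, tmp_path):
        out = tmp_path / "empty.xml"
        assert write_annotated_xml([], out) == 0
        assert list(stream_records(out)) == []


class TestAnnotatedWrite:
    def _annotated(self):
        record = next(stream_records(io.BytesIO(THREE_RECORD_XML)))
        mapping = TraitMapping(
            trait_text="Relapsing remitting multiple sclerosis",
            term_uri="http://www.ebi.ac.uk/efo/EFO_0003929",
            term_label="Relapsing remitting multiple sclerosis",
            confidence="AUTO_EXACT_LABEL",
            source="label",
        )
        return AnnotatedRecord(record=record, trait_annotations=(mapping,))

    def test_single_injected_annotation_with_uri(self, tmp_path):
        out = tmp_path / "annotated.xml"
        write_annotated_xml([self._annotated()], out)
        text = out.read_text()
        assert text.count("TraitAnnotation") == 1
        assert "http://www.ebi.ac.uk/efo/EFO_0003929" in text
        assert 'provenance="label"' in text

    def test_reparsing_annotated_output_recovers_records(self, tmp_path):
        annotated = self._annotated()
        out = tmp_path / "annotated.xml"
        write_annotated_xml([annotated], out)
        assert list(stream_records(out)) == [annotated.record]

    def test_annotation_references_must_resolve(self):
        record = next(stream_records(io.BytesIO(THREE_RECORD_XML)))
        stray = TraitMapping(
            trait_text="not in this record",
            term_uri="u",
            term_label="l",
            confidence="CURATED",
            source="curator",
        )
        with pytest.raises(ValueError):
            AnnotatedRecord(record=record, trait_annotations=(stray,))


class TestRecordToRows:
    def _annotated(self):
        record = ClinVarRecord(
            rcv_accession="RCV000000010.1",
            measures=(
                VariantMeasure(
                    measure_id="m1",
                    variant_type="single nucleotide variant",
                    spans=(GenomicSpan("GRCh38", "12", 54283899, 54283899, "A", "G"),),
                ),
            ),
            traits=(
                TraitRecord(preferred_name="Trait one"),
                TraitRecord(preferred_name="Trait two"),
            ),
        )
        return AnnotatedRecord(record=record)

    def test_one_row_per_measure_trait_pair(self):
        rows = record_to_rows(self._annotated(), ["rcv", "trait_name"])
        assert rows == ["RCV000000010.1\tTrait one", "RCV000000010.1\tTrait two"]

    def test_unknown_selector_lists_valid_ones(self):
        with pytest.raises(ColumnSpecError, match="trait_name"):
            record_to_rows(self._annotated(), ["nonsense"])

    def test_empty_column_spec_rejected(self):
        with pytest.raises(ColumnSpecError):
            record_to_rows(self._annotated(), [])

    def test_delimiter_containing_fields_quoted(self):
        annotated = self._annotated()
        record = annotated.record
        object.__setattr__(record.traits[0], "__dict__", record.traits[0].__dict__)
        rows = record_to_rows(annotated, ["trait_name", "ref"], delimiter="o")
        assert rows[0].startswith('"Trait one"')


class TestSpanValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(start=0, stop=5),
            dict(start=10, stop=5),
            dict(start=1, stop=1, ref="AX"),
        ],
    )
    def test_invalid_spans_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicSpan("GRCh38", "1", **{"ref": None, **kwargs})
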