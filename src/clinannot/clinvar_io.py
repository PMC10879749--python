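"""Streaming reader/writer for the ClinVar full-release XML dialect.

ClinVar distributes its archive as a large XML file whose root ``ReleaseSet``
holds one ``ClinVarSet`` element per RCV record (a reference assertion about
one variant/condition pair).  This module parses that dialect into a small
typed record model, and writes it back out — optionally decorated with trait
and consequence annotations in a dedicated namespace — without losing any of
the original content.

Only the RCV (``ClinVarSet``/``ReferenceClinVarAssertion``) release dialect is
supported; the VCV and SCV schemas are out of scope.  All coordinates are
1-based fully closed, matching ClinVar ``SequenceLocation`` attributes.
"""

from __future__ import annotations

import copy
import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union
from xml.etree.ElementTree import canonicalize as _c14n

from lxml import etree

__all__ = [
    "GenomicSpan",
    "VariantMeasure",
    "TraitRecord",
    "ClinVarRecord",
    "AnnotatedRecord",
    "ClinVarParseError",
    "ColumnSpecError",
    "stream_records",
    "write_annotated_xml",
    "record_to_rows",
    "record_to_element",
    "canonical_xml",
    "ROW_SELECTORS",
    "ANNOTATION_NS",
]

#: Namespace for annotation elements injected into the output XML.
ANNOTATION_NS = "http://clinannot.org/annotations/1.0"
_ANN = "{%s}" % ANNOTATION_NS

#: Trait cross-reference databases we expect to see.  Unknown labels are kept
#: (never dropped) but flagged in the record warnings.
KNOWN_XREF_DBS = frozenset(
    {
        "MedGen",
        "OMIM",
        "Orphanet",
        "MONDO",
        "EFO",
        "MeSH",
        "Human Phenotype Ontology",
        "SNOMED CT",
        "GeneReviews",
        "Office of Rare Diseases",
    }
)

_RCV_RE = re.compile(r"RCV\d+\.\d+$")
_NUC_RE = re.compile(r"^[ACGTN]+$")


class ClinVarParseError(Exception):
    """Fatal XML parse error; carries the byte offset when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset ~{offset})"
        super().__init__(message)


class ColumnSpecError(ValueError):
    """Unknown selector in a tabular column specification."""


@dataclass(frozen=True)
class GenomicSpan:
    """A located allele on one assembly; 1-based, fully closed."""

    assembly: str
    chrom: str
    start: int
    stop: int
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.stop < self.start:
            raise ValueError(f"stop {self.stop} < start {self.start}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if allele is not None and not _NUC_RE.match(allele):
                raise ValueError(f"{name} {allele!r} is not over ACGTN")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class VariantMeasure:
    """One Measure of a record: the variant, in as many notations as given."""

    measure_id: str
    variant_type: str
    spans: tuple[GenomicSpan, ...] = ()
    hgvs_expressions: tuple[str, ...] = ()
    gene_symbols: tuple[str, ...] = ()
    hgnc_ids: tuple[str, ...] = ()

    def preferred_span(self, assembly: Optional[str] = None) -> Optional[GenomicSpan]:
        """The span on `assembly`, else the first span with ref+alt, else the first."""
        if assembly is not None:
            for s in self.spans:
                if s.assembly == assembly:
                    return s
            return None
        for s in self.spans:
            if s.ref is not None and s.alt is not None:
                return s
        return self.spans[0] if self.spans else None


@dataclass(frozen=True)
class TraitRecord:
    preferred_name: str
    alternate_names: tuple[str, ...] = ()
    xrefs: tuple[tuple[str, str], ...] = ()  # (database label, identifier)

    def __post_init__(self):
        if not self.preferred_name:
            raise ValueError("preferred_name must be non-empty")


@dataclass
class ClinVarRecord:
    rcv_accession: str
    measures: tuple[VariantMeasure, ...] = ()
    traits: tuple[TraitRecord, ...] = ()
    clinical_significance: str = ""
    review_status: str = ""
    warnings: tuple[str, ...] = ()
    #: original XML element, preserved verbatim for lossless re-serialization
    source_element: Optional[etree._Element] = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self):
        if not _RCV_RE.match(self.rcv_accession):
            raise ValueError(f"bad RCV accession: {self.rcv_accession!r}")


@dataclass
class AnnotatedRecord:
    """A record plus the annotations the pipeline attached to it."""

    record: ClinVarRecord
    trait_annotations: tuple = ()  # of trait_mapping.TraitMapping
    consequence_annotations: tuple = ()  # of consequence.ConsequenceAnnotation

    def __post_init__(self):
        trait_texts = {t.preferred_name for t in self.record.traits}
        for ta in self.trait_annotations:
            if ta.trait_text not in trait_texts:
                raise ValueError(
                    f"trait annotation {ta.trait_text!r} references no record trait"
                )
        measure_ids = {m.measure_id for m in self.record.measures}
        for ca in self.consequence_annotations:
            if ca.measure_id not in measure_ids:
                raise ValueError(
                    f"consequence annotation references unknown measure {ca.measure_id!r}"
                )


# ---------------------------------------------------------------------------
# reading


def _open_source(source) -> IO[bytes]:
    if isinstance(source, (str, Path)):
        fh = open(source, "rb")
    else:
        fh = source
    head = fh.read(2)
    if hasattr(fh, "seek"):
        fh.seek(0)
        if head == b"\x1f\x8b":
            return gzip.open(fh, "rb")
        return fh
    # non-seekable stream: stitch the head back on
    rest = fh
    joined = io.BytesIO(head)
    stream = _ConcatStream(joined, rest)
    if head == b"\x1f\x8b":
        return gzip.open(stream, "rb")
    return stream


class _ConcatStream(io.RawIOBase):
    def __init__(self, first, second):
        self._first, self._second = first, second

    def readable(self):
        return True

    def read(self, n=-1):
        buf = self._first.read(n)
        if buf:
            return buf
        return self._second.read(n)


def _text(elem: Optional[etree._Element]) -> str:
    return (elem.text or "").strip() if elem is not None else ""


def _parse_measure(melem: etree._Element, warnings: list[str]) -> VariantMeasure:
    spans = []
    for loc in melem.findall("SequenceLocation"):
        start = loc.get("start")
        stop = loc.get("stop")
        if start is None or stop is None:
            continue
        ref = loc.get("referenceAllele") or None
        alt = loc.get("alternateAllele") or None
        if ref is not None and not _NUC_RE.match(ref):
            ref = None
        if alt is not None and not _NUC_RE.match(alt):
            alt = None
        try:
            spans.append(
                GenomicSpan(
                    assembly=loc.get("Assembly", ""),
                    chrom=loc.get("Chr", ""),
                    start=int(start),
                    stop=int(stop),
                    ref=ref,
                    alt=alt,
                )
            )
        except ValueError as exc:
            warnings.append(f"bad SequenceLocation skipped: {exc}")
    hgvs = tuple(
        _text(attr)
        for attr in melem.findall("AttributeSet/Attribute")
        if (attr.get("Type") or "").startswith("HGVS") and _text(attr)
    )
    symbols: list[str] = []
    hgnc: list[str] = []
    for rel in melem.findall("MeasureRelationship"):
        for ev in rel.findall("Symbol/ElementValue"):
            if ev.get("Type") == "Preferred" and _text(ev):
                symbols.append(_text(ev))
        for xr in rel.findall("XRef"):
            if xr.get("DB") == "HGNC" and xr.get("ID"):
                hgnc.append(xr.get("ID"))
    return VariantMeasure(
        measure_id=melem.get("ID", ""),
        variant_type=melem.get("Type", ""),
        spans=tuple(spans),
        hgvs_expressions=hgvs,
        gene_symbols=tuple(dict.fromkeys(symbols)),
        hgnc_ids=tuple(dict.fromkeys(hgnc)),
    )


def _parse_trait(telem: etree._Element, warnings: list[str]) -> Optional[TraitRecord]:
    preferred = ""
    alternates: list[str] = []
    for name in telem.findall("Name"):
        for ev in name.findall("ElementValue"):
            if ev.get("Type") == "Preferred" and not preferred:
                preferred = _text(ev)
            elif ev.get("Type") == "Alternate" and _text(ev):
                alternates.append(_text(ev))
    xrefs: list[tuple[str, str]] = []
    for xr in telem.findall("XRef"):
        db, ident = xr.get("DB"), xr.get("ID")
        if not db or not ident:
            continue
        if db not in KNOWN_XREF_DBS:
            warnings.append(f"unknown trait xref database {db!r}")
        xrefs.append((db, ident))
    if not preferred:
        return None
    return TraitRecord(
        preferred_name=preferred,
        alternate_names=tuple(alternates),
        xrefs=tuple(xrefs),
    )


def _element_to_record(cvs: etree._Element) -> ClinVarRecord:
    warnings: list[str] = []
    rcva = cvs.find("ReferenceClinVarAssertion")
    if rcva is None:
        raise ClinVarParseError("ClinVarSet without ReferenceClinVarAssertion")
    acc_elem = rcva.find("ClinVarAccession")
    acc = acc_elem.get("Acc", "") if acc_elem is not None else ""
    version = acc_elem.get("Version") if acc_elem is not None else None
    if version and "." not in acc:
        acc = f"{acc}.{version}"
    measures = tuple(
        _parse_measure(m, warnings) for m in rcva.findall("MeasureSet/Measure")
    )
    traits = tuple(
        t
        for telem in rcva.findall("TraitSet/Trait")
        if (t := _parse_trait(telem, warnings)) is not None
    )
    if not traits:
        warnings.append("empty-trait")
    sig = _text(rcva.find("ClinicalSignificance/Description"))
    review = _text(rcva.find("ClinicalSignificance/ReviewStatus"))
    return ClinVarRecord(
        rcv_accession=acc,
        measures=measures,
        traits=traits,
        clinical_significance=sig,
        review_status=review,
        warnings=tuple(warnings),
        source_element=cvs,
    )


def stream_records(xml_source) -> Iterator[ClinVarRecord]:
    """Lazily yield one :class:`ClinVarRecord` per ``ClinVarSet`` element.

    Memory is bounded per record: each element subtree is detached from the
    document tree after it is converted, so only the record currently held by
    the consumer is retained.  Records whose traits could not be parsed are
    yielded with an ``"empty-trait"`` warning rather than dropped; unknown
    child elements are ignored on read but preserved for re-serialization.

    Accepts a path or binary stream; gzip input is sniffed automatically.
    """
    fh = _open_source(xml_source)
    try:
        context = etree.iterparse(fh, events=("end",), tag="ClinVarSet")
        for _event, elem in context:
            # the record keeps its own detached copy of the subtree; the
            # parsed document is pruned so it never accumulates
            detached = copy.deepcopy(elem)
            detached.tail = None
            record = _element_to_record(detached)
            yield record
            elem.clear(keep_tail=True)
            parent = elem.getparent()
            while parent is not None and elem.getprevious() is not None:
                del parent[0]
    except etree.XMLSyntaxError as exc:
        offset = getattr(exc, "position", (None, None))
        raise ClinVarParseError(f"malformed XML: {exc}", offset=None) from exc
    finally:
        if isinstance(xml_source, (str, Path)):
            fh.close()


# ---------------------------------------------------------------------------
# writing


def record_to_element(record: ClinVarRecord) -> etree._Element:
    """Synthesize a ``ClinVarSet`` element from record fields.

    Used for programmatically constructed records (e.g. fixtures); records
    read from XML keep their original element and are re-serialized verbatim.
    """
    cvs = etree.Element("ClinVarSet")
    rcva = etree.SubElement(cvs, "ReferenceClinVarAssertion")
    etree.SubElement(rcva, "ClinVarAccession", Acc=record.rcv_accession, Type="RCV")
    sig = etree.SubElement(rcva, "ClinicalSignificance")
    rs = etree.SubElement(sig, "ReviewStatus")
    rs.text = record.review_status
    desc = etree.SubElement(sig, "Description")
    desc.text = record.clinical_significance
    mset = etree.SubElement(rcva, "MeasureSet", Type="Variant")
    for m in record.measures:
        melem = etree.SubElement(mset, "Measure", Type=m.variant_type, ID=m.measure_id)
        if m.hgvs_expressions:
            aset = etree.SubElement(melem, "AttributeSet")
            for expr in m.hgvs_expressions:
                attr = etree.SubElement(aset, "Attribute", Type="HGVS, genomic, top level")
                attr.text = expr
        for span in m.spans:
            attrs = {
                "Assembly": span.assembly,
                "Chr": span.chrom,
                "start": str(span.start),
                "stop": str(span.stop),
            }
            if span.ref is not None:
                attrs["referenceAllele"] = span.ref
            if span.alt is not None:
                attrs["alternateAllele"] = span.alt
            etree.SubElement(melem, "SequenceLocation", **attrs)
        if m.gene_symbols or m.hgnc_ids:
            rel = etree.SubElement(melem, "MeasureRelationship", Type="within single gene")
            for sym in m.gene_symbols:
                symbol = etree.SubElement(rel, "Symbol")
                ev = etree.SubElement(symbol, "ElementValue", Type="Preferred")
                ev.text = sym
            for hid in m.hgnc_ids:
                etree.SubElement(rel, "XRef", DB="HGNC", ID=hid)
    tset = etree.SubElement(rcva, "TraitSet", Type="Disease")
    for t in record.traits:
        telem = etree.SubElement(tset, "Trait", Type="Disease")
        name = etree.SubElement(telem, "Name")
        ev = etree.SubElement(name, "ElementValue", Type="Preferred")
        ev.text = t.preferred_name
        for alt in t.alternate_names:
            name = etree.SubElement(telem, "Name")
            ev = etree.SubElement(name, "ElementValue", Type="Alternate")
            ev.text = alt
        for db, ident in t.xrefs:
            etree.SubElement(telem, "XRef", DB=db, ID=ident)
    return cvs


def _annotation_block(annotated: AnnotatedRecord) -> Optional[etree._Element]:
    if not annotated.trait_annotations and not annotated.consequence_annotations:
        return None
    block = etree.Element(_ANN + "Annotations", nsmap={"ca": ANNOTATION_NS})
    for ta in annotated.trait_annotations:
        elem = etree.SubElement(
            block,
            _ANN + "TraitAnnotation",
            {
                "trait": ta.trait_text,
                "uri": ta.term_uri,
                "label": ta.term_label,
                "confidence": ta.confidence,
                "provenance": ta.source,
            },
        )
        elem.tail = None
    for ca in annotated.consequence_annotations:
        attrs = {
            "measure": ca.measure_id,
            "so_term": ca.so_term_name,
            "so_accession": ca.so_accession,
            "provenance": ca.backend,
        }
        if ca.gene_id:
            attrs["gene"] = ca.gene_id
        if ca.gene_symbol:
            attrs["gene_symbol"] = ca.gene_symbol
        if ca.transcript_id:
            attrs["transcript"] = ca.transcript_id
        etree.SubElement(block, _ANN + "Consequence", attrs)
    return block


def write_annotated_xml(
    records: Iterable[Union[ClinVarRecord, AnnotatedRecord]],
    sink,
    root_tag: str = "ReleaseSet",
    root_attrib: Optional[dict] = None,
) -> int:
    """Write records back out as a release XML; returns the count written.

    Every element and attribute of each original record is preserved
    verbatim; annotations are injected as a namespaced ``Annotations`` block
    appended to the ``ClinVarSet`` element.  `sink` is a path or binary
    stream; paths ending in ``.gz`` are gzip-compressed.
    """
    own = isinstance(sink, (str, Path))
    if own:
        sink = (
            gzip.open(sink, "wb")
            if str(sink).endswith(".gz")
            else open(sink, "wb")
        )
    count = 0
    try:
        sink.write(b'<?xml version="1.0" encoding="UTF-8" standalone="yes"?>\n')
        attrs = "".join(
            f' {k}="{v}"' for k, v in sorted((root_attrib or {}).items())
        )
        sink.write(f"<{root_tag}{attrs}>\n".encode())
        for item in records:
            if isinstance(item, AnnotatedRecord):
                record, annotated = item.record, item
            else:
                record, annotated = item, None
            elem = record.source_element
            if elem is None:
                elem = record_to_element(record)
            if annotated is not None:
                block = _annotation_block(annotated)
                if block is not None:
                    elem.append(block)
            sink.write(etree.tostring(elem, encoding="utf-8"))
            sink.write(b"\n")
            if annotated is not None and elem is record.source_element:
                # leave the caller's record untouched
                for child in elem.findall(_ANN + "Annotations"):
                    elem.remove(child)
            count += 1
        sink.write(f"</{root_tag}>\n".encode())
    except OSError as exc:
        raise OSError(f"write failed after {count} records (partial output): {exc}")
    finally:
        if own:
            sink.close()
    return count


def canonical_xml(source) -> str:
    """C14N form of an XML document with insignificant whitespace stripped.

    Two releases that differ only in indentation canonicalize identically;
    used as the round-trip oracle for parse→write cycles.
    """
    if isinstance(source, bytes):
        data = source
    elif isinstance(source, (str, Path)) and "\n" not in str(source):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rb") as fh:
            data = fh.read()
    else:
        data = str(source).encode()
    return _c14n(data.decode("utf-8"), strip_text=True)


# ---------------------------------------------------------------------------
# tabular export


def _join(values) -> str:
    return ",".join(values)


def _consequences(annotated: AnnotatedRecord, measure_id: str):
    return [
        c for c in annotated.consequence_annotations if c.measure_id == measure_id
    ]


def _trait_ann(annotated: AnnotatedRecord, trait_text: str):
    for ta in annotated.trait_annotations:
        if ta.trait_text == trait_text:
            return ta
    return None


#: Selector vocabulary for :func:`record_to_rows`.  Each selector maps one
#: (measure, trait) combination to a cell value.
ROW_SELECTORS = {
    "rcv": lambda a, m, t: a.record.rcv_accession,
    "clinical_significance": lambda a, m, t: a.record.clinical_significance,
    "review_status": lambda a, m, t: a.record.review_status,
    "measure_id": lambda a, m, t: m.measure_id,
    "variant_type": lambda a, m, t: m.variant_type,
    "assembly": lambda a, m, t: (s := m.preferred_span()) and s.assembly or "",
    "chrom": lambda a, m, t: (s := m.preferred_span()) and s.chrom or "",
    "start": lambda a, m, t: str(s.start) if (s := m.preferred_span()) else "",
    "stop": lambda a, m, t: str(s.stop) if (s := m.preferred_span()) else "",
    "ref": lambda a, m, t: (s := m.preferred_span()) and (s.ref or "") or "",
    "alt": lambda a, m, t: (s := m.preferred_span()) and (s.alt or "") or "",
    "hgvs": lambda a, m, t: _join(m.hgvs_expressions),
    "gene_symbols": lambda a, m, t: _join(m.gene_symbols),
    "hgnc_ids": lambda a, m, t: _join(m.hgnc_ids),
    "trait_name": lambda a, m, t: t.preferred_name,
    "trait_xrefs": lambda a, m, t: _join(f"{db}:{i}" for db, i in t.xrefs),
    "trait_uri": lambda a, m, t: (ta := _trait_ann(a, t.preferred_name))
    and ta.term_uri
    or "",
    "trait_label": lambda a, m, t: (ta := _trait_ann(a, t.preferred_name))
    and ta.term_label
    or "",
    "trait_confidence": lambda a, m, t: (ta := _trait_ann(a, t.preferred_name))
    and ta.confidence
    or "",
    "so_term": lambda a, m, t: _join(
        sorted({c.so_term_name for c in _consequences(a, m.measure_id)})
    ),
    "so_accession": lambda a, m, t: _join(
        sorted({c.so_accession for c in _consequences(a, m.measure_id)})
    ),
    "consequence_gene": lambda a, m, t: _join(
        sorted({c.gene_id for c in _consequences(a, m.measure_id) if c.gene_id})
    ),
    "consequence_backend": lambda a, m, t: _join(
        sorted({c.backend for c in _consequences(a, m.measure_id)})
    ),
}


def record_to_rows(
    record: AnnotatedRecord,
    column_spec: Sequence[str],
    delimiter: str = "\t",
    missing: str = "",
) -> list[str]:
    """Flatten one annotated record to delimited rows, one per measure × trait.

    `column_spec` names selectors from :data:`ROW_SELECTORS`; fields that
    contain the delimiter are quoted, missing values render as `missing`.
    """
    if not column_spec:
        raise ColumnSpecError(
            "empty column spec; valid selectors: " + ", ".join(sorted(ROW_SELECTORS))
        )
    unknown = [c for c in column_spec if c not in ROW_SELECTORS]
    if unknown:
        raise ColumnSpecError(
            f"unknown selector(s) {unknown}; valid selectors: "
            + ", ".join(sorted(ROW_SELECTORS))
        )
    rows = []
    measures = record.record.measures or (None,)
    traits = record.record.traits or (None,)
    for m in measures:
        for t in traits:
            cells = []
            for col in column_spec:
                if m is None or t is None:
                    value = missing
                else:
                    value = ROW_SELECTORS[col](record, m, t) or missing
                if delimiter in value or '"' in value or "\n" in value:
                    value = '"' + value.replace('"', '""') + '"'
                cells.append(value)
            rows.append(delimiter.join(cells))
    return rows
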