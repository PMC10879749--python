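"""Orchestration: parse → map traits → annotate variants → write + metrics.

One single-process pass over the release; the three stages keep the same
boundaries as the underlying modules, so a workflow-engine wrapper could
schedule them independently without refactoring.  Also home to the release
statistics (:class:`RunMetrics`) and the concordance evaluation between
this package's annotations and the source's own (:func:`evaluate_concordance`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import clinvar_io
from .clinvar_io import AnnotatedRecord, ClinVarRecord, stream_records, write_annotated_xml
from .consequence import (
    GeneIndex,
    annotate_repeat,
    annotate_structural,
    classify_variant,
    load_gene_id_map,
    load_so_equivalence,
    load_transcripts_gff3,
    most_severe,
    predict_consequences,
)
from .ontology import (
    OntologyStore,
    XrefIndex,
    load_ontology,
    normalize,
    uri_to_curie,
    xref_closure,
)
from .trait_mapping import MappingDecision, MappingsRepository, map_trait

__all__ = [
    "RunConfig",
    "RunMetrics",
    "RunResult",
    "AnnotationSet",
    "EvaluationReport",
    "ConfigError",
    "run_annotation",
    "evaluate_concordance",
]

log = logging.getLogger("clinannot")

DEFAULT_COLUMNS = [
    "rcv",
    "measure_id",
    "variant_type",
    "chrom",
    "start",
    "stop",
    "ref",
    "alt",
    "trait_name",
    "trait_uri",
    "trait_label",
    "trait_confidence",
    "consequence_gene",
    "so_term",
    "so_accession",
    "consequence_backend",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    release_xml: str = ""
    ontology: str = ""
    xref_table: str = ""
    repository: str = ""
    gff3: str = ""
    fasta: str = ""
    accession_map: str = ""
    output: str = ""
    output_format: str = "xml"  # xml | tsv
    structural_length_threshold: int = 50
    trinucleotide_rule: str = "mod3"  # mod3 | eq3
    max_hops: int = 2
    seed: int = 0  # fixtures only; annotation itself is deterministic
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key: value`` config file; unknown keys are fatal."""
        config = cls()
        valid = {f.name for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition(":")
            if not sep:
                raise ConfigError(f"{path}:{lineno}: expected 'key: value'")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(config, key)
            setattr(config, key, type(current)(value) if not isinstance(current, str) else value)
        return config

    def validate(self) -> None:
        if self.output_format not in ("xml", "tsv"):
            raise ConfigError(f"unknown output format {self.output_format!r}")
        if self.trinucleotide_rule not in ("mod3", "eq3"):
            raise ConfigError(f"unknown trinucleotide rule {self.trinucleotide_rule!r}")
        if self.structural_length_threshold <= 0 or self.max_hops <= 0:
            raise ConfigError("thresholds must be positive")
        for name in ("release_xml", "ontology", "xref_table", "repository",
                     "gff3", "fasta", "accession_map"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if not self.release_xml or not self.ontology:
            raise ConfigError("release_xml and ontology are required")


@dataclass
class RunMetrics:
    records_total: int = 0
    traits_total: int = 0  # distinct (record, trait) pairs
    traits_mapped_current: int = 0
    traits_distinct: int = 0  # distinct normalized trait names
    traits_distinct_mapped: int = 0
    measures_total: int = 0
    measures_with_gene: int = 0
    measures_with_consequence: int = 0
    class_counts: dict = field(default_factory=dict)
    complex_variants_processed: int = 0
    annotation_errors: int = 0

    def validate(self) -> None:
        for name in (
            "records_total", "traits_total", "traits_mapped_current",
            "measures_total", "measures_with_gene", "measures_with_consequence",
            "complex_variants_processed", "annotation_errors",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")
        if self.traits_mapped_current > self.traits_total:
            raise ValueError("traits_mapped_current exceeds traits_total")
        if sum(self.class_counts.values()) != self.measures_total:
            raise ValueError("class counts do not partition the measures")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    metrics: RunMetrics
    decisions: dict  # normalized trait text -> MappingDecision
    annotated: list  # list of AnnotatedRecord (toy scale)


def _load_accession_map(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
        if line.strip():
            acc, chrom = line.split("\t")[:2]
            out[acc] = chrom
    return out


def _open_reference(fasta_path):
    from pyfaidx import Fasta

    return Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)


def run_annotation(config: RunConfig) -> RunResult:
    """Annotate one release per the config; write output; return metrics.

    Deterministic for fixed inputs: traits are mapped once per distinct
    normalized name, measures routed by variant class to the matching
    backend, and all outputs use stable orderings.  Per-record annotation
    failures are counted, never fatal.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    store = load_ontology(config.ontology)
    xref_index = XrefIndex.from_tsv(config.xref_table) if config.xref_table else None
    repository = (
        MappingsRepository.load(config.repository)
        if config.repository
        else MappingsRepository()
    )
    gene_index: Optional[GeneIndex] = (
        load_transcripts_gff3(config.gff3) if config.gff3 else None
    )
    reference = _open_reference(config.fasta) if config.fasta else None
    accession_map = (
        _load_accession_map(config.accession_map) if config.accession_map else {}
    )

    records = list(stream_records(config.release_xml))

    # pass 1: trait frequencies (how many records carry each name)
    freq: Counter = Counter()
    trait_xrefs: dict[str, tuple] = {}
    for record in records:
        for trait in record.traits:
            key = normalize(trait.preferred_name)
            freq[key] += 1
            trait_xrefs.setdefault(key, trait.xrefs)

    # pass 2: one decision per distinct trait name
    decisions: dict[str, MappingDecision] = {}
    for record in records:
        for trait in record.traits:
            key = normalize(trait.preferred_name)
            if key in decisions:
                continue
            decisions[key] = map_trait(
                trait.preferred_name,
                store,
                xref_index,
                repository,
                max_hops=config.max_hops,
                record_xrefs=trait_xrefs[key],
                record_frequency=freq[key],
            )

    metrics = RunMetrics(
        class_counts={
            c: 0 for c in ("simple", "structural_precise", "repeat_expansion", "unsupported")
        }
    )
    metrics.records_total = len(records)
    metrics.traits_distinct = len(decisions)
    metrics.traits_distinct_mapped = sum(
        1 for d in decisions.values() if d.status == "automatic"
    )

    annotated_records = []
    for record in records:
        trait_annotations = []
        for trait in record.traits:
            metrics.traits_total += 1
            decision = decisions[normalize(trait.preferred_name)]
            if decision.status == "automatic":
                metrics.traits_mapped_current += 1
                trait_annotations.append(
                    dataclasses.replace(
                        decision.accepted, trait_text=trait.preferred_name
                    )
                )
        consequence_annotations = []
        for measure in record.measures:
            metrics.measures_total += 1
            cls = classify_variant(measure, config.structural_length_threshold)
            metrics.class_counts[cls] += 1
            anns = []
            try:
                if cls == "simple" and gene_index is not None and reference is not None:
                    span = measure.preferred_span()
                    raw, errors = predict_consequences(
                        [(measure.measure_id, span)], gene_index, reference
                    )
                    metrics.annotation_errors += len(errors)
                    for e in errors:
                        log.warning(json.dumps({"stage": "consequence", "error": e.reason}))
                    anns = most_severe(raw)
                elif cls == "repeat_expansion" and gene_index is not None:
                    anns = most_severe(
                        annotate_repeat(
                            measure,
                            gene_index,
                            rule=config.trinucleotide_rule,
                            accession_chrom=accession_map,
                        )
                    )
                    if anns:
                        metrics.complex_variants_processed += 1
                elif cls == "structural_precise" and gene_index is not None:
                    anns = most_severe(annotate_structural(measure, gene_index))
                    if anns:
                        metrics.complex_variants_processed += 1
            except Exception as exc:  # per-record failures never abort the run
                metrics.annotation_errors += 1
                log.warning(
                    json.dumps(
                        {"stage": "consequence", "measure": measure.measure_id,
                         "error": str(exc)}
                    )
                )
            if any(a.gene_id for a in anns):
                metrics.measures_with_gene += 1
            if anns:
                metrics.measures_with_consequence += 1
            consequence_annotations.extend(anns)
        annotated_records.append(
            AnnotatedRecord(
                record=record,
                trait_annotations=tuple(trait_annotations),
                consequence_annotations=tuple(consequence_annotations),
            )
        )

    metrics.validate()
    if config.output:
        if config.output_format == "xml":
            write_annotated_xml(annotated_records, config.output)
        else:
            with open(config.output, "w", encoding="utf-8") as fh:
                fh.write("\t".join(DEFAULT_COLUMNS) + "\n")
                for ar in annotated_records:
                    for row in clinvar_io.record_to_rows(ar, DEFAULT_COLUMNS):
                        fh.write(row + "\n")
    log.info(json.dumps({"stage": "run", "metrics": metrics.as_dict()}))
    return RunResult(metrics=metrics, decisions=decisions, annotated=annotated_records)


# ---------------------------------------------------------------------------
# concordance evaluation


@dataclass
class AnnotationSet:
    """Keyed annotation values; ``None`` marks "no annotation provided".

    Keys are ``"RCV...|trait text"`` for traits and ``"RCV...|measure id"``
    for genes and consequences; both sets being compared must share the same
    key universe per dimension.
    """

    traits: dict[str, Optional[str]] = field(default_factory=dict)
    genes: dict[str, Optional[str]] = field(default_factory=dict)
    consequences: dict[str, Optional[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationSet":
        out = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
            if not line.strip():
                continue
            kind, key, value = (line.split("\t") + [""])[:3]
            getattr(out, {"trait": "traits", "gene": "genes",
                          "consequence": "consequences"}[kind])[key] = value or None
        return out

    @classmethod
    def from_run(cls, result: RunResult) -> "AnnotationSet":
        out = cls()
        for ar in result.annotated:
            rcv = ar.record.rcv_accession
            for trait in ar.record.traits:
                ta = next(
                    (t for t in ar.trait_annotations
                     if t.trait_text == trait.preferred_name),
                    None,
                )
                out.traits[f"{rcv}|{trait.preferred_name}"] = (
                    ta.term_uri if ta else None
                )
            for measure in ar.record.measures:
                anns = [
                    c for c in ar.consequence_annotations
                    if c.measure_id == measure.measure_id
                ]
                genes = sorted({c.gene_id for c in anns if c.gene_id})
                terms = sorted({c.so_term_name for c in anns if c.gene_id})
                key = f"{rcv}|{measure.measure_id}"
                out.genes[key] = genes[0] if genes else None
                out.consequences[key] = terms[0] if terms else None
        return out


@dataclass
class DimensionReport:
    both_present: int = 0
    only_ours: int = 0
    only_source: int = 0
    neither: int = 0
    concordant: int = 0

    @property
    def concordance(self) -> float:
        return self.concordant / self.both_present if self.both_present else 0.0

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["concordance"] = self.concordance
        return d


@dataclass
class EvaluationReport:
    traits: DimensionReport
    genes: DimensionReport
    consequences: DimensionReport

    @property
    def trait_concordance(self) -> float:
        return self.traits.concordance

    @property
    def gene_concordance(self) -> float:
        return self.genes.concordance

    @property
    def consequence_concordance(self) -> float:
        return self.consequences.concordance

    def as_dict(self) -> dict:
        return {
            "traits": self.traits.as_dict(),
            "genes": self.genes.as_dict(),
            "consequences": self.consequences.as_dict(),
        }


def _terms_equivalent(
    ours: str, source: str, xref_index: Optional[XrefIndex], max_hops: int
) -> bool:
    if ours == source:
        return True
    our_curie, src_curie = uri_to_curie(ours), uri_to_curie(source)
    if our_curie == src_curie:
        return True
    if xref_index is None:
        return False
    for a, b in ((our_curie, src_curie), (src_curie, our_curie)):
        db, _, ident = a.partition(":")
        closure = xref_closure((db, ident), xref_index, max_hops)
        if any(uri_to_curie(u) == b for u in closure):
            return True
    return False


def _compare(
    ours: dict, source: dict, equivalent, label: str
) -> DimensionReport:
    if set(ours) != set(source):
        missing = sorted(set(source) - set(ours))[:5]
        extra = sorted(set(ours) - set(source))[:5]
        raise ValueError(
            f"{label}: annotation sets keyed differently "
            f"(missing from ours e.g. {missing}; extra e.g. {extra})"
        )
    report = DimensionReport()
    for key in ours:
        a, b = ours[key], source[key]
        if a is not None and b is not None:
            report.both_present += 1
            if equivalent(a, b):
                report.concordant += 1
        elif a is not None:
            report.only_ours += 1
        elif b is not None:
            report.only_source += 1
        else:
            report.neither += 1
    return report


def evaluate_concordance(
    our_annotations: AnnotationSet,
    source_annotations: AnnotationSet,
    xref_index: Optional[XrefIndex] = None,
    max_hops: int = 2,
    gene_id_map: Optional[dict] = None,
    so_equivalence: Optional[set] = None,
) -> EvaluationReport:
    """Compare this package's annotations against the source's own.

    Trait terms count as equivalent when identical or connected within
    `max_hops` in the cross-reference graph; genes when identical or linked
    by the HGNC↔Ensembl table; consequence terms when identical or paired in
    the packaged equivalence list (e.g. specific repeat subtypes vs a
    generic repeat term).  Each dimension partitions its key universe into
    both-present / only-ours / only-source / neither.
    """
    gene_map = gene_id_map if gene_id_map is not None else load_gene_id_map()
    equiv_pairs = so_equivalence if so_equivalence is not None else load_so_equivalence()

    def gene_equiv(a: str, b: str) -> bool:
        return a == b or gene_map.get(b) == a or gene_map.get(a) == b

    def so_equiv(a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in equiv_pairs

    return EvaluationReport(
        traits=_compare(
            our_annotations.traits,
            source_annotations.traits,
            lambda a, b: _terms_equivalent(a, b, xref_index, max_hops),
            "traits",
        ),
        genes=_compare(our_annotations.genes, source_annotations.genes,
                       gene_equiv, "genes"),
        consequences=_compare(
            our_annotations.consequences, source_annotations.consequences,
            so_equiv, "consequences",
        ),
    )
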