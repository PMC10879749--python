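"""Trait-mapping protocol: automatic mapping, curation round trip, repository.

The protocol mirrors how clinical trait names are harmonized in practice:

1. trait names seen before are resolved from a repository of previously
   curated mappings (released alongside the software, so most traits in a
   mature deployment resolve this way);
2. unseen names are matched against ontology labels and synonyms; only
   unambiguous exact matches are auto-accepted;
3. everything else is exported to a curation spreadsheet, reviewed by a
   human, and merged back, growing the repository for the next release;
4. curator verdicts that require new ontology terms are collected into a
   feedback report for the ontology maintainers and for text-to-term
   services.

Trait identity is normalized text (not source-database trait ids) so
mappings transfer across records that share a name.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .ontology import (
    OntologyStore,
    OntologyTerm,
    TermMatch,
    XrefIndex,
    find_matches,
    is_current,
    normalize,
    uri_to_curie,
)

__all__ = [
    "TraitMapping",
    "MappingDecision",
    "MappingsRepository",
    "RepositoryEntry",
    "CurationDialectError",
    "ImportReport",
    "FeedbackReport",
    "map_trait",
    "export_curation",
    "import_curation",
    "merge_mappings",
    "feedback_report",
]

CONFIDENCES = (
    "AUTO_EXACT_LABEL",
    "AUTO_EXACT_SYNONYM",
    "AUTO_PREVIOUS",
    "CURATED",
    "CANDIDATE",
)
SOURCES = ("label", "synonym", "xref", "repository", "curator")
#: closed curator-status vocabulary; only DONE produces mappings
CURATOR_STATUSES = ("DONE", "IMPORT", "NEW", "SKIP", "UNSURE")

#: fixed sentinel so library output is byte-deterministic; the CLI passes a
#: real date when a human runs a curation round
DEFAULT_TIMESTAMP = "1970-01-01"


class CurationDialectError(ValueError):
    """Curation TSV does not follow the dialect written by export_curation."""


@dataclass(frozen=True)
class TraitMapping:
    trait_text: str
    term_uri: str
    term_label: str
    confidence: str  # one of CONFIDENCES
    source: str  # one of SOURCES
    current: bool = True
    match_kind: str = ""  # populated on CANDIDATE mappings
    hops: int = 0

    def __post_init__(self):
        if self.confidence not in CONFIDENCES:
            raise ValueError(f"unknown confidence {self.confidence!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.confidence != "CANDIDATE" and not self.current:
            raise ValueError(
                f"{self.confidence} mapping must reference a current term"
            )

    @property
    def curie(self) -> str:
        return uri_to_curie(self.term_uri)


@dataclass
class MappingDecision:
    trait_text: str
    status: str  # automatic | requires_curation | unmapped
    accepted: Optional[TraitMapping] = None
    candidates: tuple[TraitMapping, ...] = ()
    record_frequency: int = 0
    trait_xrefs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.status not in ("automatic", "requires_curation", "unmapped"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "automatic") != (self.accepted is not None):
            raise ValueError("accepted mapping present iff status is automatic")


def _resolve_current(
    term: OntologyTerm, store: OntologyStore
) -> tuple[Optional[OntologyTerm], bool]:
    """Follow ``replaced_by`` one step; (current term, followed?) or (None, _).

    Chains longer than one step are not auto-followed — they go to curation.
    """
    if not term.obsolete:
        return term, False
    if term.replaced_by is None:
        return None, False
    replacement = store.get(term.replaced_by)
    if replacement is not None and not replacement.obsolete:
        return replacement, True
    return None, True


def _candidate(match: TermMatch, trait_text: str, store: OntologyStore) -> TraitMapping:
    source = {
        "exact_label": "label",
        "exact_synonym_exact_scope": "synonym",
        "exact_synonym_other_scope": "synonym",
        "xref": "xref",
    }[match.match_kind]
    return TraitMapping(
        trait_text=trait_text,
        term_uri=match.term.uri,
        term_label=match.term.label,
        confidence="CANDIDATE",
        source=source,
        current=not match.term.obsolete,
        match_kind=match.match_kind,
        hops=match.hops,
    )


def map_trait(
    trait_text: str,
    store: OntologyStore,
    xref_index: Optional[XrefIndex] = None,
    repository: Optional["MappingsRepository"] = None,
    max_hops: int = 2,
    record_xrefs: Sequence[tuple[str, str]] = (),
    record_frequency: int = 0,
) -> MappingDecision:
    """Decide how one trait name maps to the target ontology.

    Decision order: previously curated mapping (current term) → auto;
    previously curated but term now obsolete → curation, replacement first;
    unique exact label → auto; unique exact-scope synonym → auto; any other
    non-empty match set → curation with ranked candidates; nothing → unmapped.
    """
    if not trait_text:
        raise ValueError("trait_text must be non-empty")

    def decision(status, accepted=None, candidates=()):
        return MappingDecision(
            trait_text=trait_text,
            status=status,
            accepted=accepted,
            candidates=tuple(candidates),
            record_frequency=record_frequency,
            trait_xrefs=tuple(record_xrefs),
        )

    matches = find_matches(
        trait_text, store, xref_index, max_hops, identifiers=record_xrefs
    )
    ranked_candidates = [_candidate(m, trait_text, store) for m in matches]

    # (1)/(2): repository of previous mappings
    if repository is not None:
        for entry in repository.active_entries(trait_text):
            term = store.get(entry.curie)
            if term is None:
                continue
            resolved, followed = _resolve_current(term, store)
            if resolved is not None and not followed:
                return decision(
                    "automatic",
                    accepted=TraitMapping(
                        trait_text=trait_text,
                        term_uri=term.uri,
                        term_label=term.label,
                        confidence="AUTO_PREVIOUS",
                        source="repository",
                    ),
                )
            # term went obsolete since curation: re-curate, replacement first
            candidates = list(ranked_candidates)
            if resolved is not None:
                candidates.insert(
                    0,
                    TraitMapping(
                        trait_text=trait_text,
                        term_uri=resolved.uri,
                        term_label=resolved.label,
                        confidence="CANDIDATE",
                        source="repository",
                        match_kind="exact_label",
                    ),
                )
            if candidates:
                return decision("requires_curation", candidates=candidates)
            return decision("requires_curation")

    # (3)/(4): a single lexically matched term is high-confidence; any
    # multiple-term ambiguity — even all-exact — goes to curation.  Matches
    # reached only through record xrefs never block a lexical match, they
    # merely rank as candidates.
    lexical = [m for m in matches if m.match_kind != "xref"]
    lexical_terms = {m.term.uri for m in lexical}
    if len(lexical_terms) == 1:
        kinds = {m.match_kind for m in lexical}
        resolved, _ = _resolve_current(lexical[0].term, store)
        if resolved is not None:
            if "exact_label" in kinds:
                return decision(
                    "automatic",
                    accepted=TraitMapping(
                        trait_text=trait_text,
                        term_uri=resolved.uri,
                        term_label=resolved.label,
                        confidence="AUTO_EXACT_LABEL",
                        source="label",
                    ),
                )
            if "exact_synonym_exact_scope" in kinds:
                return decision(
                    "automatic",
                    accepted=TraitMapping(
                        trait_text=trait_text,
                        term_uri=resolved.uri,
                        term_label=resolved.label,
                        confidence="AUTO_EXACT_SYNONYM",
                        source="synonym",
                    ),
                )

    # (5): ambiguous or lower-confidence matches
    if ranked_candidates:
        return decision("requires_curation", candidates=ranked_candidates)

    # (6)
    return decision("unmapped")


# ---------------------------------------------------------------------------
# curation spreadsheet round trip

_CURATION_FIXED_COLUMNS = ["trait_text", "record_frequency"]
_CURATION_CURATOR_COLUMNS = ["chosen_curie", "status", "comment"]


def export_curation(
    decisions: Iterable[MappingDecision],
    sink,
    n_candidates: int = 5,
) -> None:
    """Write the curation spreadsheet (TSV) for unresolved decisions.

    One row per decision, sorted by descending record frequency then trait
    text; candidate columns hold ``curie|label|match_kind|hops``.  Only
    requires_curation and unmapped decisions may be included.
    """
    rows = list(decisions)
    for d in rows:
        if d.status == "automatic":
            raise ValueError(
                f"automatic decision for {d.trait_text!r} does not need curation"
            )
    rows.sort(key=lambda d: (-d.record_frequency, d.trait_text))
    header = (
        _CURATION_FIXED_COLUMNS
        + [f"candidate_{i}" for i in range(1, n_candidates + 1)]
        + _CURATION_CURATOR_COLUMNS
    )
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for d in rows:
            cells = [d.trait_text, str(d.record_frequency)]
            for cand in d.candidates[:n_candidates]:
                cells.append(
                    f"{cand.curie}|{cand.term_label}|{cand.match_kind}|{cand.hops}"
                )
            cells += [""] * (n_candidates - min(len(d.candidates), n_candidates))
            cells += ["", "", ""]  # curator columns
            writer.writerow(cells)
    finally:
        if own:
            fh.close()


@dataclass
class ImportReport:
    curated: list[TraitMapping] = field(default_factory=list)
    feedback_rows: list[dict] = field(default_factory=list)  # NEW/IMPORT rows
    rejected: list[tuple[dict, str]] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)  # SKIP/UNSURE/blank


def import_curation(source, store: OntologyStore) -> tuple[list[TraitMapping], ImportReport]:
    """Read back a curation TSV with the curator columns filled in.

    DONE rows whose chosen term is current become CURATED mappings; IMPORT
    and NEW rows are routed to the feedback report; rows with unresolvable
    or obsolete terms land in the rejection list — never silently dropped.
    """
    own = isinstance(source, (str, Path))
    fh = open(source, "r", encoding="utf-8", newline="") if own else source
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        fieldnames = reader.fieldnames or []
        missing = [
            c
            for c in _CURATION_FIXED_COLUMNS + _CURATION_CURATOR_COLUMNS
            if c not in fieldnames
        ]
        if missing:
            raise CurationDialectError(f"missing mandatory columns: {missing}")
        report = ImportReport()
        for row in reader:
            status = (row.get("status") or "").strip().upper()
            if not status or status in ("SKIP", "UNSURE"):
                report.skipped.append(row)
                continue
            if status not in CURATOR_STATUSES:
                report.rejected.append((row, f"unknown status {status!r}"))
                continue
            if status in ("IMPORT", "NEW"):
                report.feedback_rows.append(row)
                continue
            # status == DONE
            curie = (row.get("chosen_curie") or "").strip()
            if not curie:
                report.rejected.append((row, "DONE row without chosen_curie"))
                continue
            term = store.get(curie)
            if term is None:
                report.rejected.append((row, f"unknown term {curie}"))
                continue
            if term.obsolete:
                report.rejected.append((row, "obsolete term"))
                continue
            report.curated.append(
                TraitMapping(
                    trait_text=row["trait_text"],
                    term_uri=term.uri,
                    term_label=term.label,
                    confidence="CURATED",
                    source="curator",
                )
            )
        return report.curated, report
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# mappings repository


@dataclass(frozen=True)
class RepositoryEntry:
    trait_text: str
    curie: str
    label: str
    status: str  # curator status at merge time (DONE for curated entries)
    active: bool
    timestamp: str


class MappingsRepository:
    """Diff-friendly store of previously curated trait mappings.

    Serialized as a sorted 6-column TSV (trait_text, curie, label, status,
    active, timestamp) so that successive releases version-control cleanly.
    Superseded entries are kept inactive for audit.
    """

    COLUMNS = ["trait_text", "curie", "label", "status", "active", "timestamp"]

    def __init__(self, entries: Iterable[RepositoryEntry] = ()):
        self._entries: dict[str, list[RepositoryEntry]] = {}
        for e in entries:
            self._entries.setdefault(normalize(e.trait_text), []).append(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def all_entries(self) -> list[RepositoryEntry]:
        out = []
        for key in sorted(self._entries):
            out.extend(
                sorted(self._entries[key], key=lambda e: (e.curie, not e.active))
            )
        return out

    def active_entries(self, trait_text: str) -> list[RepositoryEntry]:
        return [
            e
            for e in self._entries.get(normalize(trait_text), [])
            if e.active
        ]

    @classmethod
    def load(cls, source) -> "MappingsRepository":
        own = isinstance(source, (str, Path))
        fh = open(source, "r", encoding="utf-8", newline="") if own else source
        try:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = [c for c in cls.COLUMNS if c not in (reader.fieldnames or [])]
            if missing:
                raise CurationDialectError(
                    f"repository TSV missing columns: {missing}"
                )
            return cls(
                RepositoryEntry(
                    trait_text=row["trait_text"],
                    curie=row["curie"],
                    label=row["label"],
                    status=row["status"],
                    active=row["active"] == "1",
                    timestamp=row["timestamp"],
                )
                for row in reader
            )
        finally:
            if own:
                fh.close()

    def save(self, sink) -> None:
        own = isinstance(sink, (str, Path))
        fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
        try:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(self.COLUMNS)
            for e in self.all_entries():
                writer.writerow(
                    [
                        e.trait_text,
                        e.curie,
                        e.label,
                        e.status,
                        "1" if e.active else "0",
                        e.timestamp,
                    ]
                )
        finally:
            if own:
                fh.close()

    def revalidate(self, store: OntologyStore) -> list[RepositoryEntry]:
        """Deactivate active entries whose terms are no longer current.

        Returns the deactivated entries — the re-curation queue.
        """
        stale = []
        for key, entries in self._entries.items():
            for i, e in enumerate(entries):
                if e.active and not is_current(e.curie, store):
                    entries[i] = replace(e, active=False)
                    stale.append(e)
        return stale


def merge_mappings(
    repository: MappingsRepository,
    new_mappings: Iterable[TraitMapping],
    timestamp: str = DEFAULT_TIMESTAMP,
) -> tuple[MappingsRepository, dict[str, int]]:
    """Upsert curated mappings into the repository; idempotent.

    A newly curated mapping for a trait supersedes (marks inactive, retains
    for audit) any prior active mapping of the same trait text to a
    different term.  The change summary counts added / superseded /
    unchanged mappings.
    """
    summary = {"added": 0, "superseded": 0, "unchanged": 0}
    for m in new_mappings:
        key = normalize(m.trait_text)
        entries = repository._entries.setdefault(key, [])
        if any(e.active and e.curie == m.curie for e in entries):
            summary["unchanged"] += 1
            continue
        for i, e in enumerate(entries):
            if e.active and e.curie != m.curie:
                entries[i] = replace(e, active=False)
                summary["superseded"] += 1
        reactivated = False
        for i, e in enumerate(entries):
            if not e.active and e.curie == m.curie:
                entries[i] = replace(e, active=True, timestamp=timestamp)
                reactivated = True
                break
        if not reactivated:
            entries.append(
                RepositoryEntry(
                    trait_text=m.trait_text,
                    curie=m.curie,
                    label=m.term_label,
                    status="DONE",
                    active=True,
                    timestamp=timestamp,
                )
            )
        summary["added"] += 1
    return repository, summary


# ---------------------------------------------------------------------------
# feedback report


@dataclass
class FeedbackReport:
    """Feedback generated by a curation round.

    ``ontology_requests`` lists terms the curators asked to have imported
    into / created in the target ontology, each with the supporting
    source-database identifiers (e.g. MedGen ids) from the originating
    records.  ``mapping_assertions`` is a 4-column table (trait_text, curie,
    label, status) of confirmed text→term pairs suitable for upload to a
    text-to-term service so other users benefit from the curation.
    """

    ontology_requests: list[dict] = field(default_factory=list)
    mapping_assertions: list[tuple[str, str, str, str]] = field(default_factory=list)

    def write(self, requests_sink, assertions_sink) -> None:
        for sink, rows, header in (
            (
                requests_sink,
                [
                    [r["trait_text"], r["request_type"], r["supporting_xrefs"]]
                    for r in self.ontology_requests
                ],
                ["trait_text", "request_type", "supporting_xrefs"],
            ),
            (
                assertions_sink,
                [list(a) for a in self.mapping_assertions],
                ["trait_text", "curie", "label", "status"],
            ),
        ):
            own = isinstance(sink, (str, Path))
            fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
            try:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(header)
                writer.writerows(rows)
            finally:
                if own:
                    fh.close()


def feedback_report(
    decisions: Iterable[MappingDecision],
    imports: ImportReport,
) -> FeedbackReport:
    """Build the two-section feedback report from a curation round."""
    report = FeedbackReport()
    xrefs_by_trait: dict[str, tuple] = {
        normalize(d.trait_text): d.trait_xrefs for d in decisions
    }
    for row in sorted(
        imports.feedback_rows, key=lambda r: r.get("trait_text", "")
    ):
        trait = row.get("trait_text", "")
        xrefs = xrefs_by_trait.get(normalize(trait), ())
        report.ontology_requests.append(
            {
                "trait_text": trait,
                "request_type": (row.get("status") or "").strip().upper(),
                "supporting_xrefs": ",".join(f"{db}:{i}" for db, i in xrefs),
            }
        )
    for m in sorted(imports.curated, key=lambda m: (m.trait_text, m.curie)):
        report.mapping_assertions.append(
            (m.trait_text, m.curie, m.term_label, "DONE")
        )
    return report
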