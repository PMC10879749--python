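"""Target-ontology store: labels, synonyms, cross-references, term currency.

Loads an OBO-format ontology (the flat-file subset used by EFO/MONDO-style
disease ontologies: ``id``, ``name``, ``synonym`` with scope, ``xref``,
``is_obsolete``, ``replaced_by``) and answers exact-after-normalization
queries from trait text to terms.  Fuzzy lexical matching is deliberately
absent: it belongs to remote text-to-term services, which are represented
here only as interface stubs (:mod:`clinannot.remote`), keeping the core
deterministic and fully testable offline.

Cross-reference resolution (the role played by ontology xref services) is a
breadth-first closure over an undirected identifier graph loaded from a
4-column TSV: ``source_db  source_id  target_curie  mapping_type``.
"""

from __future__ import annotations

import io
import re
import unicodedata
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import obonet

__all__ = [
    "OntologyTerm",
    "OntologyStore",
    "TermMatch",
    "XrefIndex",
    "OntologyError",
    "load_ontology",
    "find_matches",
    "is_current",
    "xref_closure",
    "normalize",
    "curie_to_uri",
    "uri_to_curie",
]

SYNONYM_SCOPES = ("exact", "related", "broad", "narrow")

#: precedence of match kinds, most confident first
MATCH_KIND_ORDER = {
    "exact_label": 0,
    "exact_synonym_exact_scope": 1,
    "exact_synonym_other_scope": 2,
    "xref": 3,
}

_URI_PREFIXES = {
    "EFO": "http://www.ebi.ac.uk/efo/EFO_",
    "Orphanet": "http://www.orpha.net/ORDO/Orphanet_",
}
_OBO_PURL = "http://purl.obolibrary.org/obo/"


class OntologyError(Exception):
    """Fatal problem in an ontology or cross-reference source."""


def curie_to_uri(curie: str) -> str:
    prefix, _, local = curie.partition(":")
    base = _URI_PREFIXES.get(prefix, f"{_OBO_PURL}{prefix}_")
    return f"{base}{local}"


def uri_to_curie(uri: str) -> str:
    for prefix, base in _URI_PREFIXES.items():
        if uri.startswith(base):
            return f"{prefix}:{uri[len(base):]}"
    if uri.startswith(_OBO_PURL):
        return uri[len(_OBO_PURL):].replace("_", ":", 1)
    return uri


_WS_RUN = re.compile(r"\s+")
_EDGE_PUNCT = ".,;:'\""


def normalize(text: str) -> str:
    """Conservative trait-text normalization: NFC, casefold, collapse
    whitespace runs, strip ``.,;:'"`` from the string ends only.

    Idempotent by construction; never merges genuinely distinct disease
    names (no punctuation removal inside the string, no stemming).
    """
    text = unicodedata.normalize("NFC", text).casefold()
    text = _WS_RUN.sub(" ", text).strip()
    return text.strip(_EDGE_PUNCT).strip()


@dataclass(frozen=True)
class OntologyTerm:
    uri: str
    curie: str
    label: str
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope)
    xrefs: tuple[tuple[str, str], ...] = ()  # (database, identifier)
    obsolete: bool = False
    replaced_by: Optional[str] = None  # URI

    def __post_init__(self):
        if not self.label:
            raise ValueError(f"term {self.curie} has empty label")
        if not self.obsolete and self.replaced_by is not None:
            raise ValueError(f"current term {self.curie} carries replaced_by")


@dataclass(frozen=True)
class TermMatch:
    term: OntologyTerm
    matched_text: str
    match_kind: str  # key of MATCH_KIND_ORDER
    hops: int = 0

    def __post_init__(self):
        if (self.match_kind == "xref") != (self.hops >= 1):
            raise ValueError("hops >= 1 iff match_kind == 'xref'")

    @property
    def sort_key(self):
        return (MATCH_KIND_ORDER[self.match_kind], self.hops, self.term.curie)


class OntologyStore:
    """Indexed collection of :class:`OntologyTerm`."""

    def __init__(self, terms: Iterable[OntologyTerm]):
        self._by_uri: dict[str, OntologyTerm] = {}
        self._by_curie: dict[str, OntologyTerm] = {}
        self._label_index: dict[str, list[str]] = {}
        self._synonym_index: dict[str, list[tuple[str, str]]] = {}
        for term in terms:
            if term.uri in self._by_uri:
                raise OntologyError(f"duplicate term id {term.curie}")
            self._by_uri[term.uri] = term
            self._by_curie[term.curie] = term
            self._label_index.setdefault(normalize(term.label), []).append(term.uri)
            for text, scope in term.synonyms:
                self._synonym_index.setdefault(normalize(text), []).append(
                    (term.uri, scope)
                )

    def __len__(self) -> int:
        return len(self._by_uri)

    def __iter__(self):
        return iter(self._by_uri.values())

    def __contains__(self, key: str) -> bool:
        return key in self._by_uri or key in self._by_curie

    def get(self, key: str) -> Optional[OntologyTerm]:
        """Look a term up by URI or CURIE."""
        return self._by_uri.get(key) or self._by_curie.get(key)

    def terms_with_label(self, text: str) -> list[OntologyTerm]:
        return [self._by_uri[u] for u in self._label_index.get(normalize(text), [])]

    def terms_with_synonym(self, text: str) -> list[tuple[OntologyTerm, str]]:
        return [
            (self._by_uri[u], scope)
            for u, scope in self._synonym_index.get(normalize(text), [])
        ]


_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z]+)?')


def _parse_synonym(raw: str, warnings: list[str]) -> Optional[tuple[str, str]]:
    m = _SYNONYM_RE.match(raw.strip())
    if not m:
        return None
    text = m.group("text").replace('\\"', '"')
    scope = (m.group("scope") or "RELATED").lower()
    if scope not in SYNONYM_SCOPES:
        warnings.append(f"unknown synonym scope {scope!r}, treated as related")
        scope = "related"
    return text, scope


def load_ontology(source) -> OntologyStore:
    """Load an OBO file (path, file object, or text) into an indexed store.

    Every ``[Term]`` stanza becomes exactly one :class:`OntologyTerm`,
    obsolete stanzas included.  Duplicate term ids are fatal.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text(encoding="utf-8")
    elif hasattr(source, "read"):
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode("utf-8")
    else:
        text = str(source)

    # obonet silently keeps the last stanza for a duplicated id; detect first
    ids = re.findall(r"^\[Term\]\s*\nid: *(\S+)", text, flags=re.MULTILINE)
    seen: set[str] = set()
    for term_id in ids:
        if term_id in seen:
            raise OntologyError(f"duplicate term id {term_id}")
        seen.add(term_id)

    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    warnings: list[str] = []
    terms = []
    for curie, data in graph.nodes(data=True):
        label = data.get("name", "")
        if not label:
            label = curie  # obsolete stubs occasionally lack a name
        synonyms = tuple(
            s
            for raw in data.get("synonym", [])
            if (s := _parse_synonym(raw, warnings)) is not None
        )
        xrefs = []
        for raw in data.get("xref", []):
            db, _, ident = raw.partition(":")
            if ident:
                xrefs.append((db, ident))
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        replaced = data.get("replaced_by", [])
        replaced_uri = curie_to_uri(replaced[0]) if (obsolete and replaced) else None
        terms.append(
            OntologyTerm(
                uri=curie_to_uri(curie),
                curie=curie,
                label=label,
                synonyms=synonyms,
                xrefs=tuple(xrefs),
                obsolete=obsolete,
                replaced_by=replaced_uri,
            )
        )
    terms.sort(key=lambda t: t.curie)
    return OntologyStore(terms)


def is_current(uri: str, store: OntologyStore) -> bool:
    """True iff the term exists in the store and is not obsolete."""
    term = store.get(uri)
    return term is not None and not term.obsolete


# ---------------------------------------------------------------------------
# cross-references


class XrefIndex:
    """Undirected identifier graph from a 4-column cross-reference TSV.

    Nodes are ``DB:identifier`` strings; a node is a *term node* when it
    appeared in the ``target_curie`` column (i.e. it names an ontology term
    rather than a source-database record).
    """

    def __init__(self):
        self._edges: dict[str, set[str]] = {}
        self._term_nodes: set[str] = set()

    @staticmethod
    def _node(db: str, ident: str) -> str:
        if ident.startswith(db + ":"):
            return ident
        return f"{db}:{ident}"

    def add(self, source_db: str, source_id: str, target_curie: str,
            mapping_type: str = "xref") -> None:
        a = self._node(source_db, source_id)
        b = target_curie
        self._edges.setdefault(a, set()).add(b)
        self._edges.setdefault(b, set()).add(a)
        self._term_nodes.add(b)

    @classmethod
    def from_tsv(cls, source) -> "XrefIndex":
        index = cls()
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            lines = Path(source).read_text(encoding="utf-8").splitlines()
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "source_db":  # header
                continue
            if len(parts) < 3:
                raise OntologyError(
                    f"cross-reference TSV line {lineno}: expected >= 3 columns"
                )
            index.add(parts[0], parts[1], parts[2],
                      parts[3] if len(parts) > 3 else "xref")
        return index

    def neighbours(self, node: str) -> set[str]:
        return self._edges.get(node, set())

    def is_term_node(self, node: str) -> bool:
        return node in self._term_nodes

    def __len__(self) -> int:
        return len(self._edges)


def xref_closure(
    identifier: tuple[str, str],
    xref_index: XrefIndex,
    max_hops: int = 2,
) -> dict[str, int]:
    """BFS closure over the cross-reference graph, edges undirected.

    Returns ``{term URI: minimal hop count}`` for every term node reachable
    within `max_hops` from ``(db, id)``; the starting identifier itself is
    excluded even when it is a term node.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    start = XrefIndex._node(*identifier)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if dist[node] == max_hops:
            continue
        for nb in xref_index.neighbours(node):
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return {
        curie_to_uri(node): hops
        for node, hops in dist.items()
        if hops >= 1 and xref_index.is_term_node(node)
    }


def find_matches(
    text: str,
    store: OntologyStore,
    xref_index: Optional[XrefIndex] = None,
    max_hops: int = 2,
    identifiers: Iterable[tuple[str, str]] = (),
) -> list[TermMatch]:
    """All terms matching `text` exactly after normalization, ranked.

    Label matches rank before exact-scope synonym matches, which rank before
    other-scope synonym matches; cross-reference matches (terms reachable in
    the xref graph from `identifiers`, e.g. the MedGen ids attached to a
    trait record) come last, nearer terms first.  Obsolete terms are
    returned flagged (``term.obsolete``) so callers can reject them or
    follow ``replaced_by``.  Ordering is total and deterministic.
    """
    if not text:
        raise ValueError("text must be non-empty")
    matches: dict[tuple[str, str], TermMatch] = {}

    def _offer(match: TermMatch):
        key = (match.term.uri, match.match_kind)
        prior = matches.get(key)
        if prior is None or match.sort_key < prior.sort_key:
            matches[key] = match

    for term in store.terms_with_label(text):
        _offer(TermMatch(term=term, matched_text=text, match_kind="exact_label"))
    for term, scope in store.terms_with_synonym(text):
        kind = (
            "exact_synonym_exact_scope"
            if scope == "exact"
            else "exact_synonym_other_scope"
        )
        _offer(TermMatch(term=term, matched_text=text, match_kind=kind))
    if xref_index is not None:
        for ident in identifiers:
            for uri, hops in xref_closure(ident, xref_index, max_hops).items():
                term = store.get(uri)
                if term is None:
                    continue
                _offer(
                    TermMatch(
                        term=term,
                        matched_text=f"{ident[0]}:{ident[1]}",
                        match_kind="xref",
                        hops=hops,
                    )
                )
    return sorted(matches.values(), key=lambda m: m.sort_key)
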