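"""Interfaces for remote annotation services; never used in the test path.

At production scale, trait text-to-term matching, ontology cross-reference
resolution and consequence prediction are delegated to hosted services.
This package keeps those roles behind the small interfaces below so a
deployment can plug clients in, while the offline implementations
(:mod:`clinannot.ontology`, :mod:`clinannot.consequence`) satisfy the same
contracts locally.

Contract expected of real clients (documented here, enforced nowhere):

* requests are batched, at most 200 variants / 100 texts per call;
* transient failures retry with exponential backoff (base 1 s, factor 2,
  max 5 attempts);
* a failed batch is logged and skipped (fail-soft) — one bad batch must
  never abort a release run;
* structural variants are submitted in region form
  ``chrom start stop DEL|DUP|INS`` (the SPDI-style allele form is used only
  for precise alleles).
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Iterable, Sequence

from .clinvar_io import GenomicSpan
from .consequence import ConsequenceAnnotation
from .ontology import TermMatch


class RemoteMatcher(ABC):
    """Text-to-ontology-term service (the role ZOOMA-like services play)."""

    batch_size = 100

    @abstractmethod
    def match(self, texts: Sequence[str]) -> dict[str, list[TermMatch]]:
        """Map each text to ranked candidate terms."""


class RemoteXrefResolver(ABC):
    """Ontology cross-reference service (the role OxO-like services play)."""

    @abstractmethod
    def closure(
        self, identifier: tuple[str, str], max_hops: int
    ) -> dict[str, int]:
        """Term URIs reachable from (db, id) with hop counts."""


class RemoteConsequenceBackend(ABC):
    """Variant effect predictor service (VEP-like)."""

    batch_size = 200

    @abstractmethod
    def predict(
        self, variants: Iterable[tuple[str, GenomicSpan]]
    ) -> list[ConsequenceAnnotation]:
        """Consequence annotations for (measure_id, span) pairs."""
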