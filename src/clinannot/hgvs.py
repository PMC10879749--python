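"""Parser for the HGVS subset that matters for complex clinical variants.

ClinVar represents repeat expansions and other complex events mostly through
HGVS strings, which can carry imprecise locations (``(a_b)`` intervals, ``?``)
and variable repeat counts (``CAG[40_55]``, ``CGG(55_200)``).  General-purpose
HGVS libraries insist on validating accessions against live sequence
repositories; this parser instead covers the documented grammar subset
offline, and fails loudly (never partially) on anything outside it.

Grammar (informal)::

    expr      := accession ":" kind "." location edit
    kind      := g | c | m | n
    location  := pos [ "_" pos ]
    pos       := "?" | [-]int | "*"int | "(" bound "_" bound ")"
    bound     := "?" | [-]int | "*"int
    edit      := ref ">" alt                      substitution (single base)
               | "delins" seq                     deletion-insertion
               | "del" [seq | int]                deletion
               | "dup" [seq]                      duplication
               | "ins" seq                        insertion
               | unit "[" n [ "_" m ] "]"         repeat, exact or ranged count
               | [unit] "(" n "_" m ")"           repeat, uncertain count

``*`` positions are 3'-UTR coordinates (``c.`` only), negative positions are
5'-UTR.  ``unparse`` inverts ``parse_hgvs`` on the whole subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Bound",
    "HgvsPosition",
    "HgvsVariant",
    "HgvsParseFailure",
    "parse_hgvs",
    "try_parse_hgvs",
    "unparse",
]

EDIT_KINDS = (
    "substitution",
    "deletion",
    "duplication",
    "insertion",
    "delins",
    "repeat",
)
COORDINATE_KINDS = ("g", "c", "m", "n")


class HgvsParseFailure(ValueError):
    """Expression is outside the supported grammar; nothing was inferred.

    Carries ``unconsumed``, the suffix at which parsing stopped, so callers
    can log what defeated the grammar before routing the variant to the
    unsupported class.
    """

    def __init__(self, expression: str, unconsumed: str, reason: str = ""):
        self.expression = expression
        self.unconsumed = unconsumed
        msg = f"cannot parse {expression!r} (stopped at {unconsumed!r})"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


@dataclass(frozen=True, order=True)
class Bound:
    """One endpoint of a (possibly uncertain) position.

    ``value=None`` renders as ``?``; ``utr3`` marks ``*``-prefixed 3'-UTR
    coordinates, which sort after all non-UTR coordinates.
    """

    utr3: bool = False
    value: Optional[int] = None

    def __str__(self) -> str:
        if self.value is None:
            return "?"
        return f"*{self.value}" if self.utr3 else str(self.value)


@dataclass(frozen=True)
class HgvsPosition:
    low: Bound
    high: Bound
    uncertain: bool = False  # written as "(low_high)"

    def __post_init__(self):
        if not self.uncertain and self.low != self.high:
            raise ValueError("precise position must have low == high")
        if (
            self.uncertain
            and self.low.value is not None
            and self.high.value is not None
            and self.low > self.high
        ):
            raise ValueError(f"uncertainty interval {self} has low > high")

    @classmethod
    def precise(cls, value: int, utr3: bool = False) -> "HgvsPosition":
        b = Bound(utr3=utr3, value=value)
        return cls(low=b, high=b)

    @property
    def outer_low(self) -> Optional[int]:
        return self.low.value

    @property
    def outer_high(self) -> Optional[int]:
        return self.high.value

    def __str__(self) -> str:
        if not self.uncertain:
            return str(self.low)
        return f"({self.low}_{self.high})"


@dataclass(frozen=True)
class HgvsVariant:
    accession: str
    coordinate_kind: str
    start: HgvsPosition
    end: Optional[HgvsPosition] = None
    edit_kind: str = "substitution"
    ref: Optional[str] = None
    alt: Optional[str] = None
    inserted: Optional[str] = None  # sequence for ins / delins
    deleted_length: Optional[int] = None  # "del5" form
    repeat_unit: Optional[str] = None
    repeat_count: Optional[tuple[int, int]] = None
    repeat_count_uncertain: bool = False  # "(n_m)" rather than "[n_m]"

    def __post_init__(self):
        if self.coordinate_kind not in COORDINATE_KINDS:
            raise ValueError(f"bad coordinate kind {self.coordinate_kind!r}")
        if self.edit_kind not in EDIT_KINDS:
            raise ValueError(f"bad edit kind {self.edit_kind!r}")
        if self.edit_kind == "repeat":
            if self.repeat_count is None:
                raise ValueError("repeat edit requires a repeat_count")
            lo, hi = self.repeat_count
            if lo > hi:
                raise ValueError(f"repeat count ({lo},{hi}) has min > max")


_TOP_RE = re.compile(
    r"^(?P<acc>[A-Za-z][A-Za-z0-9_]*(?:\.\d+)?):(?P<kind>[gcmn])\.(?P<rest>.+)$"
)
_BOUND = r"(?:\?|\*\d+|-?\d+)"
_POS_RE = re.compile(rf"\((?P<plo>{_BOUND})_(?P<phi>{_BOUND})\)|(?P<simple>{_BOUND})")

_EDIT_RES = [
    ("substitution", re.compile(r"^(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$")),
    ("delins", re.compile(r"^delins(?P<seq>[ACGTN]+)$")),
    ("deletion", re.compile(r"^del(?P<what>[ACGTN]+|\d+)?$")),
    ("duplication", re.compile(r"^dup(?P<seq>[ACGTN]+)?$")),
    ("insertion", re.compile(r"^ins(?P<seq>[ACGTN]+)$")),
    (
        "repeat",
        re.compile(r"^(?P<unit>[ACGTN]*)\[(?P<n>\d+)(?:_(?P<m>\d+))?\]$"),
    ),
    (
        "repeat_paren",
        re.compile(r"^(?P<unit>[ACGTN]*)\((?P<n>\d+)_(?P<m>\d+)\)$"),
    ),
]


def _parse_bound(token: str) -> Bound:
    if token == "?":
        return Bound()
    if token.startswith("*"):
        return Bound(utr3=True, value=int(token[1:]))
    return Bound(value=int(token))


def _parse_position(rest: str, expression: str) -> tuple[HgvsPosition, str]:
    m = _POS_RE.match(rest)
    if not m:
        raise HgvsParseFailure(expression, rest, "expected a position")
    if m.group("simple") is not None:
        b = _parse_bound(m.group("simple"))
        pos = HgvsPosition(low=b, high=b)
    else:
        try:
            pos = HgvsPosition(
                low=_parse_bound(m.group("plo")),
                high=_parse_bound(m.group("phi")),
                uncertain=True,
            )
        except ValueError as exc:
            raise HgvsParseFailure(expression, rest, str(exc))
    return pos, rest[m.end():]


def parse_hgvs(expression: str) -> HgvsVariant:
    """Parse one HGVS expression of the supported subset.

    Raises :class:`HgvsParseFailure` for anything outside the grammar —
    never a silent partial result.
    """
    expression = expression.strip()
    top = _TOP_RE.match(expression)
    if not top:
        raise HgvsParseFailure(expression, expression, "no accession:kind. prefix")
    rest = top.group("rest")
    start, rest = _parse_position(rest, expression)
    end: Optional[HgvsPosition] = None
    if rest.startswith("_"):
        end, rest = _parse_position(rest[1:], expression)
    if not rest:
        raise HgvsParseFailure(expression, rest, "missing edit")

    common = dict(
        accession=top.group("acc"),
        coordinate_kind=top.group("kind"),
        start=start,
        end=end,
    )
    for kind, regex in _EDIT_RES:
        m = regex.match(rest)
        if not m:
            continue
        try:
            if kind == "substitution":
                return HgvsVariant(
                    edit_kind="substitution",
                    ref=m.group("ref"),
                    alt=m.group("alt"),
                    **common,
                )
            if kind == "delins":
                return HgvsVariant(edit_kind="delins", inserted=m.group("seq"), **common)
            if kind == "deletion":
                what = m.group("what")
                ref = length = None
                if what and what.isdigit():
                    length = int(what)
                elif what:
                    ref = what
                return HgvsVariant(
                    edit_kind="deletion", ref=ref, deleted_length=length, **common
                )
            if kind == "duplication":
                return HgvsVariant(edit_kind="duplication", ref=m.group("seq"), **common)
            if kind == "insertion":
                return HgvsVariant(edit_kind="insertion", inserted=m.group("seq"), **common)
            if kind == "repeat":
                n = int(m.group("n"))
                mm = int(m.group("m")) if m.group("m") else n
                return HgvsVariant(
                    edit_kind="repeat",
                    repeat_unit=m.group("unit") or None,
                    repeat_count=(n, mm),
                    **common,
                )
            if kind == "repeat_paren":
                return HgvsVariant(
                    edit_kind="repeat",
                    repeat_unit=m.group("unit") or None,
                    repeat_count=(int(m.group("n")), int(m.group("m"))),
                    repeat_count_uncertain=True,
                    **common,
                )
        except ValueError as exc:
            raise HgvsParseFailure(expression, rest, str(exc))
    raise HgvsParseFailure(expression, rest, "unrecognized edit")


def try_parse_hgvs(expression: str) -> Optional[HgvsVariant]:
    """Like :func:`parse_hgvs` but returns None on failure."""
    try:
        return parse_hgvs(expression)
    except HgvsParseFailure:
        return None


def unparse(variant: HgvsVariant) -> str:
    """Render a variant back to HGVS text; inverse of :func:`parse_hgvs`."""
    loc = str(variant.start)
    if variant.end is not None:
        loc += f"_{variant.end}"
    k = variant.edit_kind
    if k == "substitution":
        edit = f"{variant.ref}>{variant.alt}"
    elif k == "delins":
        edit = f"delins{variant.inserted}"
    elif k == "deletion":
        if variant.deleted_length is not None:
            edit = f"del{variant.deleted_length}"
        else:
            edit = f"del{variant.ref or ''}"
    elif k == "duplication":
        edit = f"dup{variant.ref or ''}"
    elif k == "insertion":
        edit = f"ins{variant.inserted}"
    else:  # repeat
        unit = variant.repeat_unit or ""
        n, m = variant.repeat_count
        if variant.repeat_count_uncertain:
            edit = f"{unit}({n}_{m})"
        elif n == m:
            edit = f"{unit}[{n}]"
        else:
            edit = f"{unit}[{n}_{m}]"
    return f"{variant.accession}:{variant.coordinate_kind}.{loc}{edit}"
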