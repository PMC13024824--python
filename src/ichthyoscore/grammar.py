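"""Parsing and canonical serialization of semi-quantitative histology score codes.

The scoring system used throughout this package grades each histological axis
(stratum corneum hyperkeratosis, stratum granulosum, acanthosis, inflammation)
on a shared five-token ordinal scale::

    −−   ABSENT
    −    LOW
    +    MID
    ++   HIGH
    +++  TOP

What a token *means* is attached at interpretation time: on the stratum
granulosum axis ``−−`` is "absent" and ``+`` is "normal", while on the
inflammation axis ``−`` is "no inflammation" and ``+`` is "mild".  The token
syntax, however, is shared, which is what makes a single grammar possible.

Real-world report cells are messier than single tokens: they contain grade
ranges (``−−/−``), focal elevations (``+, focal ++``), purely focal findings
(``focal +``), stratum-corneum descriptors mixing a grade with keratinization
and texture words (``+, OK, focal PK, compact/lamellar``), and multi-biopsy
cells with index prefixes (``1,2: +, OK, lamellar``).  This module parses all
of these into typed values and serializes them back into a canonical form that
re-parses to an equal value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Union

__all__ = [
    "Grade",
    "GradeSpan",
    "Keratinization",
    "Texture",
    "CorneumDescriptor",
    "NOT_ASSESSABLE",
    "NotAssessable",
    "ScoreParseError",
    "parse_grade_span",
    "parse_corneum",
    "split_per_biopsy",
    "canonical_serialize",
    "serialize_corneum",
]

# Canonical minus is U+2212; hyphen-minus, en dash and em dash all normalize to it.
MINUS = "−"
_MINUS_VARIANTS = "-–—−"


class ScoreParseError(ValueError):
    """A score-code cell could not be parsed.

    Carries the offending token and, where known, its position in the
    normalized input so that fixture errors are row-addressable.
    """

    def __init__(self, message: str, token: str | None = None, position: int | None = None):
        self.token = token
        self.position = position
        detail = message
        if token is not None:
            detail += f" (token {token!r}"
            if position is not None:
                detail += f" at position {position}"
            detail += ")"
        super().__init__(detail)


class Grade(IntEnum):
    """Ordinal grade on the shared five-level token scale."""

    ABSENT = 0  # −−
    LOW = 1     # −
    MID = 2     # +
    HIGH = 3    # ++
    TOP = 4     # +++

    @property
    def token(self) -> str:
        return _GRADE_TO_TOKEN[self]


_GRADE_TO_TOKEN = {
    Grade.ABSENT: MINUS * 2,
    Grade.LOW: MINUS,
    Grade.MID: "+",
    Grade.HIGH: "++",
    Grade.TOP: "+++",
}
_TOKEN_TO_GRADE = {tok: grade for grade, tok in _GRADE_TO_TOKEN.items()}
# The word "none" appears in inflammation cells; the legend equates it with "−".
_TOKEN_TO_GRADE["none"] = Grade.LOW


class NotAssessable:
    """Singleton marker for cells recorded as ``n.a.`` / ``n.k.``.

    Distinct from any grade: an absent structure (``−−``) is an observation,
    a non-assessable one is missing data.
    """

    _instance: "NotAssessable | None" = None

    def __new__(cls) -> "NotAssessable":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_ASSESSABLE"

    def __bool__(self) -> bool:
        return False


NOT_ASSESSABLE = NotAssessable()

_NA_TOKENS = {"n.a.", "n.a", "na", "n.k.", "n.k", "nk", "not assessable", "missing"}


def _normalize(text: str) -> str:
    """Unify minus glyph variants and whitespace."""
    for ch in _MINUS_VARIANTS:
        text = text.replace(ch, MINUS)
    return " ".join(text.split())


QUALIFIERS = frozenset({"focal", "partial"})
_QUALIFIER_ALIASES = {"focal": "focal", "partial": "partial", "partly": "partial"}


@dataclass(frozen=True)
class GradeSpan:
    """An ordinal grade or range of grades on one scoring axis.

    ``lo``/``hi`` bound the reported range (``lo <= hi``; a plain grade is the
    degenerate span ``lo == hi``).  A trailing focal sub-code such as
    ``+, focal ++`` is stored as ``focal_elevation`` and never folded into the
    span: focality is a spatial statement, not a severity one.  A *pure* focal
    cell (``focal +``) is the named grade with the ``focal`` qualifier.
    """

    lo: Grade
    hi: Grade
    focal_elevation: Grade | None = None
    qualifiers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"span lo {self.lo!r} exceeds hi {self.hi!r}")
        unknown = set(self.qualifiers) - QUALIFIERS
        if unknown:
            raise ValueError(f"unknown qualifiers {sorted(unknown)}")

    @classmethod
    def single(cls, grade: Grade, **kw) -> "GradeSpan":
        return cls(grade, grade, **kw)

    @property
    def is_single(self) -> bool:
        return self.lo == self.hi


def _parse_grade_token(token: str, position: int = 0) -> Grade:
    grade = _TOKEN_TO_GRADE.get(token.strip())
    if grade is None:
        raise ScoreParseError("unrecognized grade", token=token, position=position)
    return grade


def _parse_span_core(token: str, position: int = 0) -> tuple[Grade, Grade]:
    """Parse ``X`` or ``X/Y`` into (lo, hi). Non-contiguous spans are allowed
    (the source table contains ``−−/++``); a reversed pair is ordered."""
    parts = token.split("/")
    if len(parts) == 1:
        g = _parse_grade_token(parts[0], position)
        return g, g
    if len(parts) == 2:
        a = _parse_grade_token(parts[0], position)
        b = _parse_grade_token(parts[1], position)
        return (a, b) if a <= b else (b, a)
    raise ScoreParseError("too many '/' in grade span", token=token, position=position)


def parse_grade_span(text: str) -> Union[GradeSpan, NotAssessable]:
    """Parse a single-axis score cell into a :class:`GradeSpan`.

    Accepted shapes: ``+``, ``−−/−``, ``+, focal ++``, ``focal +``,
    ``+, partial`` and the not-assessable markers ``n.a.``/``n.k.``.
    Unicode minus, hyphen-minus and dashes are interchangeable.
    """
    if text is None or not str(text).strip():
        raise ScoreParseError("empty score cell")
    norm = _normalize(str(text))
    if norm.lower() in _NA_TOKENS:
        return NOT_ASSESSABLE

    segments = [s.strip() for s in norm.split(",") if s.strip()]
    head = segments[0]
    qualifiers: set[str] = set()
    focal_elevation: Grade | None = None

    m = re.fullmatch(r"(focal|partly|partial)\s+(\S+)", head, flags=re.IGNORECASE)
    if m:
        # Pure focal/partial cell: the grade is present, with spatial qualifier.
        qualifiers.add(_QUALIFIER_ALIASES[m.group(1).lower()])
        lo, hi = _parse_span_core(m.group(2), norm.find(m.group(2)))
    else:
        lo, hi = _parse_span_core(head)

    for seg in segments[1:]:
        pos = norm.find(seg)
        m = re.fullmatch(r"(focal|partly|partial)\s+(\S+)", seg, flags=re.IGNORECASE)
        if m:
            kind = _QUALIFIER_ALIASES[m.group(1).lower()]
            grade = _parse_grade_token(m.group(2), pos)
            if kind == "focal":
                if focal_elevation is not None:
                    raise ScoreParseError("multiple focal sub-codes", token=seg, position=pos)
                focal_elevation = grade
            else:
                # "partly X" widens the reported range; rare, kept for completeness.
                qualifiers.add("partial")
                lo, hi = min(lo, grade), max(hi, grade)
            continue
        low = seg.lower()
        if low in _QUALIFIER_ALIASES:
            qualifiers.add(_QUALIFIER_ALIASES[low])
            continue
        raise ScoreParseError("unrecognized span segment", token=seg, position=pos)

    return GradeSpan(lo, hi, focal_elevation=focal_elevation, qualifiers=frozenset(qualifiers))


def canonical_serialize(span: Union[GradeSpan, NotAssessable]) -> str:
    """Serialize a span to its canonical score code; round-trips through
    :func:`parse_grade_span` to an equal value."""
    if isinstance(span, NotAssessable):
        return "n.a."
    if span.is_single:
        base = span.lo.token
    else:
        base = f"{span.lo.token}/{span.hi.token}"
    prefix = ""
    if "focal" in span.qualifiers:
        prefix = "focal "
    out = prefix + base
    if "partial" in span.qualifiers and "focal" not in span.qualifiers:
        out = "partial " + base
    if span.focal_elevation is not None:
        out += f", focal {span.focal_elevation.token}"
    return out


# ---------------------------------------------------------------------------
# Stratum corneum descriptor
# ---------------------------------------------------------------------------

class Keratinization(Enum):
    """Cornification mode of the stratum corneum.

    ``ORTHO_PARA_STAGGERED`` is the alternating ("OK/PK") arrangement;
    ``PARA_FOCAL_ORTHO`` covers parakeratosis-dominant cells with focal
    orthokeratosis ("PK, focal OK")."""

    ORTHO = "OK"
    PARA = "PK"
    ORTHO_FOCAL_PARA = "OK, focal PK"
    ORTHO_PARA_STAGGERED = "OK/PK"
    PARA_FOCAL_ORTHO = "PK, focal OK"

    @property
    def has_parakeratosis(self) -> bool:
        return self is not Keratinization.ORTHO

    @property
    def is_orthokeratotic(self) -> bool:
        """Orthokeratosis-based cornification (allows focal parakeratosis)."""
        return self in (Keratinization.ORTHO, Keratinization.ORTHO_FOCAL_PARA)


class Texture(Enum):
    LAMELLAR = "lamellar"
    COMPACT = "compact"
    BASKET_WEAVE = "basket weave"


_TEXTURE_ALIASES = {
    "lamellar": Texture.LAMELLAR,
    "compact": Texture.COMPACT,
    "basket weave": Texture.BASKET_WEAVE,
    "basket-weave": Texture.BASKET_WEAVE,
    "basketweave": Texture.BASKET_WEAVE,
    "basket weave-like": Texture.BASKET_WEAVE,
    "basket-weave-like": Texture.BASKET_WEAVE,
}
_TEXTURE_ORDER = [Texture.LAMELLAR, Texture.COMPACT, Texture.BASKET_WEAVE]


@dataclass(frozen=True)
class CorneumDescriptor:
    """Full stratum-corneum cell: hyperkeratosis grade, cornification mode,
    texture set and subcorneal clefting flag.

    ``grade`` may be NOT_ASSESSABLE: one reference cell reports cornification
    mode and texture without a measurable hyperkeratosis grade."""

    grade: Union[GradeSpan, NotAssessable]
    keratinization: Keratinization
    textures: frozenset[Texture] = field(default_factory=frozenset)
    clefting_subcorneal: bool = False


_KERAT_WORDS = {"ok", "pk"}


def _is_grade_like(token: str) -> bool:
    return all(ch in "+" + MINUS + "/" for ch in token.replace(" ", "")) and bool(token.strip())


def parse_corneum(text: str) -> Union[CorneumDescriptor, NotAssessable]:
    """Parse a stratum-corneum cell such as ``+, OK, focal PK, compact/lamellar``.

    Grammar: a leading grade span, a mandatory keratinization statement built
    from OK/PK tokens (``OK``, ``PK``, ``OK/PK``, ``OK, focal PK``,
    ``PK, focal OK``), an optional texture set (slash-, comma- or ``>``-
    separated) and the optional literal ``subcorneal clefting``.
    """
    if text is None or not str(text).strip():
        raise ScoreParseError("empty SC cell")
    norm = _normalize(str(text))
    if norm.lower() in _NA_TOKENS:
        return NOT_ASSESSABLE

    # ">" ranks textures (e.g. "compact > lamellar"); we keep the set.
    segments: list[str] = []
    for seg in norm.split(","):
        seg = seg.strip().rstrip(";").strip()
        if seg:
            segments.append(seg)

    grade: Union[GradeSpan, None] = None
    has_ok = False
    has_pk = False
    focal_pk = False
    focal_ok = False
    staggered = False
    textures: set[Texture] = set()
    clefting = False

    def _looks_like_grade_segment(seg: str) -> bool:
        body = re.sub(r"^(focal|partly|partial)\s+", "", seg, flags=re.IGNORECASE)
        return _is_grade_like(body)

    for seg in segments:
        pos = norm.find(seg)
        low = seg.lower()
        if low == "subcorneal clefting":
            clefting = True
            continue
        if low == "ok/pk":
            staggered = True
            continue
        if low == "ok":
            has_ok = True
            continue
        if low == "pk":
            has_pk = True
            continue
        m = re.fullmatch(r"focal\s+(ok|pk)", low)
        if m:
            if m.group(1) == "pk":
                focal_pk = True
            else:
                focal_ok = True
            continue
        if _looks_like_grade_segment(seg):
            if grade is None:
                parsed = parse_grade_span(seg)
                assert isinstance(parsed, GradeSpan)
                grade = parsed
                continue
            m = re.fullmatch(r"focal\s+(\S+)", low)
            if m and _is_grade_like(m.group(1)):
                # trailing focal sub-code elevates the existing grade
                if grade.focal_elevation is not None:
                    raise ScoreParseError("multiple focal sub-codes", token=seg, position=pos)
                grade = GradeSpan(
                    grade.lo, grade.hi,
                    focal_elevation=_parse_grade_token(_normalize(m.group(1)), pos),
                    qualifiers=grade.qualifiers,
                )
                continue
            raise ScoreParseError("multiple grade tokens in SC cell", token=seg, position=pos)
        # Texture list: split on slashes and "and".  Hyphens were normalized
        # to the canonical minus glyph above; restore them for word matching.
        parts = re.split(r"/|\band\b", low.replace(MINUS, "-"))
        matched = True
        found: list[Texture] = []
        for part in parts:
            part = part.strip().strip(">").strip()
            if not part:
                continue
            # allow ranked textures "compact > lamellar"
            for sub in part.split(">"):
                sub = sub.strip()
                if not sub:
                    continue
                tex = _TEXTURE_ALIASES.get(sub)
                if tex is None:
                    matched = False
                else:
                    found.append(tex)
        if matched and found:
            textures.update(found)
            continue
        raise ScoreParseError("unrecognized SC token", token=seg, position=pos)

    if staggered:
        kerat = Keratinization.ORTHO_PARA_STAGGERED
    elif has_ok and focal_pk:
        kerat = Keratinization.ORTHO_FOCAL_PARA
    elif has_pk and focal_ok:
        kerat = Keratinization.PARA_FOCAL_ORTHO
    elif has_ok and not has_pk:
        kerat = Keratinization.ORTHO
    elif has_pk and not has_ok:
        kerat = Keratinization.PARA
    elif has_ok and has_pk:
        # "OK, PK" without staggering marker: treat as staggered mix.
        kerat = Keratinization.ORTHO_PARA_STAGGERED
    else:
        raise ScoreParseError("SC cell lacks a keratinization (OK/PK) token", token=norm)

    return CorneumDescriptor(
        grade=NOT_ASSESSABLE if grade is None else grade,
        keratinization=kerat,
        textures=frozenset(textures),
        clefting_subcorneal=clefting,
    )


def serialize_corneum(desc: Union[CorneumDescriptor, NotAssessable]) -> str:
    """Canonical SC cell string; round-trips through :func:`parse_corneum`."""
    if isinstance(desc, NotAssessable):
        return "n.a."
    parts = []
    if not isinstance(desc.grade, NotAssessable):
        parts.append(canonical_serialize(desc.grade))
    parts.append(desc.keratinization.value)
    if desc.textures:
        ordered = [t.value for t in _TEXTURE_ORDER if t in desc.textures]
        parts.append("/".join(ordered))
    if desc.clefting_subcorneal:
        parts.append("subcorneal clefting")
    return ", ".join(parts)


# ---------------------------------------------------------------------------
# Multi-biopsy cells
# ---------------------------------------------------------------------------

# Index prefix: "1:", "1,2:", "1; 2:", "1–3, 8–14:".  Must start after
# whitespace/start-of-string so grade tokens are never mistaken for indices.
_PREFIX_RE = re.compile(
    rf"(?:(?<=[\s;])|^)(\d+(?:\s*[,;{MINUS}]\s*\d+)*)\s*:\s*"
)


def _expand_indices(prefix: str) -> list[int]:
    prefix = _normalize(prefix)
    indices: list[int] = []
    for chunk in re.split(r"[,;]", prefix):
        chunk = chunk.strip()
        if not chunk:
            continue
        if MINUS in chunk:
            a, b = chunk.split(MINUS)
            a, b = int(a), int(b)
            if b < a:
                raise ScoreParseError("descending index range", token=chunk)
            indices.extend(range(a, b + 1))
        else:
            indices.append(int(chunk))
    return indices


def split_per_biopsy(text: str) -> dict[int, str]:
    """Split a multi-biopsy cell into ``{biopsy_index: raw code}``.

    A cell without index prefixes maps entirely to biopsy 1.  Shared prefixes
    (``1,2:``) and ranges (``1–3, 8–14:``) expand to every listed index;
    assigning the same biopsy twice is an error.
    """
    if text is None:
        raise ScoreParseError("empty multi-biopsy cell")
    norm = _normalize(str(text))
    matches = list(_PREFIX_RE.finditer(norm))
    if not matches:
        return {1: norm.strip().strip(";").strip()}

    leading = norm[: matches[0].start()].strip().strip(";").strip()
    if leading:
        raise ScoreParseError(
            "text precedes first biopsy index prefix", token=leading, position=0
        )

    out: dict[int, str] = {}
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(norm)
        code = norm[m.end() : end].strip().strip(";").strip()
        for idx in _expand_indices(m.group(1)):
            if idx in out:
                raise ScoreParseError(
                    f"biopsy index {idx} assigned more than once", token=m.group(1)
                )
            out[idx] = code
    return dict(sorted(out.items()))
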