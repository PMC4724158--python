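"""Recognition and normalization of melting-point declarations in text.

Experimental sections of patents report melting points in many lexical
shapes — ``m.p. 75 °C``, ``melting point one hundred degrees Celsius``,
``mp 184–186``, ``mpt 50 ± 1 °C``, ``m.p. 210 °C decomp.`` — all of which
follow one underlying grammar::

    FromLiterature? MeltingPoint Qualifier? (Value|Range|MeasurementError) OutcomeQualifier?

This module compiles that grammar into a scanner, collapses the lexical
variants into a single :class:`MPMention` representation, converts every
mention to a Celsius interval (:class:`NormalizedMP`), repairs the common
typographic defects of patent text (decimal commas, truncated range upper
bounds), and flags values that are likely to be wrong (implausibly high,
implausibly wide, inverted, or below absolute zero).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Tuple

__all__ = [
    "PrefixKind",
    "Qualifier",
    "ValueKind",
    "Unit",
    "Outcome",
    "SuspiciousReason",
    "MPMention",
    "NormalizedMP",
    "parse_mention",
    "parse_all",
    "normalize",
    "repair",
    "flag_suspicious",
    "process_text",
    "ABSOLUTE_ZERO_C",
]

ABSOLUTE_ZERO_C = -273.15


class PrefixKind(str, Enum):
    MP_ABBREV = "mp_abbrev"
    MP_PHRASE = "mp_phrase"


class Qualifier(str, Enum):
    GREATER = "greater"
    LESS = "less"
    APPROX = "approx"
    NONE = "none"


class ValueKind(str, Enum):
    SINGLE = "single"
    RANGE = "range"
    MEASUREMENT_ERROR = "measurement_error"


class Unit(str, Enum):
    CELSIUS = "celsius"
    FAHRENHEIT = "fahrenheit"


class Outcome(str, Enum):
    MELT = "melt"
    DECOMPOSE = "decompose"
    SUBLIME = "sublime"


class SuspiciousReason(str, Enum):
    ABOVE_500 = "above_500"
    RANGE_OVER_50 = "range_over_50"
    INVERTED_RANGE = "inverted_range"
    BELOW_ABSOLUTE_ZERO = "below_absolute_zero"


@dataclass(frozen=True)
class MPMention:
    """One melting-point declaration as matched in the source text."""

    raw_text: str
    prefix_kind: PrefixKind
    from_literature: bool
    qualifier: Qualifier
    value_kind: ValueKind
    v1: float
    v2: Optional[float]  # range upper bound or error half-width
    unit: Unit
    outcome: Outcome
    char_span: Tuple[int, int]  # half-open [start, end) into the source


@dataclass(frozen=True)
class NormalizedMP:
    """A melting point reduced to a Celsius interval.

    Single values are stored as degenerate intervals (``low_c == high_c``);
    measurement errors ``v ± e`` become ``[v - e, v + e]``.
    """

    low_c: float
    high_c: float
    qualifier: Qualifier = Qualifier.NONE
    outcome: Outcome = Outcome.MELT
    suspicious: bool = False
    suspicious_reasons: frozenset = field(default_factory=frozenset)
    raw_text: str = ""

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low_c + self.high_c)


# ---------------------------------------------------------------------------
# Grammar as a compiled scanner
# ---------------------------------------------------------------------------

_ONES = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}
_NUMBER_WORDS = sorted(set(_ONES) | set(_TENS) | {"hundred", "and"},
                       key=len, reverse=True)
_WORDNUM = r"(?:%s)(?:[ \t-]+(?:%s))*" % (
    "|".join(_NUMBER_WORDS), "|".join(_NUMBER_WORDS))

# minus may appear as ASCII hyphen, unicode minus or en-dash in patents
_SIGN = r"[-−]?"
_NUM = _SIGN + r"\d+(?:\.\d+)?"
# range endpoints additionally tolerate a decimal comma ("82,5"); repaired later
_NUMC = _SIGN + r"\d+(?:[.,]\d+)?"

_UNIT = (
    r"°\s?(?P<u_sym>[CF])"
    r"|degrees?\s+(?P<u_word>celsius|centigrade|fahrenheit)"
    r"|deg\.?\s?(?P<u_deg>[CF])\b"
)

_PREFIX = (
    r"(?P<p_phrase>melting\s+point|melting\s+pt\.?)"
    r"|(?P<p_abbrev>m\.\s?p\.?t?\.?|mpt\.?|mp\.?)"
)

_QUAL = r"(?P<q>>|<|≥|≤|~|about|approximately|approx\.?|ca\.?)"

_OUTCOME = (
    r"(?P<o>\(\s*(?:decomp\.?|dec\.?|subl\.?)\s*\)"
    r"|with\s+decomposition|with\s+sublimation"
    r"|decomposition|decomposes|decomp\.?|dec\.?"
    r"|sublimation|sublimes|subl\.?)(?![A-Za-z])"
)

_BODY = (
    # measurement error: 50 ± 1
    r"(?P<ev>{num})\s*(?:±|\+/-|\+-)\s*(?P<ee>{num})"
    # range: 184–186, 159-62, 82-82,5, 100 to 102
    r"|(?P<r1>{numc})\s*(?:–|—|−|-|\bto\b)\s*(?P<r2>{numc})"
    # single numeric or spelled-out value
    r"|(?P<sv>{num})"
    r"|(?P<sw>{words})"
).format(num=_NUM, numc=_NUMC, words=_WORDNUM)

_MENTION_RE = re.compile(
    r"(?:(?P<lit>lit\.?|literature)[\s:,]+)?"
    r"(?<![A-Za-z])(?:%(prefix)s)(?![A-Za-z])"
    r"[\s:=]*"
    r"(?:%(qual)s\s*)?"
    r"(?:%(body)s)"
    r"(?:\s*(?:%(unit)s))?"
    r"(?:[\s,;]*(?:%(outcome)s))?"
    % {"prefix": _PREFIX, "qual": _QUAL, "body": _BODY,
       "unit": _UNIT, "outcome": _OUTCOME},
    re.IGNORECASE,
)

_QUAL_MAP = {
    ">": Qualifier.GREATER, "≥": Qualifier.GREATER,
    "<": Qualifier.LESS, "≤": Qualifier.LESS,
    "~": Qualifier.APPROX, "about": Qualifier.APPROX,
    "approximately": Qualifier.APPROX, "approx": Qualifier.APPROX,
    "approx.": Qualifier.APPROX, "ca": Qualifier.APPROX, "ca.": Qualifier.APPROX,
}


def _spelled_to_number(words: str) -> float:
    """Convert a spelled-out cardinal (up to 999) to a number."""
    total = 0
    for tok in re.split(r"[ \t-]+", words.lower()):
        if tok == "and" or not tok:
            continue
        if tok in _ONES:
            total += _ONES[tok]
        elif tok in _TENS:
            total += _TENS[tok]
        elif tok == "hundred":
            total = (total or 1) * 100
        else:  # pragma: no cover - regex admits only known words
            raise ValueError(f"unknown number word {tok!r}")
    return float(total)


def _to_float(token: str) -> float:
    return float(token.replace(",", ".").replace("−", "-").replace("–", "-"))


def _build_mention(m: re.Match, text: str) -> MPMention:
    prefix_kind = (PrefixKind.MP_PHRASE if m.group("p_phrase")
                   else PrefixKind.MP_ABBREV)
    qual_tok = m.group("q")
    qualifier = (_QUAL_MAP[qual_tok.lower()] if qual_tok else Qualifier.NONE)

    if m.group("ev") is not None:
        kind = ValueKind.MEASUREMENT_ERROR
        v1, v2 = _to_float(m.group("ev")), _to_float(m.group("ee"))
    elif m.group("r1") is not None:
        kind = ValueKind.RANGE
        v1, v2 = repair(m.group("r1"), m.group("r2"))
    elif m.group("sv") is not None:
        kind = ValueKind.SINGLE
        v1, v2 = _to_float(m.group("sv")), None
    else:
        kind = ValueKind.SINGLE
        v1, v2 = _spelled_to_number(m.group("sw")), None

    unit = Unit.CELSIUS
    u = (m.group("u_sym") or m.group("u_word") or m.group("u_deg") or "")
    if u.lower() in ("f", "fahrenheit"):
        unit = Unit.FAHRENHEIT

    outcome = Outcome.MELT
    o = (m.group("o") or "").lower()
    if "dec" in o:
        outcome = Outcome.DECOMPOSE
    elif "subl" in o:
        outcome = Outcome.SUBLIME

    start, end = m.span()
    return MPMention(
        raw_text=text[start:end],
        prefix_kind=prefix_kind,
        from_literature=m.group("lit") is not None,
        qualifier=qualifier,
        value_kind=kind,
        v1=v1,
        v2=v2,
        unit=unit,
        outcome=outcome,
        char_span=(start, end),
    )


def parse_mention(text: str, start_offset: int = 0) -> Optional[MPMention]:
    """Return the first melting-point mention at or after ``start_offset``.

    Text that does not contain a grammar-conformant declaration (e.g. a
    boiling point) yields ``None``.
    """
    pos = start_offset
    while pos <= len(text):
        m = _MENTION_RE.search(text, pos)
        if m is None:
            return None
        try:
            return _build_mention(m, text)
        except ValueError:
            pos = m.start() + 1
    return None


def parse_all(text: str) -> Iterator[MPMention]:
    """Iterate over every melting-point mention in ``text``, left to right."""
    pos = 0
    while True:
        mention = parse_mention(text, pos)
        if mention is None:
            return
        yield mention
        pos = mention.char_span[1]


def repair(raw_low: str, raw_high: str) -> Tuple[float, float]:
    """Repair the common defects of range endpoints in patent text.

    Decimal commas are replaced by dots (``82-82,5``); a truncated upper
    bound borrows the missing leading digits of the lower bound so that the
    two bounds have the same digit count before the decimal point and
    ``upper >= lower`` (``159-62`` -> 159-162, ``160-2`` -> 160-162).  When
    no borrowing produces ``upper >= lower`` the values are returned
    unchanged and the inverted-range flag fires downstream.
    """
    lo_s = raw_low.strip().replace(",", ".").replace("−", "-")
    hi_s = raw_high.strip().replace(",", ".").replace("−", "-")
    lo, hi = float(lo_s), float(hi_s)
    if hi >= lo:
        return lo, hi
    lo_int = lo_s.split(".")[0].lstrip("-")
    hi_int = hi_s.split(".")[0].lstrip("-")
    if 0 < len(hi_int) < len(lo_int) and not hi_s.startswith("-"):
        candidate = float(lo_int[: len(lo_int) - len(hi_int)] + hi_s)
        if candidate >= lo:
            return lo, candidate
    return lo, hi


def _f_to_c(f: float) -> float:
    return (f - 32.0) * 5.0 / 9.0


def normalize(m: MPMention) -> NormalizedMP:
    """Collapse a mention to a Celsius interval, retaining the raw text."""
    if m.value_kind is ValueKind.SINGLE:
        low, high = m.v1, m.v1
    elif m.value_kind is ValueKind.RANGE:
        low, high = m.v1, m.v2
    else:  # measurement error v1 ± v2 becomes a range
        low, high = m.v1 - m.v2, m.v1 + m.v2
    if m.unit is Unit.FAHRENHEIT:
        low, high = _f_to_c(low), _f_to_c(high)
    return NormalizedMP(
        low_c=low,
        high_c=high,
        qualifier=m.qualifier,
        outcome=m.outcome,
        raw_text=m.raw_text,
    )


def flag_suspicious(n: NormalizedMP) -> NormalizedMP:
    """Apply the suspicious-value heuristics, leaving the interval intact.

    A record is flagged when its value exceeds 500 °C, when a range is wider
    than 50 °C, when the second temperature of a range is lower than the
    first (unrepairable), or when a bound sits below absolute zero.
    """
    reasons = set()
    if max(n.low_c, n.high_c) > 500.0:
        reasons.add(SuspiciousReason.ABOVE_500)
    if abs(n.high_c - n.low_c) > 50.0:
        reasons.add(SuspiciousReason.RANGE_OVER_50)
    if n.high_c < n.low_c:
        reasons.add(SuspiciousReason.INVERTED_RANGE)
    if min(n.low_c, n.high_c) < ABSOLUTE_ZERO_C:
        reasons.add(SuspiciousReason.BELOW_ABSOLUTE_ZERO)
    if not reasons:
        return n
    return replace(n, suspicious=True, suspicious_reasons=frozenset(reasons))


def process_text(text: str) -> Iterator[NormalizedMP]:
    """Parse, normalize and flag every mention in ``text``."""
    for mention in parse_all(text):
        yield flag_suspicious(normalize(mention))
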