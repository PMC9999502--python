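"""WHO ATC classification code handling.

ATC codes are hierarchical 7-character identifiers (anatomical main group
through chemical substance).  Valid truncation points are the five canonical
levels:

==== ======= ====================== ========
len  example level                  pattern
==== ======= ====================== ========
1    N       anatomical main group  L
3    N05     therapeutic subgroup   Ldd
4    N05C    pharmacological group  LddL
5    N05CD   chemical subgroup      LddLL
7    N05CD08 chemical substance     LddLLdd
==== ======= ====================== ========

Class-level statements in explicit PIM criteria are expressed as one of the
four truncated levels; individual drug substances are always 7 characters.
Matching is positional string-prefix matching, which is exactly how the ATC
hierarchy nests.
"""

from __future__ import annotations

import re

CANONICAL_LENGTHS = (1, 3, 4, 5, 7)

_LEVEL_RE = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d\d$"),
    4: re.compile(r"^[A-Z]\d\d[A-Z]$"),
    5: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]$"),
    7: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]\d\d$"),
}


def is_valid_pattern(code: str) -> bool:
    """True if *code* is a syntactically valid ATC code or class prefix."""
    if not isinstance(code, str):
        return False
    rx = _LEVEL_RE.get(len(code))
    return bool(rx and rx.match(code))


def is_substance_code(code: str) -> bool:
    """True for a full 7-character substance-level code."""
    return len(code) == 7 and is_valid_pattern(code)


def validate_pattern(code: str) -> str:
    """Return *code* unchanged, raising ``ValueError`` if it is not a valid
    ATC pattern at one of the five canonical levels."""
    if not is_valid_pattern(code):
        raise ValueError(
            f"{code!r} is not a valid ATC pattern "
            f"(lengths {CANONICAL_LENGTHS}, e.g. 'N05C' or 'N06AA09')"
        )
    return code


def matches_prefix(code: str, pattern: str) -> bool:
    """Positional prefix match of a substance *code* against an ATC *pattern*.

    A 7-character substance code belongs to class ``N05C`` iff its text
    starts with ``N05C``; the five canonical lengths make this unambiguous.
    """
    return code.startswith(pattern)


def class_of(code: str, level_length: int) -> str:
    """Truncate a substance code to the class prefix of the given length."""
    if level_length not in CANONICAL_LENGTHS:
        raise ValueError(f"level length must be one of {CANONICAL_LENGTHS}")
    if level_length > len(code):
        raise ValueError(f"code {code!r} shorter than requested level")
    return code[:level_length]
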