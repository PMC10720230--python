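"""ICD-10 category codes and the 22-chapter grouping.

Diseases are identified by 3-character ICD-10 category codes (one letter
followed by two digits, e.g. ``I10``).  Each category belongs to one of the
22 chapters of the classification; the chapter ranges are shipped as a
packaged data table (``data/icd10_chapters.csv``).  Chapters 1-14 — the
somatic disease chapters from infectious diseases through genitourinary
diseases — are the analysis scope; chapters 15-22 (pregnancy, perinatal,
congenital, symptoms, injury, external causes, factors influencing health
status, and special-purpose U codes) are filtered out upstream.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib import resources

__all__ = [
    "CODE_PATTERN",
    "IN_SCOPE_CHAPTERS",
    "InvalidCodeError",
    "chapter",
    "normalize_code",
]

CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}$")

#: Chapters retained by the cohort filters (infectious ... genitourinary).
IN_SCOPE_CHAPTERS = frozenset(range(1, 15))


class InvalidCodeError(ValueError):
    """Raised when a raw diagnosis string cannot be reduced to a valid code."""


@lru_cache(maxsize=1)
def _chapter_ranges() -> tuple[tuple[str, str, int], ...]:
    ref = resources.files("mmnet.data").joinpath("icd10_chapters.csv")
    with ref.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return tuple((r["start"], r["end"], int(r["chapter"])) for r in rows)


@lru_cache(maxsize=4096)
def chapter(code: str) -> int | None:
    """Chapter (1-22) of a 3-character code, or None for gap codes.

    A handful of lexicographically valid categories fall between chapter
    blocks (e.g. D49, E91-E99, V00); these map to no chapter and are
    treated as out of scope by the filters.
    """
    if not CODE_PATTERN.match(code):
        raise InvalidCodeError(f"not a 3-character ICD-10 category: {code!r}")
    for start, end, chap in _chapter_ranges():
        if start <= code <= end:
            return chap
    return None


def normalize_code(raw: str) -> str:
    """Reduce a raw diagnosis string to its 3-character category.

    Uppercases, strips dots and whitespace, and truncates subcategory
    digits: ``"e78.5" -> "E78"``.  Raises :class:`InvalidCodeError` when
    the result is not letter-digit-digit.
    """
    if not raw or not raw.strip():
        raise InvalidCodeError("empty diagnosis code")
    cleaned = raw.strip().upper().replace(".", "")
    code = cleaned[:3]
    if not CODE_PATTERN.match(code):
        raise InvalidCodeError(f"cannot normalize {raw!r} to a category code")
    return code


def in_scope(code: str) -> bool:
    """True when the code's chapter is one of the somatic chapters 1-14."""
    return chapter(code) in IN_SCOPE_CHAPTERS
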