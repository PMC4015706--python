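"""Linkage identifiers: Soundex encoding and agreement patterns.

Linkage in this package is based on five anonymised identifiers only:
sex, the Soundex phonetic code of the surname, and the day, month and
year of birth.  Comparing two records field-by-field yields a five-state
*agreement pattern* over the alphabet {agree, disagree, missing}; every
downstream quantity (match weights, joint match probabilities) is a
function of that pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "FIELDS",
    "AGREE",
    "DISAGREE",
    "MISSING",
    "IdentifierSet",
    "InvalidIdentifierError",
    "soundex",
    "compare_identifiers",
]

#: Canonical field order used everywhere a 5-tuple appears.
FIELDS = ("sex", "soundex", "dob_day", "dob_month", "dob_year")

AGREE = "A"
DISAGREE = "D"
MISSING = "M"

_SOUNDEX_PATTERN = re.compile(r"^[A-Z][0-9]{3}$")

# American Soundex digit classes.
_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


class InvalidIdentifierError(ValueError):
    """Raised when an identifier value cannot be encoded or validated."""


def soundex(surname: str) -> str:
    """Encode a surname as an American Soundex code (letter + 3 digits).

    The first letter is retained; remaining letters map to digit classes
    (B,F,P,V -> 1; C,G,J,K,Q,S,X,Z -> 2; D,T -> 3; L -> 4; M,N -> 5;
    R -> 6).  Vowels and Y act as separators; H and W are transparent, so
    two letters with the same code separated only by H or W collapse to
    one digit.  The result is zero-padded or truncated to three digits.

    Parameters
    ----------
    surname : str
        Surname; case and non-alphabetic characters are ignored.

    Raises
    ------
    InvalidIdentifierError
        If no alphabetic characters remain after cleaning.
    """
    letters = re.sub(r"[^A-Z]", "", surname.upper())
    if not letters:
        raise InvalidIdentifierError(f"no codable letters in surname {surname!r}")

    digits = []
    # Code of the most recent coded letter, for duplicate suppression.
    # Initialise with the first letter's own code so e.g. "Pf" -> P100.
    prev_code = _SOUNDEX_CODES.get(letters[0], "")
    for ch in letters[1:]:
        code = _SOUNDEX_CODES.get(ch)
        if code is None:
            # H and W are transparent (prev_code survives); vowels and Y
            # break the run so a repeated code is counted again.
            if ch not in "HW":
                prev_code = ""
            continue
        if code != prev_code:
            digits.append(code)
            prev_code = code
        if len(digits) == 3:
            break
    return letters[0] + "".join(digits).ljust(3, "0")


@dataclass(frozen=True)
class IdentifierSet:
    """The five linkage identifiers of one record; ``None`` means missing.

    ``sex`` is ``"M"`` or ``"F"``; ``soundex_code`` is a letter followed by
    three digits; date-of-birth components are plain integers compared as
    three separate fields.
    """

    sex: Optional[str] = None
    soundex_code: Optional[str] = None
    dob_day: Optional[int] = None
    dob_month: Optional[int] = None
    dob_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("M", "F"):
            raise InvalidIdentifierError(f"sex must be M/F, got {self.sex!r}")
        if self.soundex_code is not None and not _SOUNDEX_PATTERN.match(
            self.soundex_code
        ):
            raise InvalidIdentifierError(
                f"malformed soundex code {self.soundex_code!r}"
            )
        if self.dob_day is not None and not 1 <= self.dob_day <= 31:
            raise InvalidIdentifierError(f"dob_day out of range: {self.dob_day}")
        if self.dob_month is not None and not 1 <= self.dob_month <= 12:
            raise InvalidIdentifierError(f"dob_month out of range: {self.dob_month}")

    def as_tuple(self) -> tuple:
        return (self.sex, self.soundex_code, self.dob_day, self.dob_month, self.dob_year)


def _state(a, b) -> str:
    if a is None or b is None:
        return MISSING
    return AGREE if a == b else DISAGREE


def compare_identifiers(a: IdentifierSet, b: IdentifierSet) -> str:
    """Compare two identifier sets field by field.

    Returns a 5-character pattern string over A (agree), D (disagree),
    M (either side missing), ordered as :data:`FIELDS`.  Missingness is a
    distinct third state and is never coerced to disagreement, because
    missing values and value errors are injected separately by the
    simulation and carry different evidence.
    """
    return "".join(_state(x, y) for x, y in zip(a.as_tuple(), b.as_tuple()))
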