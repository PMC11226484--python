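"""WHO Anatomical-Therapeutic-Chemical (ATC) classification codes.

ATC codes are hierarchical: a 7-character level-5 code such as ``A10BA02``
identifies a substance (metformin), while its prefixes identify ever broader
groups -- ``A10BA`` (biguanides, level 4), ``A10B`` (blood glucose lowering
drugs, level 3), ``A10`` (drugs used in diabetes, level 2) and ``A``
(alimentary tract and metabolism, level 1).  Therapeutic-equivalence
switching is restricted to substances agreeing at level 5 (exceptionally
level 4), so the package needs exact prefix arithmetic on these codes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ATCCode", "ATCError", "parse_atc", "atc_match"]

# code length -> hierarchy level
_LEVEL_BY_LENGTH = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
# hierarchy level -> prefix length
PREFIX_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

# character class per position: True = letter expected, False = digit
_IS_LETTER = (True, False, False, True, True, False, False)


class ATCError(ValueError):
    """Raised for malformed ATC codes or invalid level requests."""


@dataclass(frozen=True, order=True)
class ATCCode:
    """A validated ATC code at any of the five hierarchy levels."""

    code: str

    @property
    def level(self) -> int:
        return _LEVEL_BY_LENGTH[len(self.code)]

    def prefix(self, level: int) -> str:
        """The code truncated to ``level``; errors if the code is shallower."""
        if level not in PREFIX_LENGTH:
            raise ATCError(f"no such ATC level: {level}")
        if self.level < level:
            raise ATCError(
                f"code {self.code!r} is level {self.level}, "
                f"cannot take a level-{level} prefix"
            )
        return self.code[: PREFIX_LENGTH[level]]

    def prefixes(self) -> tuple[str, ...]:
        """All strict ancestor prefixes, shallowest first."""
        return tuple(
            self.code[: PREFIX_LENGTH[lv]] for lv in range(1, self.level)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def parse_atc(code: str) -> ATCCode:
    """Validate ``code`` against the ATC scheme and wrap it.

    The scheme alternates letters and digits (L DD L L DD); valid lengths
    are 1, 3, 4, 5 and 7 characters.  Validation errors name the offending
    position (0-based).
    """
    if not code:
        raise ATCError("empty ATC code")
    code = code.strip().upper()
    if len(code) not in _LEVEL_BY_LENGTH:
        raise ATCError(
            f"ATC code {code!r} has invalid length {len(code)} "
            "(expected 1, 3, 4, 5 or 7)"
        )
    for pos, ch in enumerate(code):
        want_letter = _IS_LETTER[pos]
        if want_letter and not ch.isalpha():
            raise ATCError(f"ATC code {code!r}: letter expected at position {pos}")
        if not want_letter and not ch.isdigit():
            raise ATCError(f"ATC code {code!r}: digit expected at position {pos}")
    return ATCCode(code)


def atc_match(a: ATCCode, b: ATCCode, level: int) -> bool:
    """True iff ``a`` and ``b`` agree on their level-``level`` prefix.

    Both codes must be at least as deep as ``level``.
    """
    return a.prefix(level) == b.prefix(level)
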