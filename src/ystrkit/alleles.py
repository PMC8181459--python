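"""Exact STR allele repeat designations.

Y-STR alleles are named by repeat count, optionally with a microvariant
suffix giving the number of extra bases beyond complete repeats (e.g. the
DYS576 allele 19.1 = 19 repeats plus one base).  Designations are stored
exactly, as an integer count of tenths, so 19.1 round-trips as "19.1" and
never as 19.100000000000001.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import AlleleParseError

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")

#: Microvariant suffixes seen on commercial Y-STR ladders.
VALID_FRACTIONS = frozenset({0, 1, 2, 3})


@dataclass(frozen=True, order=True)
class AlleleValue:
    """A repeat designation stored exactly in tenths of a repeat.

    ``AlleleValue(tenths=191)`` is the microvariant allele 19.1.
    Ordering and equality follow the numeric value.
    """

    tenths: int

    def __post_init__(self) -> None:
        if self.tenths <= 0:
            raise AlleleParseError(f"allele designation must be positive, got {self.tenths / 10}")
        if self.tenths % 10 not in VALID_FRACTIONS:
            raise AlleleParseError(
                f"fractional part .{self.tenths % 10} is not a valid microvariant suffix"
            )

    @classmethod
    def parse(cls, token: str) -> "AlleleValue":
        """Parse a printed designation like ``"14"`` or ``"19.1"``."""
        m = _ALLELE_RE.match(token.strip())
        if m is None:
            raise AlleleParseError(f"unparsable allele token {token!r}")
        whole = int(m.group(1))
        frac = int(m.group(2)) if m.group(2) is not None else 0
        return cls(tenths=whole * 10 + frac)

    @classmethod
    def from_repeats(cls, repeats: int) -> "AlleleValue":
        """Build an integer-repeat allele (the common, non-microvariant case)."""
        return cls(tenths=int(repeats) * 10)

    @property
    def numeric(self) -> float:
        """Face numeric value used in repeat-count distances (19.1 -> 19.1)."""
        return self.tenths / 10.0

    @property
    def integer_repeats(self) -> int:
        """Complete-repeat count with the microvariant suffix truncated."""
        return self.tenths // 10

    @property
    def is_microvariant(self) -> bool:
        return self.tenths % 10 != 0

    def __str__(self) -> str:
        whole, frac = divmod(self.tenths, 10)
        return str(whole) if frac == 0 else f"{whole}.{frac}"

    def __repr__(self) -> str:
        return f"AlleleValue({self})"
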