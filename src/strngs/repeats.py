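"""Repeat-length values with microvariant ("n.r") semantics.

An STR allele is identified by the number of complete repeat units it
carries.  Sequencing can also reveal *partial* repeats: an allele spanning
13 full units plus 2 extra bases is written ``13.2`` (the convention used
by capillary-electrophoresis nomenclature).  :class:`RepeatLength` keeps
the whole-unit count and the leftover base count as integers, so ``13.2``
never degrades into the float ``13.2``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (``N`` maps to ``N``)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@functools.total_ordering
@dataclass(frozen=True)
class RepeatLength:
    """A repeat count of ``whole`` complete units plus ``remainder`` bases.

    ``remainder`` is measured in base pairs and must be smaller than the
    locus's repeat unit size; that bound is enforced where the unit size
    is known (the caller and the simulator), not here.
    """

    whole: int
    remainder: int = 0

    def __post_init__(self) -> None:
        if self.whole < 0:
            raise ValueError(f"whole repeat count must be >= 0, got {self.whole}")
        if self.remainder < 0:
            raise ValueError(f"remainder must be >= 0, got {self.remainder}")

    @property
    def is_partial(self) -> bool:
        return self.remainder != 0

    def total_bp(self, repeat_size: int) -> int:
        """Length of the repeat tract in base pairs for a given unit size."""
        return self.whole * repeat_size + self.remainder

    @classmethod
    def from_bp(cls, bp: int, repeat_size: int) -> "RepeatLength":
        """Convert a tract length in bp into whole units plus remainder."""
        if bp < 0:
            raise ValueError(f"tract length must be >= 0, got {bp}")
        return cls(bp // repeat_size, bp % repeat_size)

    def shifted(self, units: int) -> "RepeatLength":
        """This length with ``units`` whole repeats added (may raise if < 0)."""
        return RepeatLength(self.whole + units, self.remainder)

    @classmethod
    def parse(cls, text: str) -> "RepeatLength":
        """Parse ``"13"`` or ``"13.2"`` (CE nomenclature) into a value."""
        text = text.strip()
        if "." in text:
            whole_s, _, rem_s = text.partition(".")
            return cls(int(whole_s), int(rem_s))
        return cls(int(text))

    @classmethod
    def coerce(cls, value: "RepeatLength | int | str") -> "RepeatLength":
        if isinstance(value, RepeatLength):
            return value
        if isinstance(value, int):
            return cls(value)
        if isinstance(value, str):
            return cls.parse(value)
        raise TypeError(f"cannot interpret {value!r} as a repeat length")

    def _key(self) -> tuple[int, int]:
        return (self.whole, self.remainder)

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, RepeatLength):
            return NotImplemented
        return self._key() < other._key()

    def __str__(self) -> str:
        if self.remainder:
            return f"{self.whole}.{self.remainder}"
        return str(self.whole)

    def __repr__(self) -> str:
        return f"RepeatLength({self})"
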