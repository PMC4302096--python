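"""RNA sequences with 1-based coordinates.

All coordinates in this package are 1-based and inclusive; the exterior
loop is closed by the pseudo base pair ``psi = (0, n + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALPHABET = frozenset("ACGU")

#: Watson-Crick plus wobble pairs; only these can form base pairs.
COMPLEMENTARY = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)


class InputError(ValueError):
    """Invalid user-supplied sequence or file content."""


def normalize_residues(raw: str) -> str:
    """Uppercase, map T/t to U, and validate against the RNA alphabet."""
    res = raw.upper().replace("T", "U")
    bad = set(res) - ALPHABET
    if bad:
        raise InputError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return res


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence; ``seq[i]`` returns the base at 1-based position i."""

    id: str
    residues: str = field()

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError("empty sequence")
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.residues[i - 1]

    def can_pair(self, i: int, j: int) -> bool:
        return (self[i], self[j]) in COMPLEMENTARY
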