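"""Ranked taxonomic lineages in greengenes-style string form.

A lineage is an ordered tuple of rank values from kingdom down to strain.
Deeper ranks may be absent, but there are no gaps: if a rank is present,
every shallower rank is present too.  The string form joins present ranks
with ";" using the conventional one-letter prefixes, e.g.
``k__Bacteria;p__Firmicutes;...;g__Lactobacillus;s__Lactobacillus crispatus``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "strain")
PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")

#: 1-based depth of each rank (kingdom=1 ... strain=8)
RANK_DEPTH = {rank: i + 1 for i, rank in enumerate(RANKS)}
GENUS_DEPTH = RANK_DEPTH["genus"]
SPECIES_DEPTH = RANK_DEPTH["species"]


class LineageError(ValueError):
    """Raised for malformed lineage strings."""


@total_ordering
@dataclass(frozen=True)
class Lineage:
    """An immutable ranked lineage, possibly truncated at any rank."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise LineageError(f"lineage deeper than {len(RANKS)} ranks: {self.names}")
        for name in self.names:
            if not name:
                raise LineageError(f"empty rank value in {self.names!r} (gaps not allowed)")

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        """Parse ``k__...;p__...;...`` into a Lineage.

        Raises LineageError on wrong prefixes, out-of-order ranks or gaps.
        """
        text = text.strip()
        if not text:
            return cls(())
        names = []
        for depth, field in enumerate(text.split(";")):
            field = field.strip()
            if depth >= len(RANKS):
                raise LineageError(f"too many ranks in {text!r}")
            prefix = PREFIXES[depth]
            if not field.startswith(prefix):
                raise LineageError(
                    f"rank {depth + 1} of {text!r} must start with {prefix!r}, got {field!r}"
                )
            value = field[len(prefix):]
            if not value:
                raise LineageError(f"empty {RANKS[depth]} value in {text!r}")
            names.append(value)
        return cls(tuple(names))

    def __str__(self) -> str:
        return ";".join(p + n for p, n in zip(PREFIXES, self.names))

    def __lt__(self, other: "Lineage") -> bool:
        return self.names < other.names

    def __len__(self) -> int:
        return len(self.names)

    @property
    def depth(self) -> int:
        """Number of assigned ranks (kingdom=1 ... strain=8)."""
        return len(self.names)

    @property
    def deepest_rank(self) -> str | None:
        """Name of the deepest assigned rank, or None for an empty lineage."""
        return RANKS[len(self.names) - 1] if self.names else None

    def truncate(self, depth: int) -> "Lineage":
        """Lineage restricted to the first ``depth`` ranks."""
        return Lineage(self.names[:depth])

    def at_rank(self, rank: str) -> str | None:
        """Value at a named rank, or None if unassigned."""
        idx = RANK_DEPTH[rank] - 1
        return self.names[idx] if idx < len(self.names) else None

    def is_prefix_of(self, other: "Lineage") -> bool:
        """True iff this lineage is a (non-strict) rank-prefix of ``other``."""
        return other.names[: len(self.names)] == self.names
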