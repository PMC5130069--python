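"""Domain types shared by all modules.

A *template* is the set of all alignment records sharing one read name
(both mates of a pair plus any secondary/supplementary records).  The
pipeline assigns every template to exactly one of four categories:
species A, species B, ambiguous, or unaligned.

Missing tag values are represented by ``None`` (the ``MISSING`` alias),
never by 0: an alignment without an NM tag must not beat one with
``NM:i:0`` once scores are put on a common orientation.  Translation of
``MISSING`` into numeric worst-case sentinels happens in one place, in
:mod:`xenosplit.scoring`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, List, Optional, Tuple

#: Sentinel for an absent optional tag.  Distinct from 0 by design.
MISSING = None


class XenosplitError(Exception):
    """Base class for all errors raised by this package."""


class SortednessError(XenosplitError):
    """Input records violate the required natural name order."""


class TagFormatError(XenosplitError):
    """An optional tag is present but not an integer."""


class FixtureSpecError(XenosplitError):
    """A synthetic fixture specification is invalid."""


class AssignmentCategory(enum.Enum):
    """Per-template verdict of the disambiguation."""

    SPECIES_A = "SPECIES_A"
    SPECIES_B = "SPECIES_B"
    AMBIGUOUS = "AMBIGUOUS"
    UNALIGNED = "UNALIGNED"

    def mirrored(self) -> "AssignmentCategory":
        """Category under a swap of the two species' roles."""
        if self is AssignmentCategory.SPECIES_A:
            return AssignmentCategory.SPECIES_B
        if self is AssignmentCategory.SPECIES_B:
            return AssignmentCategory.SPECIES_A
        return self


@dataclass(frozen=True)
class TagScores:
    """Per-record alignment quality metrics read from optional tags.

    Parameters
    ----------
    as_score : int or None
        Aligner-reported alignment score (AS tag, higher is better).
    nm : int or None
        Edit distance to the reference (NM tag, lower is better).
    nh : int or None
        Number of reported alignments (NH tag, lower is better).
    xo : int or None
        Number of gap opens (XO tag, lower is better).
    mapped : bool
        False iff the record's unmapped flag is set.  An unmapped record
        contributes no scores: all four metrics must be ``MISSING``.
    """

    as_score: Optional[int] = MISSING
    nm: Optional[int] = MISSING
    nh: Optional[int] = MISSING
    xo: Optional[int] = MISSING
    mapped: bool = True

    def __post_init__(self) -> None:
        for name in ("nm", "nh", "xo"):
            v = getattr(self, name)
            if v is not MISSING and v < 0:
                raise ValueError(f"{name.upper()} must be >= 0, got {v}")
        if not self.mapped and any(
            v is not MISSING for v in (self.as_score, self.nm, self.nh, self.xo)
        ):
            raise ValueError("an unmapped record must carry no scores")


@dataclass
class TemplateGroup:
    """All alignment records of one template in one species' input.

    ``records`` are opaque alignment records in file order; ``scores``
    holds one ``(mate_index, TagScores)`` entry per record, in the same
    order, and is filled lazily by the scoring module.
    """

    template_name: str
    records: List[Any] = field(default_factory=list)
    scores: List[Tuple[int, TagScores]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.records:
            raise ValueError("TemplateGroup must contain at least one record")
        if self.scores and len(self.scores) != len(self.records):
            raise ValueError("scores must have exactly one entry per record")


@dataclass(frozen=True)
class QualityQuad:
    """Best metric value per mate and species, higher always better.

    This is the size-4 quality-score array the decision rules operate
    on: (read 1 vs A, read 2 vs A, read 1 vs B, read 2 vs B).  Absent
    evidence is filled with the scheme's worst-case sentinel, never left
    undefined.
    """

    r1_a: int
    r2_a: int
    r1_b: int
    r2_b: int

    @property
    def pair_a(self) -> Tuple[int, int]:
        return (self.r1_a, self.r2_a)

    @property
    def pair_b(self) -> Tuple[int, int]:
        return (self.r1_b, self.r2_b)


@dataclass(frozen=True)
class SummaryStats:
    """Counts of templates per category for one sample."""

    sample_id: str
    n_species_a: int
    n_species_b: int
    n_ambiguous: int
    n_unaligned: int
    n_total: int

    def validate(self) -> None:
        counts = (
            self.n_species_a,
            self.n_species_b,
            self.n_ambiguous,
            self.n_unaligned,
            self.n_total,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in {self}")
        parts = sum(counts[:4])
        if parts != self.n_total:
            raise ValueError(
                f"category counts sum to {parts}, expected total {self.n_total}"
            )


def strip_mate_suffix(name: str) -> str:
    """Remove a single trailing ``/1`` or ``/2`` mate suffix, if present.

    Applied exactly once per record name; ``"A/1/2"`` becomes ``"A/1"``.

    Raises
    ------
    ValueError
        If ``name`` is empty.
    """
    if not name:
        raise ValueError("read name must be non-empty")
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name
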