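"""Natural name order and synchronized traversal of two record streams.

Both inputs must be natural-name-sorted so the two files can be walked
synchronously with memory bounded by one template group per stream.
"Natural" means embedded digit runs compare numerically (``read2`` <
``read10``), the order produced by common name-sorting of Illumina-style
read names.  Sortedness is validated on the fly and violations are a
hard error: a silently misordered input would corrupt the merge join and
mis-pair templates between the two species.
"""

from __future__ import annotations

import functools
import re
from typing import Any, Callable, Iterable, Iterator, Optional, Tuple

from .core import SortednessError, TemplateGroup, strip_mate_suffix

_DIGIT_RUN = re.compile(rb"(\d+)")


@functools.total_ordering
class NameKey:
    """Sort key decomposing a read name into text and digit-run chunks.

    Numeric chunks are maximal ASCII digit runs and compare by integer
    value; text chunks compare bytewise.  At a position where the kinds
    differ, numeric sorts first.  A name whose chunks are a prefix of
    the other's sorts first.  Equal integer values with different digit
    strings ("007" vs "7") tie-break on the shorter digit string, so the
    order is total.  Concatenating the chunk texts reproduces the name.
    """

    __slots__ = ("name", "chunks", "_key")

    def __init__(self, name: str):
        if not name:
            raise ValueError("read name must be non-empty")
        self.name = name
        raw = name.encode("utf-8")
        parts = _DIGIT_RUN.split(raw)
        chunks = []
        key = []
        for i, part in enumerate(parts):
            if part == b"":
                continue
            if i % 2:  # odd indices are the captured digit runs
                chunks.append((int(part), part.decode()))
                key.append((0, int(part), len(part)))
            else:
                chunks.append(part.decode())
                key.append((1, part))
        self.chunks = tuple(chunks)
        self._key = tuple(key)

    def __eq__(self, other) -> bool:
        return self._key == other._key

    def __lt__(self, other) -> bool:
        return self._key < other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"NameKey({self.name!r})"


def natural_key(name: str) -> NameKey:
    return NameKey(name)


def natural_compare(a: str, b: str) -> int:
    """Three-way natural comparison of two read names (-1, 0 or 1)."""
    ka, kb = NameKey(a), NameKey(b)
    if ka < kb:
        return -1
    if kb < ka:
        return 1
    return 0


def _default_name(record) -> str:
    return record.query_name


def iter_template_groups(
    stream: Iterable[Any],
    get_name: Callable[[Any], str] = _default_name,
) -> Iterator[TemplateGroup]:
    """Group consecutive same-name records into TemplateGroups.

    Mate suffixes (``/1``, ``/2``) are stripped once before grouping.
    The stripped names must be non-decreasing in natural order; a
    violation raises :class:`~xenosplit.core.SortednessError` naming the
    offending records.
    """
    current: Optional[TemplateGroup] = None
    current_key: Optional[NameKey] = None
    pos = -1
    for pos, record in enumerate(stream):
        name = strip_mate_suffix(get_name(record))
        if current is not None and name == current.template_name:
            current.records.append(record)
            continue
        key = NameKey(name)
        if current_key is not None and key < current_key:
            raise SortednessError(
                f"input is not natural-name-sorted: record {pos} "
                f"({name!r}) precedes record {pos - len(current.records)} "
                f"({current.template_name!r})"
            )
        if current is not None:
            yield current
        current = TemplateGroup(template_name=name, records=[record])
        current_key = key
    if current is not None:
        yield current


def synchronize(
    groups_a: Iterable[TemplateGroup],
    groups_b: Iterable[TemplateGroup],
) -> Iterator[Tuple[Optional[TemplateGroup], Optional[TemplateGroup]]]:
    """Merge-join two name-sorted group streams on template name.

    Yields ``(a, b)`` for names present in both streams, ``(a, None)``
    or ``(None, b)`` for names private to one.  Every input group
    appears in exactly one tuple; memory is bounded by one group per
    stream.
    """
    it_a = iter(groups_a)
    it_b = iter(groups_b)
    a = next(it_a, None)
    b = next(it_b, None)
    while a is not None or b is not None:
        if a is None:
            yield (None, b)
            b = next(it_b, None)
            continue
        if b is None:
            yield (a, None)
            a = next(it_a, None)
            continue
        if a.template_name == b.template_name:
            yield (a, b)
            a = next(it_a, None)
            b = next(it_b, None)
            continue
        # equal keys imply equal names (digit ties include length), so
        # unequal names here always order strictly
        if NameKey(a.template_name) < NameKey(b.template_name):
            yield (a, None)
            a = next(it_a, None)
        else:
            yield (None, b)
            b = next(it_b, None)
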