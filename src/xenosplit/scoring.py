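"""Tag extraction and the per-template decision rules.

Two schemes are supported, matching what common aligners emit:

``AS_NM``
    For BWA-MEM-, STAR- and Bowtie2-style output.  The alignment score
    (AS, higher better) is the primary metric; edit distance (NM, lower
    better) breaks full AS ties.

``SUM_NM_NH_XO``
    For TopHat2-/HISAT2-style output.  The sum NM + NH + XO (edit
    distance + number of reported alignments + gap opens, lower better)
    is the single metric.

Orientation convention
----------------------
All internal comparisons are higher-is-better.  Lower-is-better metrics
are negated at extraction time: the comparator sees -NM and -(NM+NH+XO),
so the original rules' ``min(QS)`` (the best score on the lower-better
scale) corresponds to ``max`` here and vice versa.  One comparator,
fewer sign bugs.

Missing evidence
----------------
Absent evidence must lose every comparison against real evidence and tie
against equally absent evidence (so two templates orphaned in opposite
species can still be resolved on their present mates).  A missing AS tag
resolves to -32768; missing NM, NH or XO to 32768; a mate with no mapped
record gets the worst-case composite of the active metric.
"""

from __future__ import annotations

import enum
from typing import Optional, Tuple

from .core import (
    MISSING,
    AssignmentCategory,
    QualityQuad,
    TagScores,
    TagFormatError,
    TemplateGroup,
)

WORST_AS = -32768
WORST_NM = 32768
WORST_NH = 32768
WORST_XO = 32768

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_READ2 = 0x80


class Scheme(enum.Enum):
    """Which tag set drives the decision for a run (one per run)."""

    AS_NM = "as-nm"
    SUM_NM_NH_XO = "sum-nm-nh-xo"


#: Aligner aliases accepted on the command line.
ALIGNER_SCHEMES = {
    "bwa": Scheme.AS_NM,
    "star": Scheme.AS_NM,
    "bowtie2": Scheme.AS_NM,
    "tophat2": Scheme.SUM_NM_NH_XO,
    "hisat2": Scheme.SUM_NM_NH_XO,
}


def resolve_scheme(value) -> Scheme:
    """Accept a Scheme, a scheme value string, or an aligner alias."""
    if isinstance(value, Scheme):
        return value
    key = str(value).lower()
    if key in ALIGNER_SCHEMES:
        return ALIGNER_SCHEMES[key]
    try:
        return Scheme(key)
    except ValueError:
        raise ValueError(
            f"unknown aligner/scheme {value!r}; expected one of "
            f"{sorted(ALIGNER_SCHEMES)} or "
            f"{[s.value for s in Scheme]}"
        ) from None


class Metric(enum.Enum):
    AS = "AS"
    NEG_NM = "NEG_NM"
    SUM = "SUM"


def mate_index(record) -> int:
    """1 or 2 from the record's flag; single-end records count as mate 1."""
    flag = record.flag
    if flag & _FLAG_PAIRED and flag & _FLAG_READ2:
        return 2
    return 1


def extract_tag_scores(record, scheme: Scheme) -> TagScores:
    """Read AS/NM/NH/XO from a record's optional tags.

    Unmapped records return all-``MISSING`` scores with ``mapped=False``.
    A tag that is present but not an integer raises
    :class:`~xenosplit.core.TagFormatError` naming the tag and record.
    """
    if record.flag & _FLAG_UNMAPPED:
        return TagScores(mapped=False)
    values = {}
    for tag, attr in (("AS", "as_score"), ("NM", "nm"), ("NH", "nh"), ("XO", "xo")):
        if record.has_tag(tag):
            v = record.get_tag(tag)
            if isinstance(v, bool) or not isinstance(v, int):
                raise TagFormatError(
                    f"tag {tag} of record {record.query_name!r} is not an "
                    f"integer: {v!r}"
                )
            values[attr] = int(v)
        else:
            values[attr] = MISSING
    return TagScores(mapped=True, **values)


def score_group(group: TemplateGroup, scheme: Scheme) -> TemplateGroup:
    """Fill ``group.scores`` (one entry per record) if not yet populated."""
    if len(group.scores) != len(group.records):
        group.scores = [
            (mate_index(r), extract_tag_scores(r, scheme)) for r in group.records
        ]
    return group


def _metric_of(ts: TagScores, metric: Metric) -> int:
    """Single-record metric value, higher-is-better, sentinels applied."""
    if metric is Metric.AS:
        return ts.as_score if ts.as_score is not MISSING else WORST_AS
    if metric is Metric.NEG_NM:
        return -(ts.nm if ts.nm is not MISSING else WORST_NM)
    nm = ts.nm if ts.nm is not MISSING else WORST_NM
    nh = ts.nh if ts.nh is not MISSING else WORST_NH
    xo = ts.xo if ts.xo is not MISSING else WORST_XO
    return -(nm + nh + xo)


def worst_value(metric: Metric) -> int:
    """Worst-case composite for a mate with no mapped record."""
    if metric is Metric.AS:
        return WORST_AS
    if metric is Metric.NEG_NM:
        return -WORST_NM
    return -(WORST_NM + WORST_NH + WORST_XO)


def metric_values(
    group: Optional[TemplateGroup], scheme: Scheme, metric: Metric
) -> Tuple[int, int]:
    """Best metric value per mate across all mapped records of a group.

    Secondary and supplementary records participate (multiple alignments
    are allowed); duplicate and QC-fail flags are ignored, the records
    are still scored.  A mate with no mapped record contributes the
    worst-case sentinel.  For single-end groups (no record carries the
    paired flag) the read-2 slot is filled with the read-1 value, which
    reduces the paired rules to a single-value comparison.
    """
    sentinel = worst_value(metric)
    if group is None:
        return (sentinel, sentinel)
    score_group(group, scheme)
    best = {1: None, 2: None}
    any_paired = False
    for record, (mate, ts) in zip(group.records, group.scores):
        if record.flag & _FLAG_PAIRED:
            any_paired = True
        if not ts.mapped:
            continue
        v = _metric_of(ts, metric)
        if best[mate] is None or v > best[mate]:
            best[mate] = v
    r1 = best[1] if best[1] is not None else sentinel
    if not any_paired:
        r2 = r1
    else:
        r2 = best[2] if best[2] is not None else sentinel
    return (r1, r2)


def _compare_pairs(
    pair_a: Tuple[int, int], pair_b: Tuple[int, int]
) -> Optional[AssignmentCategory]:
    """One round of the max/min comparison; None on a full tie."""
    max_a, max_b = max(pair_a), max(pair_b)
    if max_a > max_b:
        return AssignmentCategory.SPECIES_A
    if max_a < max_b:
        return AssignmentCategory.SPECIES_B
    min_a, min_b = min(pair_a), min(pair_b)
    if min_a > min_b:
        return AssignmentCategory.SPECIES_A
    if min_a < min_b:
        return AssignmentCategory.SPECIES_B
    return None


def decide_as_nm(
    as_a: Tuple[int, int],
    as_b: Tuple[int, int],
    negnm_a: Tuple[int, int],
    negnm_b: Tuple[int, int],
) -> AssignmentCategory:
    """AS-primary decision with -NM tie-break.

    Assign A if A's best AS beats B's, or the bests tie and A's worst
    beats B's; mirror for B.  Only when both best and worst AS tie is
    the identical comparison repeated on -NM; a full tie there too is
    ambiguous.
    """
    verdict = _compare_pairs(as_a, as_b)
    if verdict is not None:
        return verdict
    verdict = _compare_pairs(negnm_a, negnm_b)
    if verdict is not None:
        return verdict
    return AssignmentCategory.AMBIGUOUS


def decide_sum(
    sum_a: Tuple[int, int], sum_b: Tuple[int, int]
) -> AssignmentCategory:
    """Decision on the negated NM+NH+XO sums (higher better here).

    On the original lower-is-better scale: ambiguous if best and worst
    sums are identical across species; assign A if A's best sum is
    lower, or the bests tie and A's worst is lower; else B.  Because the
    inputs arrive negated, "lower sum" reads as ``>`` below.
    """
    best_a, best_b = max(sum_a), max(sum_b)
    worst_a, worst_b = min(sum_a), min(sum_b)
    if best_a == best_b and worst_a == worst_b:
        return AssignmentCategory.AMBIGUOUS
    if best_a > best_b or (best_a == best_b and worst_a > worst_b):
        return AssignmentCategory.SPECIES_A
    return AssignmentCategory.SPECIES_B


def has_mapped_record(group: Optional[TemplateGroup], scheme: Scheme) -> bool:
    if group is None:
        return False
    score_group(group, scheme)
    return any(ts.mapped for _, ts in group.scores)


def disambiguate_template(
    group_a: Optional[TemplateGroup],
    group_b: Optional[TemplateGroup],
    scheme: Scheme,
) -> AssignmentCategory:
    """Assign one template given its groups in both species' inputs.

    A template present in only one input (with at least one mapped
    record) goes to that species without competition; a template with no
    mapped record anywhere is unaligned; otherwise the quality quads are
    built and the scheme's rules applied.
    """
    if group_a is None and group_b is None:
        raise RuntimeError("both groups absent: caller bug")
    mapped_a = has_mapped_record(group_a, scheme)
    mapped_b = has_mapped_record(group_b, scheme)
    if not mapped_a and not mapped_b:
        return AssignmentCategory.UNALIGNED
    if group_b is None and mapped_a:
        return AssignmentCategory.SPECIES_A
    if group_a is None and mapped_b:
        return AssignmentCategory.SPECIES_B
    if scheme is Scheme.AS_NM:
        as_a = metric_values(group_a, scheme, Metric.AS)
        as_b = metric_values(group_b, scheme, Metric.AS)
        negnm_a = metric_values(group_a, scheme, Metric.NEG_NM)
        negnm_b = metric_values(group_b, scheme, Metric.NEG_NM)
        return decide_as_nm(as_a, as_b, negnm_a, negnm_b)
    sum_a = metric_values(group_a, scheme, Metric.SUM)
    sum_b = metric_values(group_b, scheme, Metric.SUM)
    return decide_sum(sum_a, sum_b)


def build_quad(
    group_a: Optional[TemplateGroup],
    group_b: Optional[TemplateGroup],
    scheme: Scheme,
    metric: Metric,
) -> QualityQuad:
    """Convenience constructor for the size-4 quality array of a metric."""
    r1a, r2a = metric_values(group_a, scheme, metric)
    r1b, r2b = metric_values(group_b, scheme, metric)
    return QualityQuad(r1a, r2a, r1b, r2b)
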