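"""Synthetic SAM fixture generation with truth labels.

Every other module is testable without downloads: this module writes
pairs of natural-name-sorted SAM files with fully controlled read
names, flags and AS/NM/NH/XO tags, plus a truth table mapping each
template name to its expected assignment category.

The decision logic only ever reads names, flags and optional tags, so
alignment geometry is irrelevant: fixtures use a tiny synthetic
reference (one 1,000-base contig per species) with dummy positions and
CIGAR strings.

Truth labels for randomly generated fixtures come from
:func:`reference_assignment`, a deliberately naive, unoptimized
transcription of the published decision-rule lists that shares no code
with the production path in :mod:`xenosplit.scoring`; the two are held
in agreement by tests.  Only the canonical branch-coverage fixture
carries hand-derived labels (double entry: the hand labels must agree
with the transcription).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pysam

from .core import AssignmentCategory, FixtureSpecError, TemplateGroup
from .pairsync import NameKey
from .scoring import Scheme

_REF_LEN = 1000
_SEQ = "ACGTACGTAC"

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800

# worst-case defaults shared with the scoring module's sentinel design
_WORST_AS = -32768
_WORST_PER_TAG = 32768


@dataclass(frozen=True)
class AlnSpec:
    """One alignment record to synthesize: tags and flag modifiers."""

    tags: Mapping[str, int] = field(default_factory=dict)
    mapped: bool = True
    secondary: bool = False
    supplementary: bool = False


#: Per-species template description: maps mate index (1 or 2) to the
#: records to emit for that mate; a missing key means the mate is absent
#: from that file.  ``None`` at the species level means the whole
#: template is absent from that species' file.
SpeciesSpec = Optional[Dict[int, Sequence[AlnSpec]]]


@dataclass
class TemplateSpec:
    name: str
    species_a: SpeciesSpec
    species_b: SpeciesSpec
    expected: Optional[AssignmentCategory] = None
    note: str = ""
    paired: bool = True


@dataclass
class FixtureSpec:
    templates: List[TemplateSpec]
    scheme: Scheme
    seed: int = 0

    def validate(self) -> None:
        names = [t.name for t in self.templates]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FixtureSpecError(f"duplicate template names: {dupes}")
        for t in self.templates:
            if t.species_a is None and t.species_b is None:
                raise FixtureSpecError(
                    f"template {t.name!r} absent from both species"
                )


def _fixture_header(species: str) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": f"chr_{species}", "LN": _REF_LEN}],
        }
    )


def _make_record(
    name: str,
    mate: int,
    aln: AlnSpec,
    paired: bool,
    header: Optional[pysam.AlignmentHeader],
) -> pysam.AlignedSegment:
    rec = (
        pysam.AlignedSegment(header)
        if header is not None
        else pysam.AlignedSegment()
    )
    rec.query_name = name
    flag = 0
    if paired:
        flag |= _FLAG_PAIRED
        flag |= _FLAG_READ2 if mate == 2 else _FLAG_READ1
    if not aln.mapped:
        flag |= _FLAG_UNMAPPED
    if aln.secondary:
        flag |= _FLAG_SECONDARY
    if aln.supplementary:
        flag |= _FLAG_SUPPLEMENTARY
    rec.flag = flag
    rec.query_sequence = _SEQ
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(_SEQ))
    if aln.mapped and header is not None:
        rec.reference_id = 0
        rec.reference_start = 100
        rec.mapping_quality = 60
        rec.cigarstring = f"{len(_SEQ)}M"
    else:
        rec.reference_id = -1
        rec.reference_start = -1
    for tag, value in aln.tags.items():
        rec.set_tag(tag, int(value), value_type="i")
    return rec


def _species_records(
    tspec: TemplateSpec,
    species_spec: SpeciesSpec,
    header: Optional[pysam.AlignmentHeader],
) -> Optional[List[pysam.AlignedSegment]]:
    if species_spec is None:
        return None
    records = []
    for mate in sorted(species_spec):
        if mate not in (1, 2):
            raise FixtureSpecError(
                f"template {tspec.name!r}: mate index must be 1 or 2"
            )
        for aln in species_spec[mate]:
            records.append(_make_record(tspec.name, mate, aln, tspec.paired, header))
    if not records:
        return None
    return records


def materialize_groups(
    tspec: TemplateSpec,
) -> Tuple[Optional[TemplateGroup], Optional[TemplateGroup]]:
    """In-memory TemplateGroup pair for one template spec (no files)."""
    recs_a = _species_records(tspec, tspec.species_a, None)
    recs_b = _species_records(tspec, tspec.species_b, None)
    ga = TemplateGroup(tspec.name, recs_a) if recs_a else None
    gb = TemplateGroup(tspec.name, recs_b) if recs_b else None
    return ga, gb


def build_fixture(
    spec: FixtureSpec, out_dir
) -> Tuple[Path, Path, Dict[str, AssignmentCategory]]:
    """Write the two SAM files and the truth table for a fixture spec.

    Templates are emitted in natural name order so the outputs always
    pass the pipeline's sortedness check.  Returns the two SAM paths
    and the truth mapping; the truth is also written as a TSV next to
    the SAM files.  Templates without a hand-set expected category get
    their label from :func:`reference_assignment`.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path_a = out_dir / "speciesA.sam"
    path_b = out_dir / "speciesB.sam"
    truth_path = out_dir / "truth.tsv"

    ordered = sorted(spec.templates, key=lambda t: NameKey(t.name))
    header_a = _fixture_header("A")
    header_b = _fixture_header("B")
    truth: Dict[str, AssignmentCategory] = {}
    with pysam.AlignmentFile(str(path_a), "w", header=header_a) as out_a, \
            pysam.AlignmentFile(str(path_b), "w", header=header_b) as out_b:
        for tspec in ordered:
            for rec in _species_records(tspec, tspec.species_a, header_a) or []:
                out_a.write(rec)
            for rec in _species_records(tspec, tspec.species_b, header_b) or []:
                out_b.write(rec)
            if tspec.expected is not None:
                truth[tspec.name] = tspec.expected
            else:
                ga, gb = materialize_groups(tspec)
                truth[tspec.name] = reference_assignment(ga, gb, spec.scheme)
    with open(truth_path, "w") as fh:
        fh.write("template_name\texpected_category\n")
        for name in sorted(truth, key=NameKey):
            fh.write(f"{name}\t{truth[name].value}\n")
    return path_a, path_b, truth


# ---------------------------------------------------------------------------
# Independent rule transcription (truth-label oracle)
# ---------------------------------------------------------------------------

def reference_assignment(
    group_a: Optional[TemplateGroup],
    group_b: Optional[TemplateGroup],
    scheme: Scheme,
) -> AssignmentCategory:
    """Naive, literal transcription of the published decision rules.

    Works directly on raw flags and tags, building the size-4 quality
    array on the rules' own orientation (AS higher-better; the NM+NH+XO
    sum lower-better).  Shares no code with the production scoring path
    and stays unoptimized on purpose: it is the independent oracle the
    production implementation is tested against.
    """

    def mate_of(rec) -> int:
        if rec.flag & _FLAG_PAIRED and rec.flag & _FLAG_READ2:
            return 2
        return 1

    def mapped_recs(group, mate):
        if group is None:
            return []
        return [
            r
            for r in group.records
            if not (r.flag & _FLAG_UNMAPPED) and mate_of(r) == mate
        ]

    def tag_or(rec, tag, default):
        return int(rec.get_tag(tag)) if rec.has_tag(tag) else default

    def single_end(group) -> bool:
        return group is not None and not any(
            r.flag & _FLAG_PAIRED for r in group.records
        )

    any_a = bool(mapped_recs(group_a, 1) or mapped_recs(group_a, 2))
    any_b = bool(mapped_recs(group_b, 1) or mapped_recs(group_b, 2))
    if not any_a and not any_b:
        return AssignmentCategory.UNALIGNED
    if group_b is None and any_a:
        return AssignmentCategory.SPECIES_A
    if group_a is None and any_b:
        return AssignmentCategory.SPECIES_B

    def qs_pair(group, per_record, absent):
        """(read1, read2) best values; single-end copies read 1."""
        best = []
        for mate in (1, 2):
            values = [per_record(r) for r in mapped_recs(group, mate)]
            best.append(values)
        r1 = max(best[0]) if best[0] else absent
        if single_end(group):
            return [r1, r1]
        r2 = max(best[1]) if best[1] else absent
        return [r1, r2]

    if scheme is Scheme.AS_NM:
        # QS = [r1 sp1, r2 sp1, r1 sp2, r2 sp2], AS higher better
        qs_as = qs_pair(group_a, lambda r: tag_or(r, "AS", _WORST_AS), _WORST_AS) + \
            qs_pair(group_b, lambda r: tag_or(r, "AS", _WORST_AS), _WORST_AS)
        qs_negnm = qs_pair(
            group_a, lambda r: -tag_or(r, "NM", _WORST_PER_TAG), -_WORST_PER_TAG
        ) + qs_pair(
            group_b, lambda r: -tag_or(r, "NM", _WORST_PER_TAG), -_WORST_PER_TAG
        )

        def rules_1_2(qs):
            s1, s2 = qs[0:2], qs[2:4]
            if max(s1) > max(s2) or (max(s1) == max(s2) and min(s1) > min(s2)):
                return AssignmentCategory.SPECIES_A
            if max(s1) < max(s2) or (max(s1) == max(s2) and min(s1) < min(s2)):
                return AssignmentCategory.SPECIES_B
            return None

        # rule 3: if AS did not resolve, repeat for -NM; rule 4: ambiguous
        verdict = rules_1_2(qs_as)
        if verdict is None:
            verdict = rules_1_2(qs_negnm)
        return verdict if verdict is not None else AssignmentCategory.AMBIGUOUS

    # sum scheme: QS = NM + NH + XO, lower better, absence is worst-case
    worst_sum = 3 * _WORST_PER_TAG

    def record_sum(r):
        return (
            tag_or(r, "NM", _WORST_PER_TAG)
            + tag_or(r, "NH", _WORST_PER_TAG)
            + tag_or(r, "XO", _WORST_PER_TAG)
        )

    def qs_pair_low(group):
        best = []
        for mate in (1, 2):
            values = [record_sum(r) for r in mapped_recs(group, mate)]
            best.append(values)
        r1 = min(best[0]) if best[0] else worst_sum
        if single_end(group):
            return [r1, r1]
        r2 = min(best[1]) if best[1] else worst_sum
        return [r1, r2]

    qs = qs_pair_low(group_a) + qs_pair_low(group_b)
    s1, s2 = qs[0:2], qs[2:4]
    # rule 1: identical best (and worst) scores for both species
    if min(s1) == min(s2) and max(s1) == max(s2):
        return AssignmentCategory.AMBIGUOUS
    # rule 2: species 1 on strictly better best, or tied best and better worst
    if min(s1) < min(s2) or (min(s1) == min(s2) and max(s1) < max(s2)):
        return AssignmentCategory.SPECIES_A
    # rule 3
    return AssignmentCategory.SPECIES_B


# ---------------------------------------------------------------------------
# Canonical branch-coverage fixture
# ---------------------------------------------------------------------------

def _pair(tags1: Mapping[str, int], tags2: Mapping[str, int]) -> Dict[int, Sequence[AlnSpec]]:
    return {1: [AlnSpec(tags1)], 2: [AlnSpec(tags2)]}


def canonical_fixture(scheme: Scheme) -> FixtureSpec:
    """Twelve hand-labelled templates covering every decision branch."""
    A = AssignmentCategory.SPECIES_A
    B = AssignmentCategory.SPECIES_B
    AMB = AssignmentCategory.AMBIGUOUS
    UNA = AssignmentCategory.UNALIGNED
    unmapped_pair = {1: [AlnSpec(mapped=False)], 2: [AlnSpec(mapped=False)]}

    if scheme is Scheme.AS_NM:
        t = [
            TemplateSpec(
                "t01", _pair({"AS": 50, "NM": 0}, {"AS": 50, "NM": 0}),
                _pair({"AS": 40, "NM": 0}, {"AS": 40, "NM": 0}),
                A, "best AS strictly higher for A",
            ),
            TemplateSpec(
                "t02", _pair({"AS": 40, "NM": 0}, {"AS": 40, "NM": 0}),
                _pair({"AS": 50, "NM": 0}, {"AS": 50, "NM": 0}),
                B, "best AS strictly higher for B",
            ),
            TemplateSpec(
                "t03", _pair({"AS": 50, "NM": 0}, {"AS": 40, "NM": 0}),
                _pair({"AS": 50, "NM": 0}, {"AS": 30, "NM": 0}),
                A, "best AS tied at 50; worst 40 > 30 favors A",
            ),
            TemplateSpec(
                "t04", _pair({"AS": 50, "NM": 0}, {"AS": 30, "NM": 0}),
                _pair({"AS": 50, "NM": 0}, {"AS": 40, "NM": 0}),
                B, "best AS tied; worst mate favors B",
            ),
            TemplateSpec(
                "t05", _pair({"AS": 50, "NM": 1}, {"AS": 50, "NM": 1}),
                _pair({"AS": 50, "NM": 2}, {"AS": 50, "NM": 2}),
                A, "AS fully tied; -NM (-1 > -2) favors A",
            ),
            TemplateSpec(
                "t06", _pair({"AS": 50, "NM": 2}, {"AS": 50, "NM": 2}),
                _pair({"AS": 50, "NM": 1}, {"AS": 50, "NM": 1}),
                B, "AS fully tied; -NM favors B",
            ),
            TemplateSpec(
                "t07", _pair({"AS": 50, "NM": 1}, {"AS": 50, "NM": 1}),
                _pair({"AS": 50, "NM": 1}, {"AS": 50, "NM": 1}),
                AMB, "AS and NM identical everywhere",
            ),
            TemplateSpec(
                "t08", _pair({"AS": 50, "NM": 0}, {"AS": 50, "NM": 0}),
                None, A, "template present only in A",
            ),
            TemplateSpec(
                "t09", None,
                _pair({"AS": 50, "NM": 0}, {"AS": 50, "NM": 0}),
                B, "template present only in B",
            ),
            TemplateSpec(
                "t10", unmapped_pair, unmapped_pair,
                UNA, "present in both files, mapped in neither",
            ),
            TemplateSpec(
                "t11",
                {
                    1: [
                        AlnSpec({"AS": 30, "NM": 0}),
                        AlnSpec({"AS": 55, "NM": 0}, secondary=True),
                    ],
                    2: [AlnSpec({"AS": 50, "NM": 0})],
                },
                _pair({"AS": 50, "NM": 0}, {"AS": 50, "NM": 0}),
                A, "secondary alignment carries A's best AS (55)",
            ),
            TemplateSpec(
                "t12",
                {1: [AlnSpec({"AS": 50, "NM": 0})], 2: [AlnSpec(mapped=False)]},
                _pair({"AS": 50, "NM": 0}, {"AS": 50, "NM": 0}),
                B, "A's mate 2 unmapped: best AS ties, worst favors B",
            ),
        ]
        return FixtureSpec(templates=t, scheme=scheme)

    def sum_tags(nm: int) -> Dict[str, int]:
        return {"NM": nm, "NH": 1, "XO": 0}  # sum = NM + 1

    t = [
        TemplateSpec(
            "t01", _pair(sum_tags(1), sum_tags(2)),
            _pair(sum_tags(4), sum_tags(5)),
            A, "best sum 2 < 5 favors A",
        ),
        TemplateSpec(
            "t02", _pair(sum_tags(4), sum_tags(5)),
            _pair(sum_tags(1), sum_tags(2)),
            B, "best sum favors B",
        ),
        TemplateSpec(
            "t03", _pair(sum_tags(1), sum_tags(2)),
            _pair(sum_tags(1), sum_tags(3)),
            A, "best sums tie at 2; worst 3 < 4 favors A",
        ),
        TemplateSpec(
            "t04", _pair(sum_tags(1), sum_tags(3)),
            _pair(sum_tags(1), sum_tags(2)),
            B, "best sums tie; worst favors B",
        ),
        TemplateSpec(
            "t05", _pair(sum_tags(1), sum_tags(2)),
            _pair(sum_tags(1), sum_tags(2)),
            AMB, "identical best and worst sums",
        ),
        TemplateSpec(
            "t06", _pair(sum_tags(1), sum_tags(1)), None,
            A, "template present only in A",
        ),
        TemplateSpec(
            "t07", None, _pair(sum_tags(1), sum_tags(1)),
            B, "template present only in B",
        ),
        TemplateSpec(
            "t08", unmapped_pair, unmapped_pair,
            UNA, "mapped in neither file",
        ),
        TemplateSpec(
            "t09",
            {
                1: [
                    AlnSpec(sum_tags(5)),
                    AlnSpec(sum_tags(1), secondary=True),
                ],
                2: [AlnSpec(sum_tags(3))],
            },
            _pair(sum_tags(2), sum_tags(2)),
            A, "secondary alignment carries A's best sum (2 < 3)",
        ),
        TemplateSpec(
            "t10",
            {1: [AlnSpec(sum_tags(2))], 2: [AlnSpec(mapped=False)]},
            _pair(sum_tags(2), sum_tags(3)),
            B, "A's mate 2 unmapped: best sums tie, worst favors B",
        ),
        TemplateSpec(
            "t11", _pair({}, {}),
            _pair(sum_tags(1), sum_tags(2)),
            B, "A mapped but has no usable tags; worst-case sums lose",
        ),
        TemplateSpec(
            "t12",
            {1: [AlnSpec(sum_tags(1))]},
            {1: [AlnSpec(sum_tags(2))]},
            A, "single-end template; lower sum favors A",
            paired=False,
        ),
    ]
    return FixtureSpec(templates=t, scheme=scheme)


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------

_TAG_RANGES = {"AS": (0, 60), "NM": (0, 10), "NH": (1, 5), "XO": (0, 3)}
_P_SPECIES_ABSENT = 0.1
_P_MATE_ABSENT = 0.1
_P_MATE_UNMAPPED = 0.1
_P_TAG_MISSING = 0.05
_P_SINGLE_END = 0.05
_P_EXTRA_RECORD = 0.3


def _random_aln(rng: random.Random, secondary: bool = False) -> AlnSpec:
    tags = {}
    for tag, (lo, hi) in _TAG_RANGES.items():
        if rng.random() >= _P_TAG_MISSING:
            tags[tag] = rng.randint(lo, hi)
    return AlnSpec(tags, secondary=secondary)


def _random_species(rng: random.Random, single_end: bool) -> SpeciesSpec:
    if rng.random() < _P_SPECIES_ABSENT:
        return None
    mates = (1,) if single_end else (1, 2)
    spec: Dict[int, Sequence[AlnSpec]] = {}
    for mate in mates:
        r = rng.random()
        if r < _P_MATE_ABSENT:
            continue
        if r < _P_MATE_ABSENT + _P_MATE_UNMAPPED:
            spec[mate] = [AlnSpec(mapped=False)]
            continue
        records = [_random_aln(rng)]
        if rng.random() < _P_EXTRA_RECORD:
            records.append(_random_aln(rng, secondary=True))
        spec[mate] = records
    if not spec:
        return None
    return spec


def _random_template(name: str, rng: random.Random) -> TemplateSpec:
    single_end = rng.random() < _P_SINGLE_END
    species_a = _random_species(rng, single_end)
    species_b = _random_species(rng, single_end)
    if species_a is None and species_b is None:
        if single_end:
            species_a = {1: [_random_aln(rng)]}
        else:
            species_a = {1: [_random_aln(rng)], 2: [_random_aln(rng)]}
    return TemplateSpec(
        name, species_a, species_b, paired=not single_end,
        note="randomly generated",
    )


def random_quads(
    n: int, seed: int, scheme: Scheme
) -> List[Tuple[Optional[TemplateGroup], Optional[TemplateGroup], AssignmentCategory]]:
    """n reproducible random template-group pairs with oracle labels.

    Tags are drawn from small integer ranges (AS in [0, 60], NM in
    [0, 10], NH in [1, 5], XO in [0, 3]); mates and whole groups are
    randomly absent or unmapped.  The label is computed by
    :func:`reference_assignment`, never by the production path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out = []
    for i in range(n):
        tspec = _random_template(f"q{i}", rng)
        ga, gb = materialize_groups(tspec)
        out.append((ga, gb, reference_assignment(ga, gb, scheme)))
    return out


def random_fixture(
    n: int, seed: int, scheme: Scheme, out_dir
) -> Tuple[Path, Path, Dict[str, AssignmentCategory]]:
    """Write a random n-template fixture pair with oracle truth labels."""
    rng = random.Random(seed)
    templates = [_random_template(f"q{i}", rng) for i in range(n)]
    spec = FixtureSpec(templates=templates, scheme=scheme, seed=seed)
    return build_fixture(spec, out_dir)
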