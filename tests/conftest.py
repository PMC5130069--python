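import pysam
import pytest
from hypothesis import settings

from xenosplit.core import AssignmentCategory, TemplateGroup
from xenosplit.synthfix import AlnSpec, _make_record

settings.register_profile("default", derandomize=True, max_examples=200)
settings.load_profile("default")


def make_record(name="r1", mate=1, paired=True, mapped=True, secondary=False, **tags):
    """In-memory alignment record with the given flags and tags."""
    return _make_record(
        name, mate, AlnSpec(tags, mapped=mapped, secondary=secondary), paired, None
    )


def make_group(name, *records):
    return TemplateGroup(name, list(records))


def pair_group(name, tags1, tags2, paired=True):
    """Group with one mapped record per mate carrying the given tags."""
    return make_group(
        name,
        make_record(name, mate=1, paired=paired, **tags1),
        make_record(name, mate=2, paired=paired, **tags2),
    )


def read_assignments(out_dir, sample_id, truth_names):
    """Reconstruct per-template categories from a run's output BAMs."""
    found = {}
    for suffix, category in (
        (".speciesA.bam", AssignmentCategory.SPECIES_A),
        (".speciesB.bam", AssignmentCategory.SPECIES_B),
        (".ambiguousSpeciesA.bam", AssignmentCategory.AMBIGUOUS),
        (".ambiguousSpeciesB.bam", AssignmentCategory.AMBIGUOUS),
    ):
        path = out_dir / f"{sample_id}{suffix}"
        with pysam.AlignmentFile(str(path), "rb") as af:
            for rec in af.fetch(until_eof=True):
                prev = found.get(rec.query_name)
                assert prev is None or prev is category, (
                    f"{rec.query_name} in conflicting outputs: {prev}, {category}"
                )
                found[rec.query_name] = category
    return {
        name: found.get(name, AssignmentCategory.UNALIGNED) for name in truth_names
    }


def record_ids(path):
    """Multiset of (name, flag) identities of a BAM/SAM file's records."""
    out = []
    with pysam.AlignmentFile(str(path)) as af:
        for rec in af.fetch(until_eof=True):
            out.append((rec.query_name, rec.flag))
    return out


@pytest.fixture
def tmp_out(tmp_path):
    d = tmp_path / "out"
    d.mkdir()
    return d
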