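import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_group, make_record, pair_group
from xenosplit.core import MISSING, AssignmentCategory, TagFormatError
from xenosplit.scoring import (
    Metric,
    Scheme,
    decide_as_nm,
    decide_sum,
    disambiguate_template,
    extract_tag_scores,
    metric_values,
    resolve_scheme,
    worst_value,
)

A = AssignmentCategory.SPECIES_A
B = AssignmentCategory.SPECIES_B
AMB = AssignmentCategory.AMBIGUOUS
UNA = AssignmentCategory.UNALIGNED


@pytest.mark.parametrize(
    "alias,scheme",
    [
        ("bwa", Scheme.AS_NM),
        ("STAR", Scheme.AS_NM),
        ("bowtie2", Scheme.AS_NM),
        ("tophat2", Scheme.SUM_NM_NH_XO),
        ("hisat2", Scheme.SUM_NM_NH_XO),
        ("as-nm", Scheme.AS_NM),
        ("sum-nm-nh-xo", Scheme.SUM_NM_NH_XO),
        (Scheme.AS_NM, Scheme.AS_NM),
    ],
)
def test_resolve_scheme_aliases(alias, scheme):
    assert resolve_scheme(alias) is scheme


def test_resolve_scheme_rejects_unknown_alias():
    with pytest.raises(ValueError, match="unknown aligner"):
        resolve_scheme("novoalign")


class TestExtractTagScores:
    def test_reads_present_tags_and_leaves_others_missing(self):
        rec = make_record("r", AS=50, NM=2)
        ts = extract_tag_scores(rec, Scheme.AS_NM)
        assert (ts.as_score, ts.nm, ts.nh, ts.xo) == (50, 2, MISSING, MISSING)
        assert ts.mapped

    def test_unmapped_record_is_all_missing(self):
        ts = extract_tag_scores(make_record("r", mapped=False), Scheme.AS_NM)
        assert not ts.mapped
        assert all(v is MISSING for v in (ts.as_score, ts.nm, ts.nh, ts.xo))

    def test_non_integer_tag_is_a_format_error_naming_the_tag(self):
        rec = make_record("oddball")
        rec.set_tag("AS", 1.5, value_type="f")
        with pytest.raises(TagFormatError, match="AS.*oddball"):
            extract_tag_scores(rec, Scheme.AS_NM)

    def test_sum_scheme_tags_feed_the_sum(self):
        rec = make_record("r", paired=False, NM=2, NH=1, XO=0)
        g = make_group("r", rec)
        assert metric_values(g, Scheme.SUM_NM_NH_XO, Metric.SUM) == (-3, -3)


class TestMetricValues:
    def test_best_over_multiple_records_per_mate(self):
        g = make_group(
            "r",
            make_record("r", mate=1, AS=47),
            make_record("r", mate=1, secondary=True, AS=50),
            make_record("r", mate=2, AS=40),
        )
        assert metric_values(g, Scheme.AS_NM, Metric.AS) == (50, 40)

    def test_paired_mate_without_record_gets_sentinel(self):
        g = make_group("r", make_record("r", mate=1, AS=50))
        r1, r2 = metric_values(g, Scheme.AS_NM, Metric.AS)
        assert (r1, r2) == (50, worst_value(Metric.AS))

    def test_single_end_copies_read1_into_read2_slot(self):
        g = make_group("r", make_record("r", mate=1, paired=False, AS=50))
        assert metric_values(g, Scheme.AS_NM, Metric.AS) == (50, 50)

    def test_sum_metric_best_is_lowest_sum_negated(self):
        g = make_group(
            "r",
            make_record("r", mate=1, NM=2, NH=1, XO=0),
            make_record("r", mate=1, secondary=True, NM=5, NH=1, XO=1),
        )
        r1, _ = metric_values(g, Scheme.SUM_NM_NH_XO, Metric.SUM)
        assert r1 == -3

    def test_absent_group_is_all_sentinel(self):
        s = worst_value(Metric.NEG_NM)
        assert metric_values(None, Scheme.AS_NM, Metric.NEG_NM) == (s, s)

    def test_unmapped_records_do_not_contribute(self):
        g = make_group(
            "r",
            make_record("r", mate=1, AS=50),
            make_record("r", mate=2, mapped=False),
        )
        assert metric_values(g, Scheme.AS_NM, Metric.AS) == (
            50,
            worst_value(Metric.AS),
        )


@pytest.mark.parametrize(
    "as_a,as_b,negnm_a,negnm_b,expected",
    [
        # strict max dominance
        ((50, 50), (40, 40), (0, 0), (0, 0), A),
        # maxima tie at 50, min 40 > 30 favors B
        ((50, 30), (50, 40), (0, 0), (0, 0), B),
        # AS fully tied; -NM max -1 > -2 favors A
        ((50, 50), (50, 50), (-1, -1), (-2, -2), A),
        # everything identical
        ((50, 50), (50, 50), (-1, -1), (-1, -1), AMB),
        # -NM consulted only on full AS tie: AS min already resolves
        ((50, 30), (50, 40), (0, 0), (-5, -5), B),
    ],
)
def test_decide_as_nm(as_a, as_b, negnm_a, negnm_b, expected):
    assert decide_as_nm(as_a, as_b, negnm_a, negnm_b) is expected


@pytest.mark.parametrize(
    "sum_a,sum_b,expected",
    [
        # raw sums A=(2,3), B=(5,6): best 2 < 5
        ((-2, -3), (-5, -6), A),
        # raw sums A=(2,4), B=(2,3): best tie, worst 3 < 4
        ((-2, -4), (-2, -3), B),
        # identical best and worst
        ((-2, -3), (-2, -3), AMB),
    ],
)
def test_decide_sum_on_negated_orientation(sum_a, sum_b, expected):
    assert decide_sum(sum_a, sum_b) is expected


class TestDisambiguateTemplate:
    def test_single_present_mapped_group_wins_outright(self):
        g = pair_group("r", {"AS": 50}, {"AS": 50})
        assert disambiguate_template(g, None, Scheme.AS_NM) is A
        assert disambiguate_template(None, g, Scheme.AS_NM) is B

    def test_nothing_mapped_anywhere_is_unaligned(self):
        ga = make_group("r", make_record("r", mate=1, mapped=False))
        gb = make_group("r", make_record("r", mate=1, mapped=False))
        assert disambiguate_template(ga, gb, Scheme.AS_NM) is UNA
        assert disambiguate_template(ga, None, Scheme.AS_NM) is UNA

    def test_as_tie_broken_by_edit_distance(self):
        ga = pair_group("r", {"AS": 50, "NM": 1}, {"AS": 50, "NM": 1})
        gb = pair_group("r", {"AS": 50, "NM": 0}, {"AS": 50, "NM": 0})
        assert disambiguate_template(ga, gb, Scheme.AS_NM) is B

    def test_both_absent_is_a_caller_bug(self):
        with pytest.raises(RuntimeError):
            disambiguate_template(None, None, Scheme.AS_NM)

    def test_identical_groups_tie(self):
        ga = pair_group("r", {"AS": 50, "NM": 1}, {"AS": 40, "NM": 2})
        gb = pair_group("r", {"AS": 50, "NM": 1}, {"AS": 40, "NM": 2})
        assert disambiguate_template(ga, gb, Scheme.AS_NM) is AMB
        assert disambiguate_template(ga, gb, Scheme.SUM_NM_NH_XO) is AMB


pair_strategy = st.tuples(st.integers(-5, 5), st.integers(-5, 5))


@given(pair_strategy, pair_strategy, pair_strategy, pair_strategy)
def test_decide_as_nm_species_symmetry(as_a, as_b, negnm_a, negnm_b):
    forward = decide_as_nm(as_a, as_b, negnm_a, negnm_b)
    backward = decide_as_nm(as_b, as_a, negnm_b, negnm_a)
    assert backward is forward.mirrored()


@given(pair_strategy, pair_strategy)
def test_decide_sum_species_symmetry(sum_a, sum_b):
    assert decide_sum(sum_b, sum_a) is decide_sum(sum_a, sum_b).mirrored()


@given(pair_strategy, pair_strategy)
def test_decide_sum_self_tie_is_ambiguous(sum_a, sum_b):
    assert decide_sum(sum_a, sum_a) is AMB
    assert decide_sum(sum_b, sum_b) is AMB
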