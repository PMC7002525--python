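"""Hard/optional variant filters and background copy-number assignment."""
import random

import pytest

from svccf import (Breakend, Breakpoint, CNAnnotation, CNState, Direction,
                   FilterParams, SampleMeta, SVClass, apply_filters,
                   assign_background_cn)
from svccf.count import ReadCounts
from svccf.io_formats import CNMap


def bp(id_, p1=10_000, p2=50_000, d1="+", d2="-", c1="1", c2="1",
       cls=SVClass.DEL):
    return Breakpoint(id_, Breakend(c1, p1, Direction(d1)),
                      Breakend(c2, p2, Direction(d2)), cls)


def counts(s1=3, s2=3, c=2, o1=40, o2=38, high=False):
    return ReadCounts(split_lo=s1, split_hi=s2, spanning=c, norm_lo=o1,
                      norm_hi=o2, high_depth_flag=high)


@pytest.fixture
def meta():
    return SampleMeta(purity=0.75, insert_mean=300.0)


def cn_map_from(segments):
    cn = CNMap()
    for chrom, start, end, states in segments:
        cn.add(chrom, start, end, CNAnnotation(tuple(states)))
    return cn


class TestApplyFilters:
    def test_minimal_support_kept(self, meta):
        # one split + one spanning read with healthy depth passes
        kept, rejected = apply_filters([(bp("a"), counts(s1=1, s2=0, c=1))],
                                       meta)
        assert len(kept) == 1 and not rejected

    def test_no_split_rejected(self, meta):
        kept, rej = apply_filters([(bp("a"), counts(s1=0, s2=0))], meta)
        assert rej == [(bp("a"), "min_support")]

    def test_no_spanning_rejected(self, meta):
        _, rej = apply_filters([(bp("a"), counts(c=0))], meta)
        assert rej[0][1] == "min_support"

    def test_size_filter_uses_fragment_size(self, meta):
        # u - l = 200 <= 300 (insert mean) rejected; inter-chromosomal exempt
        _, rej = apply_filters([(bp("a", 10_000, 10_200), counts())], meta)
        assert rej[0][1] == "size"
        kept, _ = apply_filters(
            [(bp("a", 10_000, 10_200, c2="2", cls=SVClass.INTRX), counts())],
            meta)
        assert len(kept) == 1

    def test_min_depth_strictly_greater(self, meta):
        shallow = counts(s1=1, s2=0, c=1, o1=0, o2=0)  # depth 2 at each end
        _, rej = apply_filters([(bp("a"), shallow)], meta)
        assert rej[0][1] == "min_depth"

    def test_germline_supported_rejected(self, meta):
        germ_bp = bp("g", 10_003, 50_004)  # both ends within 6 bp, same dirs
        germ = [(germ_bp, counts(s1=2, s2=0, c=0))]
        _, rej = apply_filters([(bp("a"), counts())], meta, germline=germ)
        assert rej[0][1] == "germline"

    def test_germline_outside_window_kept(self, meta):
        germ = [(bp("g", 10_010, 50_000), counts())]
        kept, _ = apply_filters([(bp("a"), counts())], meta, germline=germ)
        assert len(kept) == 1

    def test_invalid_cn_at_both_ends_rejected(self, meta):
        cn = cn_map_from([("1", 1, 100_000, [CNState(0, 0, 1.0)])])
        _, rej = apply_filters([(bp("a"), counts())], meta, cn_map=cn)
        assert rej[0][1] == "invalid_cn"

    def test_one_valid_end_kept_with_default_fallback(self, meta):
        cn = cn_map_from([("1", 1, 20_000, [CNState(2, 1, 1.0)]),
                          ("1", 20_000, 100_000, [CNState(0, 0, 1.0)])])
        kept, _ = apply_filters([(bp("a"), counts())], meta, cn_map=cn)
        assert len(kept) == 1
        _, _, ann_lo, ann_hi = kept[0]
        assert ann_lo.states[0].major == 2
        assert ann_hi.total_tumour == 2  # invalid end fell back to default

    def test_neutral_only_option(self, meta):
        cn = cn_map_from([("1", 1, 100_000, [CNState(2, 1, 1.0)])])
        _, rej = apply_filters([(bp("a"), counts())], meta, cn_map=cn,
                               params=FilterParams(neutral_only=True))
        assert rej[0][1] == "non_neutral_cn"

    def test_exclude_subclonal_option(self, meta):
        cn = cn_map_from([("1", 1, 100_000,
                           [CNState(2, 1, 0.6), CNState(1, 1, 0.4)])])
        _, rej = apply_filters([(bp("a"), counts())], meta, cn_map=cn,
                               params=FilterParams(exclude_subclonal_cn=True))
        assert rej[0][1] == "subclonal_cn"

    def test_blacklist_overlap(self, meta):
        params = FilterParams(blacklist=(("1", 9_000, 11_000),))
        _, rej = apply_filters([(bp("a"), counts())], meta, params=params)
        assert rej[0][1] == "blacklist"

    def test_high_depth_flag_rejected(self, meta):
        _, rej = apply_filters([(bp("a"), counts(high=True))], meta)
        assert rej[0][1] == "high_depth"

    def test_partition_and_order_independence(self, meta):
        svs = [(bp(f"s{i}", 10_000 + 1000 * i, 50_000 + 1000 * i),
                counts(s1=i % 3, s2=1, c=i % 2, o1=30 + i, o2=30))
               for i in range(12)]
        kept1, rej1 = apply_filters(list(svs), meta)
        assert len(kept1) + len(rej1) == len(svs)
        shuffled = list(svs)
        random.Random(0).shuffle(shuffled)
        kept2, _ = apply_filters(shuffled, meta)
        assert {k[0].id for k in kept1} == {k[0].id for k in kept2}


class TestAssignBackgroundCN:
    def test_intrachromosomal_flanks(self):
        # DEL at (10k, 50k): both ends annotated from the flanking (2,1)
        # segments, never from the deleted interval
        cn = cn_map_from([("1", 1, 10_000, [CNState(2, 1, 1.0)]),
                          ("1", 10_000, 50_000, [CNState(1, 0, 1.0)]),
                          ("1", 50_000, 900_000, [CNState(2, 1, 1.0)])])
        ann_lo, ann_hi, f1, f2 = assign_background_cn(bp("a"), cn)
        assert f1 and f2
        assert ann_lo.states[0] == CNState(2, 1, 1.0)
        assert ann_hi.states[0] == CNState(2, 1, 1.0)

    def test_never_uses_inner_segment(self):
        # adversarial: the inner segment differs wildly from the flanks
        cn = cn_map_from([("1", 1, 10_000, [CNState(3, 2, 1.0)]),
                          ("1", 10_000, 50_001, [CNState(8, 8, 1.0)]),
                          ("1", 50_001, 900_000, [CNState(1, 1, 1.0)])])
        ann_lo, ann_hi, _, _ = assign_background_cn(bp("a"), cn)
        assert ann_lo.states[0].major == 3
        assert ann_hi.states[0].major == 1

    def test_interchromosomal_opposite_direction(self):
        cn = cn_map_from([("1", 1, 10_000, [CNState(4, 1, 1.0)]),
                          ("1", 10_000, 900_000, [CNState(1, 1, 1.0)]),
                          ("2", 1, 50_001, [CNState(1, 1, 1.0)]),
                          ("2", 50_001, 900_000, [CNState(5, 1, 1.0)])])
        # '+' at 1:10_000 -> background upstream; '-' at 2:50_000 ->
        # background downstream
        sv = bp("a", 10_000, 50_000, "+", "-", c1="1", c2="2",
                cls=SVClass.INTRX)
        ann_lo, ann_hi, _, _ = assign_background_cn(sv, cn)
        assert ann_lo.states[0].major == 4
        assert ann_hi.states[0].major == 5

    def test_subclonal_weighted_total(self):
        cn = cn_map_from([("1", 1, 900_000,
                           [CNState(2, 1, 0.6), CNState(1, 1, 0.4)])])
        ann_lo, _, _, _ = assign_background_cn(bp("a"), cn)
        assert ann_lo.total_tumour == pytest.approx(2.6)

    def test_no_cn_input_defaults_to_normal(self):
        ann_lo, ann_hi, f1, f2 = assign_background_cn(bp("a"), None)
        assert not f1 and not f2
        assert ann_lo.total_tumour == ann_lo.total_normal == 2

    def test_position_outside_segments_defaults(self):
        cn = cn_map_from([("1", 100_000, 900_000, [CNState(2, 1, 1.0)])])
        ann_lo, _, found, _ = assign_background_cn(bp("a"), cn)
        assert not found and ann_lo.total_tumour == 2
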