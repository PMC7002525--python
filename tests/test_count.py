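"""Read classification, per-SV counting and VAF computation."""
import numpy as np
import pysam
import pytest

from svccf import (Breakend, Breakpoint, Direction, SampleMeta, SVClass,
                   ReadCategory, adjust_normals, classify_read, compute_vaf,
                   count_sv, generate_alignments)
from svccf.count import ReadCounts
from svccf.simulate import (_anomalous_read, _mk_read, _normal_read,
                            _sam_header, _spanning_pair, _split_read)


def make_bp(d1="+", d2="-", chrom2="1", p1=20_000, p2=60_000,
            cls=SVClass.UNKNOWN):
    return Breakpoint("sv", Breakend("1", p1, Direction(d1)),
                      Breakend(chrom2, p2, Direction(d2)), cls)


@pytest.fixture
def bp_del():
    return make_bp("+", "-", cls=SVClass.DEL)


class TestClassifyRead:
    def setup_method(self):
        self.meta = SampleMeta()
        self.bp = make_bp("+", "-")
        self.header = _sam_header(self.bp, self.meta)

    def test_split_matching_direction(self):
        read = _split_read(self.header, "r", self.bp.lo, self.meta, 15)
        assert classify_read([read], self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.SPLIT

    def test_split_opposite_direction_is_anomalous(self):
        # clip on the left of a '+' breakend supports the opposite direction
        wrong = Breakend("1", 20_000, Direction.MINUS)
        read = _split_read(self.header, "r", wrong, self.meta, 15)
        assert classify_read([read], self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.ANOMALOUS

    def test_subthreshold_clip_is_anomalous(self):
        read = _split_read(self.header, "r", self.bp.lo, self.meta, 5)
        assert classify_read([read], self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.ANOMALOUS

    def test_spanning_pair(self):
        pair = _spanning_pair(self.header, "r", self.bp.lo, self.bp.hi,
                              self.meta)
        assert classify_read(pair, self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.SPANNING

    def test_spanning_mates_not_facing_break_anomalous(self):
        # both mates on the wrong strand: geometry says discordant, but the
        # reads do not face the junction
        pair = _spanning_pair(self.header, "r", self.bp.lo, self.bp.hi,
                              self.meta)
        for r in pair:
            r.is_reverse = not r.is_reverse
        assert classify_read(pair, self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.ANOMALOUS

    def test_clean_crossing_read_is_normal(self):
        read = _normal_read(self.header, "r", self.bp.lo, self.meta)
        assert classify_read([read], self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.NORMAL

    def test_double_clipped_is_anomalous(self):
        read = _anomalous_read(self.header, "r", self.bp.lo, self.meta)
        assert classify_read([read], self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.ANOMALOUS

    def test_distant_read_is_irrelevant(self):
        read = _mk_read(self.header, "r", "1", 5_000, "100M")
        assert classify_read([read], self.bp.lo, self.meta,
                             partner=self.bp.hi) is ReadCategory.IRRELEVANT


class TestCountSV:
    @pytest.mark.parametrize("d1,d2,chrom2,cls", [
        ("+", "-", "1", SVClass.DEL),
        ("-", "+", "1", SVClass.DUP),
        ("+", "+", "1", SVClass.INV),
        ("-", "-", "1", SVClass.INV),
        ("+", "-", "2", SVClass.INTRX),
    ])
    def test_exact_tallies_per_class(self, tmp_path, d1, d2, chrom2, cls):
        meta = SampleMeta(expected_depth=100)
        bp = make_bp(d1, d2, chrom2=chrom2, cls=cls)
        path = generate_alignments(bp, 10, 8, 5, 30, 32, 4, meta, seed=1,
                                   out_path=tmp_path / "t.bam")
        with pysam.AlignmentFile(path) as aln:
            c = count_sv(bp, aln, meta)
        assert (c.split_lo, c.split_hi, c.spanning) == (10, 8, 5)
        assert (c.norm_lo, c.norm_hi, c.anomalous) == (30, 32, 4)
        assert c.support == 23
        assert c.depth_lo == 53 and c.depth_hi == 55

    def test_zero_reads_zero_counts(self, tmp_path):
        meta = SampleMeta()
        bp = make_bp(cls=SVClass.DEL)
        path = generate_alignments(bp, 0, 0, 0, 0, 0, 0, meta, seed=1,
                                   out_path=tmp_path / "t.bam")
        with pysam.AlignmentFile(path) as aln:
            c = count_sv(bp, aln, meta)
        assert c.support == 0 and c.norm_lo == 0 and not c.high_depth_flag

    def test_high_depth_flag(self, tmp_path):
        # expected_depth * max_cn = 50 * 4 = 200; 250 normals exceed it
        meta = SampleMeta(expected_depth=50, max_cn=4)
        bp = make_bp(cls=SVClass.DEL)
        path = generate_alignments(bp, 5, 5, 5, 250, 10, 0, meta, seed=1,
                                   out_path=tmp_path / "t.bam")
        with pysam.AlignmentFile(path) as aln:
            c = count_sv(bp, aln, meta)
        assert c.high_depth_flag

    def test_complex_sv_rejected(self, tmp_path):
        meta = SampleMeta()
        bp = make_bp(cls=SVClass.COMPLEX)
        with pytest.raises(ValueError, match="complex"):
            count_sv(bp, None, meta)

    def test_inversion_opposite_side_reads_not_counted(self, tmp_path):
        # reads supporting the reciprocal (-,-) breakpoint of an inversion
        # must not inflate the (+,+) breakpoint's support
        meta = SampleMeta(expected_depth=100)
        bp_plus = make_bp("+", "+", cls=SVClass.INV)
        bp_minus = make_bp("-", "-", cls=SVClass.INV)
        path = generate_alignments(bp_minus, 12, 12, 0, 0, 0, 0, meta, seed=2,
                                   out_path=tmp_path / "t.bam")
        with pysam.AlignmentFile(path) as aln:
            c = count_sv(bp_plus, aln, meta)
        assert c.support == 0
        assert c.anomalous == 24  # opposite-direction support is anomalous

    def test_impossible_geometry_raises(self, tmp_path):
        meta = SampleMeta()
        bp = make_bp(p1=20_000, p2=20_500, cls=SVClass.DEL)
        with pytest.raises(ValueError, match="too close"):
            generate_alignments(bp, 1, 1, 1, 1, 1, 0, meta, seed=1,
                                out_path=tmp_path / "t.bam")


class TestAdjustNormals:
    def test_duplication_scaling(self):
        # AF_norm = 1 - 0.8/2 = 0.6 applied to both ends' normals
        meta = SampleMeta(purity=0.8, ploidy=2.0)
        c = ReadCounts(split_lo=5, split_hi=5, spanning=2, norm_lo=50,
                       norm_hi=40)
        out = adjust_normals(c, SVClass.DUP, meta)
        assert out.norm_lo == pytest.approx(30.0)
        assert out.norm_hi == pytest.approx(24.0)
        assert out.adjusted

    def test_non_gain_unchanged(self):
        meta = SampleMeta(purity=0.8)
        c = ReadCounts(norm_lo=50, norm_hi=40)
        for cls in (SVClass.DEL, SVClass.INV, SVClass.TRX, SVClass.INTRX):
            out = adjust_normals(c, cls, meta)
            assert out.norm_lo == 50 and not out.adjusted

    def test_zero_purity_limit(self):
        meta = SampleMeta(purity=1e-9, ploidy=2.0)
        c = ReadCounts(norm_lo=50, norm_hi=50)
        out = adjust_normals(c, SVClass.DUP, meta)
        assert out.norm_lo == pytest.approx(50.0, rel=1e-6)


class TestComputeVAF:
    def test_balanced_counts(self):
        c = ReadCounts(split_lo=15, split_hi=10, spanning=5, norm_lo=30,
                       norm_hi=30)
        lo, hi = compute_vaf(c)
        assert lo.vaf == pytest.approx(0.5)
        assert hi.vaf == pytest.approx(0.5)

    def test_duplication_adjusted_vaf(self):
        # t=1, n_p=2: o' = 75 * 0.5 = 37.5, VAF = 25/62.5 = 0.4
        meta = SampleMeta(purity=1.0, ploidy=2.0)
        c = ReadCounts(split_lo=15, split_hi=5, spanning=5, norm_lo=75,
                       norm_hi=75)
        c = adjust_normals(c, SVClass.DUP, meta)
        lo, _ = compute_vaf(c)
        assert lo.vaf == pytest.approx(25 / 62.5)

    def test_zero_support(self):
        c = ReadCounts(norm_lo=40, norm_hi=40)
        lo, _ = compute_vaf(c)
        assert lo.vaf == 0.0

    def test_zero_depth_flagged(self):
        c = ReadCounts()
        lo, _ = compute_vaf(c)
        assert lo.d == 0
        with pytest.raises(ValueError):
            lo.vaf

    def test_per_side_support_mode(self):
        c = ReadCounts(split_lo=10, split_hi=6, spanning=4, norm_lo=30,
                       norm_hi=30, support_mode="per_side")
        lo, hi = compute_vaf(c)
        assert lo.b == 14 and hi.b == 10
        assert lo.d == 44 and hi.d == 40


class TestVAFProperties:
    def test_mean_vaf_half_purity_on_simulated_heterozygous(self):
        # non-gain SVs at purity t: expected VAF = t/2
        from svccf import SimConfig, simulate_counts

        for t in (0.4, 0.8):
            cfg = SimConfig(n_sv=(300,), clone_ccfs=(1.0,), purity=t,
                            depth=100, error_rate=0.0,
                            class_mix={"DEL": 1.0}, seed=5)
            ds, _ = simulate_counts(cfg)
            vaf = (ds["b1"] / ds["d1"]).mean()
            assert vaf == pytest.approx(t / 2, abs=0.01)

    def test_duplication_unadjusted_biased_low(self):
        from svccf import SimConfig, simulate_counts

        for t in (0.2, 0.6, 1.0):
            cfg = SimConfig(n_sv=(300,), clone_ccfs=(1.0,), purity=t,
                            depth=100, error_rate=0.0,
                            class_mix={"DUP": 1.0}, seed=6)
            ds, _ = simulate_counts(cfg)
            adj = (ds["b1"] / ds["d1"]).mean()
            raw = (ds["b1"] / (ds["b1"] + ds["norm1_raw"])).mean()
            assert adj == pytest.approx(t / 2, abs=0.012)
            if t > 0.21:  # bias grows with purity; tiny at t ~ 0.2
                assert raw < adj - 0.01
            else:
                assert raw <= adj + 1e-9
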