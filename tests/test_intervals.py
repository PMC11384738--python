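"""Interval algebra: BED I/O, merge, overlap, blacklist, consensus, categories."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfrewire.intervals import (
    BedParseError,
    GenomicInterval,
    RegionSet,
    categorize_by_condition,
    consensus_peaks,
    drop_unplaced,
    filter_blacklist,
    merge,
    overlap_pairs,
    read_bed,
    write_bed,
)

from conftest import covered_bases_oracle, overlap_pairs_oracle, random_region_set


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestGenomicInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(ValueError):
            iv(100, 100)
        with pytest.raises(ValueError):
            iv(200, 100)
        with pytest.raises(ValueError):
            iv(-5, 10)

    def test_half_open_overlap(self):
        assert iv(0, 100).overlap_bp(iv(100, 200)) == 0  # book-ended: no overlap
        assert iv(0, 100).overlap_bp(iv(50, 150)) == 50
        assert iv(0, 100).overlap_bp(iv(0, 100, chrom="chr2")) == 0


class TestBedIO:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n# comment\nchr2\t5\t10\tpeak\t3\t+\n")
        rs = read_bed(p)
        assert rs[0] == iv(0, 100)
        assert rs[1] == GenomicInterval("chr2", 5, 10, "peak", 3.0, "+")

    @pytest.mark.parametrize(
        "line",
        ["chr1\t100\t100", "chr1\t-1\t100", "chr1\tx\t100", "chr1\t100"],
    )
    def test_malformed_line_reports_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_round_trip_random(self, tmp_path, rng):
        rs = random_region_set(rng, 1000, genome_len=100_000, label="pk")
        path = tmp_path / "rt.bed"
        write_bed(rs, path)
        back = read_bed(path, label=rs.label)
        assert back.intervals == rs.intervals

    def test_drop_unplaced(self):
        rs = RegionSet(intervals=(iv(0, 10), iv(0, 10, chrom="chrUn_xx")))
        assert [x.chrom for x in drop_unplaced(rs)] == ["chr1"]


class TestMerge:
    def test_overlapping_and_bookended(self):
        got = merge(RegionSet(intervals=(iv(0, 100), iv(50, 150))))
        assert [(x.start, x.end) for x in got] == [(0, 150)]
        got = merge(RegionSet(intervals=(iv(0, 100), iv(100, 200))))
        assert [(x.start, x.end) for x in got] == [(0, 200)]

    def test_max_gap(self):
        got = merge(RegionSet(intervals=(iv(0, 100), iv(110, 200))), max_gap=10)
        assert [(x.start, x.end) for x in got] == [(0, 200)]

    def test_idempotent_and_coverage_preserving(self, rng):
        rs = random_region_set(rng, 500, genome_len=10_000)
        m = merge(rs)
        assert m.intervals == merge(m).intervals
        assert m.is_disjoint()
        got = {(x.chrom, b) for x in m for b in range(x.start, x.end)}
        assert got == covered_bases_oracle(rs)

    def test_matches_bedtools(self, tmp_path, rng):
        """Cross-check the merge dialect against bedtools merge."""
        rs = random_region_set(rng, 300, genome_len=50_000)
        src = tmp_path / "in.bed"
        with src.open("w") as fh:
            for x in rs:
                fh.write(f"{x.chrom}\t{x.start}\t{x.end}\n")
        try:
            out = subprocess.run(
                ["bedtools", "merge", "-i", str(src)],
                capture_output=True, text=True, check=True,
            ).stdout
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("bedtools unavailable")
        expected = [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.strip().splitlines())
        ]
        assert [(x.chrom, x.start, x.end) for x in merge(rs)] == expected


class TestOverlapPairs:
    def test_half_open_and_partial(self):
        a = RegionSet(intervals=(iv(0, 100),))
        b = RegionSet(intervals=(iv(100, 200),))
        assert overlap_pairs(a, b) == []
        b = RegionSet(intervals=(iv(50, 150),))
        [(pa, pb, ov)] = overlap_pairs(a, b)
        assert ov == 50

    def test_bad_min_frac(self):
        a = RegionSet(intervals=(iv(0, 10),))
        with pytest.raises(ValueError):
            overlap_pairs(a, a, min_frac=1.5)

    @pytest.mark.parametrize("min_bp,min_frac", [(1, 0.0), (10, 0.0), (1, 0.5)])
    def test_matches_all_pairs_oracle(self, rng, min_bp, min_frac):
        a = random_region_set(rng, 200, genome_len=10_000, label="a")
        b = random_region_set(rng, 200, genome_len=10_000, label="b")
        got = overlap_pairs(a, b, min_bp=min_bp, min_frac=min_frac)
        assert got == overlap_pairs_oracle(a, b, min_bp=min_bp, min_frac=min_frac)


class TestFilterBlacklist:
    def test_identity_whole_and_toy(self):
        peaks = RegionSet(intervals=(iv(10, 20), iv(30, 40)))
        assert filter_blacklist(peaks, RegionSet()).intervals == peaks.intervals
        whole = RegionSet(intervals=(iv(0, 1000),))
        assert len(filter_blacklist(peaks, whole)) == 0
        bl = RegionSet(intervals=(iv(35, 50),))
        assert [(x.start, x.end) for x in filter_blacklist(peaks, bl)] == [(10, 20)]


class TestConsensusPeaks:
    def test_identical_replicates(self):
        rs = RegionSet(intervals=(iv(0, 100), iv(500, 700)))
        assert consensus_peaks(rs, rs).intervals == rs.intervals

    def test_threshold_inclusive_and_below(self):
        r1 = RegionSet(intervals=(iv(0, 100),))
        assert len(consensus_peaks(r1, RegionSet(intervals=(iv(50, 150),)))) == 1
        assert len(consensus_peaks(r1, RegionSet(intervals=(iv(90, 150),)))) == 0

    def test_reference_side_denominator(self):
        # overlap 50 bp: 50% of the 100 bp rep1 peak but 25% of the rep2 peak
        r1 = RegionSet(intervals=(iv(0, 100),))
        r2 = RegionSet(intervals=(iv(50, 250),))
        assert len(consensus_peaks(r1, r2)) == 1
        assert len(consensus_peaks(r1, r2, reciprocal=True)) == 0

    def test_bad_fraction(self):
        rs = RegionSet(intervals=(iv(0, 10),))
        with pytest.raises(ValueError):
            consensus_peaks(rs, rs, min_overlap_frac=0.0)


class TestCategorize:
    def test_identical_and_disjoint(self):
        rs = RegionSet(label="c1", intervals=(iv(0, 100), iv(200, 300)))
        cats = categorize_by_condition(rs, rs.relabel("c2"))
        assert cats.n_cond1_only == cats.n_cond2_only == 0
        assert cats.n_shared_cond1 == cats.n_shared_cond2 == 2
        other = RegionSet(label="c2", intervals=(iv(1000, 1100),))
        cats = categorize_by_condition(rs, other)
        assert cats.n_shared_regions == 0
        assert cats.n_cond1_only == 2 and cats.n_cond2_only == 1

    def test_hand_traced_toy(self):
        c1 = RegionSet(label="c1", intervals=(iv(100, 200), iv(300, 400)))
        c2 = RegionSet(label="c2", intervals=(iv(150, 250), iv(500, 600)))
        cats = categorize_by_condition(c1, c2)
        assert [(x.start, x.end) for x in cats.cond1_only] == [(300, 400)]
        assert [(x.start, x.end) for x in cats.cond2_only] == [(500, 600)]
        assert [(x.start, x.end) for x in cats.shared] == [(100, 250)]

    def test_count_conservation_random(self, rng):
        for _ in range(20):
            c1 = random_region_set(rng, int(rng.integers(1, 60)), genome_len=5_000, label="c1")
            c2 = random_region_set(rng, int(rng.integers(1, 60)), genome_len=5_000, label="c2")
            cats = categorize_by_condition(c1, c2)
            assert cats.n_cond1_only + cats.n_shared_cond1 == len(c1)
            assert cats.n_cond2_only + cats.n_shared_cond2 == len(c2)
            # a peak is shared iff the all-pairs oracle finds an overlap
            shared1 = {iva for iva, _, _ in overlap_pairs_oracle(c1, c2)}
            assert cats.n_shared_cond1 == len(shared1)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 990), st.integers(1, 200)).map(
            lambda t: (t[0], min(1000, t[0] + t[1]))
        ),
        min_size=1,
        max_size=30,
    ),
    st.integers(0, 10),
)
def test_merge_commutative_and_coverage(pairs, max_gap):
    """merge() is order-invariant and, at gap 0, coverage-preserving."""
    ivs = tuple(GenomicInterval("chr1", s, e) for s, e in pairs)
    fwd = merge(RegionSet(intervals=ivs), max_gap=max_gap)
    rev = merge(RegionSet(intervals=ivs[::-1]), max_gap=max_gap)
    assert fwd.intervals == rev.intervals
    assert fwd.is_disjoint()
    if max_gap == 0:
        got = {b for x in fwd for b in range(x.start, x.end)}
        want = {b for s, e in pairs for b in range(s, e)}
        assert got == want
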