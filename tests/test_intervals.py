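"""Interval model, BED I/O and exact algebra against brute-force mask oracles."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from g4hub.intervals import (
    BedParseError,
    GenomeTable,
    GenomicInterval,
    IntervalSet,
    TssRecord,
    count_overlapping,
    intersect,
    merge,
    overlap_bp,
    promoter_intervals,
    read_bed,
    subtract,
    write_bed,
)
from conftest import CHROM_LEN, interval_mask, random_interval_set


# -- model invariants --------------------------------------------------------

@pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (10, 3)])
def test_invalid_coordinates_rejected(start, end):
    with pytest.raises(ValueError):
        GenomicInterval("chr1", start, end)


def test_invalid_strand_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 10, strand="*")


def test_genome_table_rejects_nonpositive_length():
    with pytest.raises(ValueError):
        GenomeTable({"chr1": 0})


def test_interval_set_sorts_on_construction():
    ivs = IntervalSet(
        [GenomicInterval("chr2", 5, 9), GenomicInterval("chr1", 100, 200),
         GenomicInterval("chr1", 50, 80)]
    )
    assert [(iv.chrom, iv.start) for iv in ivs] == [("chr1", 50), ("chr1", 100), ("chr2", 5)]


# -- BED I/O -----------------------------------------------------------------

def test_read_bed_sorts_and_parses(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1 100 200\nchr1 50 80\n")
    ivs = read_bed(p)
    assert [(iv.start, iv.end) for iv in ivs] == [(50, 80), (100, 200)]


def test_read_bed_empty_file(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert len(read_bed(p)) == 0


@pytest.mark.parametrize("line", ["chr1 x 200", "chr1 200 100", "chr1 5"])
def test_read_bed_malformed_line_names_line_number(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text("chr1 0 10\n" + line + "\n")
    with pytest.raises(BedParseError, match=":2"):
        read_bed(p)


def test_bed6_roundtrip_byte_identical(tmp_path, rng):
    """write -> read -> write reproduces the file byte for byte (100 fixtures)."""
    for trial in range(100):
        n = int(rng.integers(1, 30))
        starts = rng.integers(0, 9000, size=n)
        ivs = IntervalSet(
            [
                GenomicInterval(
                    f"chr{int(rng.integers(1, 4))}",
                    int(s),
                    int(s + rng.integers(1, 500)),
                    strand=str(rng.choice(["+", "-", "."])),
                    name=f"iv{k}",
                    score=float(np.round(rng.random() * 10, 3)),
                )
                for k, s in enumerate(starts)
            ]
        )
        p1, p2 = tmp_path / "r1.bed", tmp_path / "r2.bed"
        write_bed(ivs, p1)
        write_bed(read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes(), f"trial {trial}"


# -- merge -------------------------------------------------------------------

@pytest.mark.parametrize(
    "spans,gap,expected",
    [
        ([(0, 10), (5, 15)], 0, [(0, 15)]),
        ([(0, 10), (20, 30)], 0, [(0, 10), (20, 30)]),
        ([(0, 10), (20, 30)], 10, [(0, 30)]),
        ([(0, 10), (10, 20)], 0, [(0, 20)]),
    ],
)
def test_merge_examples(spans, gap, expected):
    ivs = IntervalSet([GenomicInterval("chr1", s, e) for s, e in spans])
    assert [(iv.start, iv.end) for iv in merge(ivs, gap)] == expected


def test_merge_negative_gap_rejected():
    with pytest.raises(ValueError):
        merge(IntervalSet([GenomicInterval("chr1", 0, 5)]), gap=-1)


def test_merge_matches_mask_oracle(rng):
    for _ in range(50):
        ivs = random_interval_set(rng, n=200)
        merged = merge(ivs)
        assert np.array_equal(interval_mask(merged), interval_mask(ivs))
        starts = np.array([iv.start for iv in merged])
        ends = np.array([iv.end for iv in merged])
        assert np.all(starts[1:] > ends[:-1])  # disjoint after merge


@given(st.integers(0, 2**31 - 1), st.integers(0, 50))
def test_merge_idempotent(seed, gap):
    ivs = random_interval_set(np.random.default_rng(seed), n=50)
    once = merge(ivs, gap)
    assert merge(once, gap) == once


# -- subtract / intersect ----------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((0, 100), [(40, 60)], [(0, 40), (60, 100)]),
        ((10, 20), [(0, 50)], []),
        ((10, 20), [(30, 50)], [(10, 20)]),
        ((0, 100), [(0, 10), (90, 100)], [(10, 90)]),
    ],
)
def test_subtract_examples(a, b, expected):
    res = subtract(
        IntervalSet([GenomicInterval("chr1", *a)]),
        IntervalSet([GenomicInterval("chr1", s, e) for s, e in b]),
    )
    assert [(iv.start, iv.end) for iv in res] == expected


def test_subtract_matches_mask_oracle(rng):
    for _ in range(50):
        a = random_interval_set(rng, n=40)
        b = random_interval_set(rng, n=40)
        got = interval_mask(subtract(a, b))
        want = interval_mask(a) & ~interval_mask(b)
        assert np.array_equal(got, want)


@given(st.integers(0, 2**31 - 1))
def test_subtract_plus_intersect_reconstructs_footprint(seed):
    rng = np.random.default_rng(seed)
    a = random_interval_set(rng, n=30)
    b = random_interval_set(rng, n=30)
    recon = interval_mask(subtract(a, b)) | interval_mask(intersect(a, b))
    assert np.array_equal(recon, interval_mask(a))


# -- count_overlapping -------------------------------------------------------

def test_count_overlapping_examples():
    q = IntervalSet([GenomicInterval("chr1", 100, 200)])
    s = IntervalSet([GenomicInterval("chr1", 150, 160)])
    assert count_overlapping(q, s) == 1
    assert count_overlapping(IntervalSet([]), s) == 0
    assert count_overlapping(q, s, min_overlap=10) == 1
    assert count_overlapping(q, s, min_overlap=11) == 0


def test_count_overlapping_counts_each_query_once():
    q = IntervalSet([GenomicInterval("chr1", 0, 100)])
    s = IntervalSet([GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 30, 40)])
    assert count_overlapping(q, s) == 1


def test_count_overlapping_min_overlap_validation():
    q = IntervalSet([GenomicInterval("chr1", 0, 10)])
    with pytest.raises(ValueError):
        count_overlapping(q, q, min_overlap=0)


def test_count_overlapping_matches_quadratic_oracle(rng):
    for _ in range(20):
        q = random_interval_set(rng, n=25)
        s = random_interval_set(rng, n=25)
        smask = interval_mask(s)
        want = sum(1 for iv in q if smask[iv.start: iv.end].any())
        assert count_overlapping(q, s) == want
        # bp agreement too
        want_bp = np.array([int(smask[iv.start: iv.end].sum()) for iv in q])
        assert np.array_equal(overlap_bp(q, s), want_bp)


@given(st.integers(0, 2**31 - 1))
def test_count_overlapping_monotone_in_subject(seed):
    rng = np.random.default_rng(seed)
    q = random_interval_set(rng, n=30)
    s = random_interval_set(rng, n=30)
    extra = random_interval_set(rng, n=10)
    bigger = IntervalSet(list(s) + list(extra))
    assert count_overlapping(q, bigger) >= count_overlapping(q, s)


def test_algebra_agrees_with_bedtools(tmp_path, rng):
    """Independent cross-check of merge and subtract against bedtools."""
    a = random_interval_set(rng, n=60)
    b = random_interval_set(rng, n=60)
    pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(IntervalSet(sorted(a, key=lambda i: (i.chrom, i.start, i.end))), pa)
    write_bed(b, pb)

    def parse(out):
        return [tuple(map(int, line.split("\t")[1:3]))
                for line in out.strip().splitlines() if line]

    merged = subprocess.run(
        ["bedtools", "merge", "-i", str(pa)], capture_output=True, text=True, check=True
    )
    assert [(iv.start, iv.end) for iv in merge(a)] == parse(merged.stdout)
    sub = subprocess.run(
        ["bedtools", "subtract", "-a", str(pa), "-b", str(pb)],
        capture_output=True, text=True, check=True,
    )
    got = sorted((iv.start, iv.end) for iv in subtract(a, b))
    assert got == sorted(parse(sub.stdout))


# -- promoters ---------------------------------------------------------------

def test_promoter_windows():
    genome = GenomeTable({"chr1": 100_000})
    recs = [
        TssRecord("plus", "chr1", 5000, "+"),
        TssRecord("minus", "chr1", 5000, "-"),
        TssRecord("clipped", "chr1", 300, "+"),
    ]
    prom = promoter_intervals(recs, genome, upstream=1000, downstream=0)
    spans = {iv.name: (iv.start, iv.end) for iv in prom}
    assert spans["plus"] == (4000, 5000)
    assert spans["minus"] == (5000, 6000)
    assert spans["clipped"] == (0, 300)


def test_promoter_downstream_extension_is_strand_mirrored():
    genome = GenomeTable({"chr1": 100_000})
    prom = promoter_intervals(
        [TssRecord("m", "chr1", 5000, "-")], genome, upstream=1000, downstream=200
    )
    assert (prom[0].start, prom[0].end) == (4800, 6000)


def test_promoter_fully_outside_chromosome_excluded():
    genome = GenomeTable({"chr1": 100_000})
    prom = promoter_intervals(
        [TssRecord("gone", "chr1", 0, "+"), TssRecord("ok", "chr1", 5000, "+")],
        genome, upstream=1000,
    )
    assert len(prom) == 1 and prom.n_excluded == 1


def test_promoter_invalid_window_args():
    genome = GenomeTable({"chr1": 1000})
    recs = [TssRecord("g", "chr1", 500, "+")]
    with pytest.raises(ValueError):
        promoter_intervals(recs, genome, upstream=0)
    with pytest.raises(ValueError):
        promoter_intervals(recs, genome, upstream=100, downstream=-5)
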