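"""Interval arithmetic, BED round-trips, promoters, classification, overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoreg.intervals import (
    BedParseError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    classify_element,
    downstream_regions,
    overlap_any,
    overlap_pairs,
    promoter_regions,
    read_intervals,
    write_intervals,
)


# ---------------------------------------------------------------------------
# BED parsing and round trips
# ---------------------------------------------------------------------------


def test_read_intervals_parses_named_interval(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\tHAR-X\n")
    ivs = read_intervals(p)
    assert len(ivs) == 1
    iv = ivs[0]
    assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "HAR-X")


@pytest.mark.parametrize(
    "content",
    ["chr1\t200\t100\n", "chr1\t100\n", "chr1\tx\t200\n"],
    ids=["inverted", "too-few-columns", "non-integer"],
)
def test_read_intervals_rejects_malformed(tmp_path, content):
    p = tmp_path / "bad.bed"
    p.write_text(content)
    with pytest.raises(BedParseError, match="line 1"):
        read_intervals(p)


def test_unsorted_input_is_sorted_and_roundtrips(tmp_path):
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 10_000, 50)
    recs = [
        (f"chr{1 + (i % 2)}", int(s), int(s) + int(rng.integers(1, 100)), f"e{i}")
        for i, s in enumerate(starts)
    ]
    rng.shuffle(recs)
    ivs = IntervalSet.from_records(recs)
    keys = list(zip(ivs.chroms.astype(str), ivs.starts))
    assert keys == sorted(keys)
    p = tmp_path / "rt.bed"
    write_intervals(ivs, p)
    assert read_intervals(p) == ivs


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        IntervalSet(["chr1"], [-5], [10])


# ---------------------------------------------------------------------------
# promoters / downstream flanks
# ---------------------------------------------------------------------------


def _gene(gene_id="G1", chrom="chr1", strand="+", tss=10_000, tes=20_000, **kw):
    if strand == "-":
        tss, tes = max(tss, tes), min(tss, tes)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                     tes=tes, exons=kw.pop("exons", [(min(tss, tes), max(tss, tes))]),
                     **kw)


def test_promoter_plus_strand_2kb():
    prom = promoter_regions([_gene(strand="+", tss=10_000)], 2000)
    assert (prom[0].start, prom[0].end) == (8000, 10_000)


def test_promoter_minus_strand_mirror():
    g = GeneModel("G1", "chr1", "-", tss=10_000, tes=5_000, exons=[(5_000, 10_000)])
    prom = promoter_regions([g], 2000)
    assert (prom[0].start, prom[0].end) == (10_000, 12_000)


def test_promoter_clipped_at_chromosome_start():
    prom = promoter_regions([_gene(tss=500, tes=5_000)], 2000)
    assert (prom[0].start, prom[0].end) == (0, 500)


def test_promoter_clipped_at_chromosome_end():
    g = GeneModel("G1", "chr1", "-", tss=9_500, tes=5_000, exons=[(5_000, 9_500)])
    prom = promoter_regions([g], 2000, chrom_sizes={"chr1": 10_000})
    assert (prom[0].start, prom[0].end) == (9_500, 10_000)


def test_downstream_regions_strand_aware():
    down = downstream_regions([_gene(strand="+", tss=10_000, tes=20_000)], 1000)
    assert (down[0].start, down[0].end) == (20_000, 21_000)
    g = GeneModel("G2", "chr1", "-", tss=20_000, tes=10_000, exons=[(10_000, 20_000)])
    down = downstream_regions([g], 1000)
    assert (down[0].start, down[0].end) == (9_000, 10_000)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def gene_for_classes():
    # + strand gene 10k-20k: exon1 10000-10500 (utr5 first 100 bp),
    # exon2 15000-15500, exon3 19500-20000 (utr3 last 150 bp)
    return GeneModel(
        gene_id="GENE_B", chrom="chr1", strand="+", tss=10_000, tes=20_000,
        exons=[(10_000, 10_500), (15_000, 15_500), (19_500, 20_000)],
        utr5=[(10_000, 10_100)], utr3=[(19_850, 20_000)], cds_length=1200,
    )


@pytest.mark.parametrize(
    "start,end,category,coding",
    [
        (15_100, 15_200, "exon", True),
        (10_020, 10_080, "utr5", True),
        (19_900, 19_950, "utr3", True),
        (9_400, 9_600, "promoter1kb", True),
        (20_200, 20_400, "downstream1kb", True),
        (12_000, 12_100, "intron", False),
        (40_000, 40_100, "intergenic", False),
    ],
)
def test_classify_element_categories(gene_for_classes, start, end, category, coding):
    cat = classify_element(GenomicInterval("chr1", start, end), [gene_for_classes])
    assert cat.category == category
    assert cat.coding is coding
    if coding:
        assert cat.gene_ids == ("GENE_B",)


def test_classify_precedence_exon_over_intron(gene_for_classes):
    # spans exon2 and surrounding intron: exon wins
    cat = classify_element(GenomicInterval("chr1", 14_900, 15_100), [gene_for_classes])
    assert cat.category == "exon"


def test_classify_element_two_genes_owns_both(gene_for_classes):
    g2 = GeneModel(
        gene_id="GENE_C", chrom="chr1", strand="-", tss=15_600, tes=15_050,
        exons=[(15_050, 15_600)],
    )
    cat = classify_element(GenomicInterval("chr1", 15_100, 15_200),
                           [gene_for_classes, g2])
    assert set(cat.gene_ids) == {"GENE_B", "GENE_C"}


def test_classification_partitions_synthetic_genome(small_study):
    """Every base of a small region falls in exactly one category; the
    coding + intron + intergenic fractions sum to 1 by construction."""
    genes = [g for g in small_study.genes if g.chrom == "chr1"][:5]
    lo = min(g.start for g in genes) - 2000
    hi = max(g.end for g in genes) + 2000
    counts = {}
    for pos in range(lo, hi, 97):  # stride sampling of bases
        cat = classify_element(GenomicInterval("chr1", pos, pos + 1), genes)
        counts[cat.category] = counts.get(cat.category, 0) + 1
    total = sum(counts.values())
    coding = sum(v for k, v in counts.items()
                 if k not in ("intron", "intergenic"))
    assert coding + counts.get("intron", 0) + counts.get("intergenic", 0) == total


# ---------------------------------------------------------------------------
# overlap primitive
# ---------------------------------------------------------------------------


def brute_force_pairs(a, b):
    out = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if str(a.chroms[i]) != str(b.chroms[j]):
                continue
            ov = min(a.ends[i], b.ends[j]) - max(a.starts[i], b.starts[j])
            if ov > 0:
                out.add((i, j, int(ov)))
    return out


def test_half_open_adjacency_no_overlap():
    a = IntervalSet(["chr1"], [0], [10])
    b = IntervalSet(["chr1"], [10], [20])
    assert overlap_pairs(a, b) == []


def test_simple_overlap_length():
    a = IntervalSet(["chr1"], [0], [10])
    b = IntervalSet(["chr1"], [5], [15])
    assert overlap_pairs(a, b) == [(0, 0, 5)]


def test_overlap_matches_quadratic_oracle():
    rng = np.random.default_rng(42)
    def rand_set(n):
        starts = rng.integers(0, 5_000, n)
        lens = rng.integers(1, 400, n)
        chroms = rng.choice(["chr1", "chr2"], n)
        return IntervalSet(chroms, starts, starts + lens)
    a, b = rand_set(500), rand_set(500)
    assert set(overlap_pairs(a, b)) == brute_force_pairs(a, b)
    mask = overlap_any(a, b)
    hit_idx = {i for i, _, _ in brute_force_pairs(a, b)}
    assert set(np.flatnonzero(mask)) == hit_idx


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.tuples(st.integers(0, 2_000), st.integers(1, 300)),
             min_size=1, max_size=30),
    st.lists(st.tuples(st.integers(0, 2_000), st.integers(1, 300)),
             min_size=1, max_size=30),
    st.integers(0, 10_000),
)
def test_overlap_shift_invariance(a_raw, b_raw, k):
    """Shifting all coordinates by +k leaves overlap results unchanged."""
    a = IntervalSet(["chr1"] * len(a_raw), [s for s, _ in a_raw],
                    [s + l for s, l in a_raw])
    b = IntervalSet(["chr1"] * len(b_raw), [s for s, _ in b_raw],
                    [s + l for s, l in b_raw])
    a_k = IntervalSet(["chr1"] * len(a_raw), [s + k for s, _ in a_raw],
                      [s + l + k for s, l in a_raw])
    b_k = IntervalSet(["chr1"] * len(b_raw), [s + k for s, _ in b_raw],
                      [s + l + k for s, l in b_raw])
    assert overlap_pairs(a, b) == overlap_pairs(a_k, b_k)
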