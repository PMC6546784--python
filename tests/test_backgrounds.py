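"""GC content, matched-background sampling, conserved-region calling."""

import numpy as np
import pytest
from scipy import stats

from evoreg.backgrounds import (
    sample_conservation_matched,
    sample_gc_length_matched,
)
from evoreg.conservation import ConservationTrack, call_conserved_regions
from evoreg.genome import AllAmbiguousError, GenomeSequence
from evoreg.intervals import IntervalSet


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("AATT", 0.0), ("GCGC", 1.0), ("ACGTACGT", 0.5), ("acgt", 0.5),
     ("GCNN", 1.0)],  # Ns excluded from numerator and denominator
)
def test_gc_content(seq, expected):
    g = GenomeSequence.from_dict({"chr1": seq})
    assert g.gc_content("chr1", 0, len(seq)) == pytest.approx(expected)


def test_gc_content_all_ambiguous_errors():
    g = GenomeSequence.from_dict({"chr1": "NNNN"})
    with pytest.raises(AllAmbiguousError):
        g.gc_content("chr1", 0, 4)


def test_gc_prefix_matches_direct_count(small_study):
    rng = np.random.default_rng(3)
    for _ in range(20):
        s = int(rng.integers(0, 2_990_000))
        e = s + int(rng.integers(50, 5000))
        seq = small_study.genome.sequence("chr1", s, e).upper()
        direct = (seq.count("G") + seq.count("C")) / len(seq)
        assert small_study.genome.gc_content("chr1", s, e) == pytest.approx(direct)


# ---------------------------------------------------------------------------
# GC/length-matched sampling
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def gc_matched(small_study):
    elems = small_study.elements["HAR"].subset(np.arange(120))
    return elems, sample_gc_length_matched(
        elems, small_study.genome, reps=10, gc_tol=0.05, seed=5
    )


def test_matched_controls_same_chrom_length_gc(small_study, gc_matched):
    elems, ms = gc_matched
    assert ms.total_drawn == 120 * 10
    for i in range(len(elems)):
        src = elems[i]
        src_gc = small_study.genome.gc_content(src.chrom, src.start, src.end)
        for ctrl in ms.controls[i]:
            assert ctrl.chrom == src.chrom
            assert len(ctrl) == len(src)
            gc = small_study.genome.gc_content(ctrl.chrom, ctrl.start, ctrl.end)
            assert abs(gc - src_gc) < 0.05


def test_matched_pool_is_deduplicated(gc_matched):
    _, ms = gc_matched
    seen = {(iv.chrom, iv.start, iv.end) for iv in ms.pooled}
    assert len(seen) == len(ms.pooled) == ms.n_dedup


def test_matched_sampling_deterministic(small_study):
    elems = small_study.elements["HAR"].subset(np.arange(20))
    a = sample_gc_length_matched(elems, small_study.genome, reps=5, seed=9)
    b = sample_gc_length_matched(elems, small_study.genome, reps=5, seed=9)
    c = sample_gc_length_matched(elems, small_study.genome, reps=5, seed=10)
    assert a.pooled == b.pooled
    assert c.pooled != a.pooled


def test_control_gc_distribution_matches_sources(small_study, gc_matched):
    """KS distance between source and control GC distributions stays small."""
    elems, ms = gc_matched
    src_gc = [
        small_study.genome.gc_content(iv.chrom, iv.start, iv.end) for iv in elems
    ]
    ctrl_gc = [
        small_study.genome.gc_content(iv.chrom, iv.start, iv.end)
        for iv in ms.pooled
    ]
    d = stats.ks_2samp(src_gc, ctrl_gc).statistic
    assert d < 0.1


# ---------------------------------------------------------------------------
# conserved-region calling
# ---------------------------------------------------------------------------


def test_constant_track_gives_one_region():
    track = ConservationTrack({"chr1": (np.array([0, 100]), np.array([0.5]))})
    regions = call_conserved_regions(track)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (0, 100)


def test_short_run_below_min_len_dropped():
    track = ConservationTrack(
        {"chr1": (np.array([0, 40, 55, 100]), np.array([0.1, 0.8, 0.1]))}
    )
    assert len(call_conserved_regions(track, min_len=20)) == 0
    # a 21 bp run qualifies ("larger than 20 bp" is strict)
    track21 = ConservationTrack(
        {"chr1": (np.array([0, 40, 61, 100]), np.array([0.1, 0.8, 0.1]))}
    )
    assert len(call_conserved_regions(track21, min_len=20)) == 1


def test_threshold_is_strict():
    track = ConservationTrack({"chr1": (np.array([0, 100]), np.array([0.40]))})
    assert len(call_conserved_regions(track, threshold=0.40)) == 0


def test_called_regions_match_per_base_oracle():
    rng = np.random.default_rng(12)
    scores = np.repeat(rng.uniform(0, 1, 200), rng.integers(1, 40, 200))
    track = ConservationTrack.from_arrays({"chr1": scores})
    called = call_conserved_regions(track, min_len=20, threshold=0.40)
    # per-base brute force
    above = scores > 0.40
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j + 1 - i > 20:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    assert [(iv.start, iv.end) for iv in called] == runs


def test_mean_score_batch_matches_direct():
    rng = np.random.default_rng(4)
    scores = np.repeat(rng.uniform(0, 1, 50), rng.integers(5, 50, 50))
    track = ConservationTrack.from_arrays({"chr1": scores})
    starts = rng.integers(0, len(scores) - 100, 30)
    ends = starts + rng.integers(10, 100, 30)
    got = track.mean_score_batch("chr1", starts, ends)
    want = [scores[s:e].mean() for s, e in zip(starts, ends)]
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_bedgraph_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    scores = np.repeat(np.round(rng.uniform(0, 1, 30), 3), rng.integers(5, 30, 30))
    track = ConservationTrack.from_arrays({"chr1": scores})
    p = tmp_path / "c.bedGraph"
    track.to_bedgraph(p)
    back = ConservationTrack.from_bedgraph(p, {"chr1": len(scores)})
    s = np.arange(0, len(scores) - 10, 7)
    np.testing.assert_allclose(
        back.mean_score_batch("chr1", s, s + 10),
        track.mean_score_batch("chr1", s, s + 10),
        rtol=1e-9,
    )


# ---------------------------------------------------------------------------
# conservation-matched sampling
# ---------------------------------------------------------------------------


def test_conservation_matched_on_planted_islands():
    """Elements on high-score islands draw controls that land on islands."""
    rng = np.random.default_rng(21)
    L = 400_000
    scores = np.full(L, 0.1)
    island_starts = np.arange(2_000, L - 2_000, 4_000)
    for s in island_starts:
        scores[s : s + 500] = 0.8
    track = ConservationTrack.from_arrays({"chr1": scores})
    starts = rng.choice(island_starts, 30, replace=False)
    elems = IntervalSet(["chr1"] * 30, starts, starts + 400)
    sets = sample_conservation_matched(elems, track, n_sets=20, seed=3)
    assert len(sets) == 20 and all(len(s) == 30 for s in sets)
    on_island = 0
    total = 0
    island_set = set(island_starts)
    for st_ in sets:
        for iv in st_:
            total += 1
            # mean score ~0.8 only achievable on an island
            if track.mean_score(iv.chrom, iv.start, iv.end) > 0.6:
                on_island += 1
    assert on_island / total >= 0.95


def test_conservation_matched_constant_track_degenerates_to_length():
    track = ConservationTrack({"chr1": (np.array([0, 100_000]), np.array([0.3]))})
    elems = IntervalSet(["chr1"] * 5, [0, 100, 200, 300, 400],
                        [50, 150, 250, 350, 450])
    sets = sample_conservation_matched(elems, track, n_sets=5, seed=1)
    for st_ in sets:
        assert list(st_.lengths) == [50] * 5
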