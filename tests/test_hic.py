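"""Contact binning, locus profiles, Weibull null, BH correction, targets."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from evoreg.hic import (
    ContactMatrix,
    DegenerateFitError,
    LocusProfile,
    assign_targets,
    bin_anchor,
    correct_and_call,
    fit_null,
    interaction_pvalues,
    locus_profile,
    profiles_for_intervals,
)
from evoreg.intervals import GeneModel, GenomicInterval, IntervalSet


# ---------------------------------------------------------------------------
# binning and profiles
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "start,end,bins",
    [
        (25_000, 26_000, [2]),
        (9_500, 10_500, [0, 1]),
        (123_456, 123_472, [12]),  # a 16 bp element maps to exactly one bin
    ],
)
def test_bin_anchor(start, end, bins):
    assert bin_anchor(GenomicInterval("chr1", start, end), 10_000) == bins


@pytest.fixture(scope="module")
def toy_contacts():
    n = 300
    rng = np.random.default_rng(1)
    rows, cols, vals = [], [], []
    for o in range(1, 100):
        i = np.arange(n - o)
        rows.append(i)
        cols.append(i + o)
        vals.append(rng.uniform(0.5, 2.0, n - o))
    m = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return ContactMatrix({"chr1": m}, bin_size=10_000)


def test_interior_anchor_has_198_candidates(toy_contacts):
    prof = locus_profile(toy_contacts, "chr1", 150, window=1_000_000)
    assert len(prof) == 198
    assert prof.offsets.min() == -99 and prof.offsets.max() == 99
    assert 0 not in prof.offsets


def test_boundary_anchor_clipped(toy_contacts):
    prof = locus_profile(toy_contacts, "chr1", 3)
    assert len(prof) == 3 + 99


def test_distance_arithmetic(toy_contacts):
    prof = locus_profile(toy_contacts, "chr1", 150)
    d = dict(zip(prof.offsets, prof.distances))
    assert d[7] == 70_000 and d[-42] == 420_000


def test_symmetric_lookup(toy_contacts):
    assert toy_contacts.get("chr1", 10, 20) == toy_contacts.get("chr1", 20, 10)
    assert toy_contacts.get("chr1", 5, 250) == 0.0  # absent entry reads as 0


def test_coo_roundtrip(tmp_path, toy_contacts):
    p = tmp_path / "c.tsv"
    toy_contacts.write_coo(p)
    back = ContactMatrix.read_coo(p, {"chr1": 3_000_000}, 10_000)
    prof_a = locus_profile(toy_contacts, "chr1", 150)
    prof_b = locus_profile(back, "chr1", 150)
    np.testing.assert_allclose(prof_a.values, prof_b.values, rtol=1e-5)


# ---------------------------------------------------------------------------
# Weibull null
# ---------------------------------------------------------------------------


def _profile(chrom, anchor, values, distances=None):
    n = len(values)
    offsets = np.arange(1, n + 1)
    return LocusProfile(
        chrom=chrom, anchor=anchor, offsets=offsets,
        distances=offsets * 10_000 if distances is None else distances,
        values=np.asarray(values, float),
    )


def test_weibull_mle_recovery_within_5pct():
    rng = np.random.default_rng(123)
    draws = 5.0 * rng.weibull(2.0, 5000)
    profiles = [_profile("chr1", i, [v], distances=np.array([10_000]))
                for i, v in enumerate(draws)]
    null = fit_null(profiles)
    k, lam = null.params("chr1", 10_000)
    assert abs(k - 2.0) / 2.0 < 0.05
    assert abs(lam - 5.0) / 5.0 < 0.05


def test_fit_ignores_zeros():
    """Adding zero contacts leaves the fit unchanged (positive-only contract)."""
    rng = np.random.default_rng(5)
    draws = 3.0 * rng.weibull(1.5, 2000)
    with_zeros = np.concatenate([draws, np.zeros(2000)])
    prof_a = _profile("chr1", 0, with_zeros, distances=np.full(4000, 10_000))
    prof_b = _profile("chr1", 0, draws, distances=np.full(2000, 10_000))
    null_a = fit_null([prof_a], min_obs=1)
    null_b = fit_null([prof_b], min_obs=1)
    assert null_a.params("chr1", 10_000) == null_b.params("chr1", 10_000)
    assert null_a.cells[("chr1", 10_000)].zero_frac == pytest.approx(0.5)


def test_degenerate_identical_observations_error():
    prof = _profile("chr1", 0, np.full(50, 2.5), distances=np.full(50, 10_000))
    with pytest.raises(DegenerateFitError):
        fit_null([prof], min_obs=1)


def test_no_positive_observations_error():
    prof = _profile("chr1", 0, np.zeros(50), distances=np.full(50, 10_000))
    with pytest.raises(DegenerateFitError, match="chr1"):
        fit_null([prof], min_obs=1)


def test_pooling_flag_set_for_sparse_cells():
    rng = np.random.default_rng(9)
    # two distances with 5 obs each; min_obs 8 forces pooling
    vals = rng.weibull(2.0, 10)
    prof = _profile(
        "chr1", 0, vals,
        distances=np.repeat([10_000, 20_000], 5),
    )
    null = fit_null([prof], min_obs=8)
    assert null.cells[("chr1", 10_000)].pooled
    assert null.cells[("chr1", 20_000)].pooled


# ---------------------------------------------------------------------------
# survival p-values
# ---------------------------------------------------------------------------


@pytest.fixture()
def unit_null():
    from evoreg.hic import _Cell, NullModel

    null = NullModel()
    null.cells[("chr1", 10_000)] = _Cell(1.0, 1.0, 100, False, 0.0)
    null.cells[("chr1", 20_000)] = _Cell(2.0, 3.0, 100, False, 0.0)
    return null


def test_survival_closed_forms(unit_null):
    assert unit_null.survival("chr1", 10_000, 0.0) == 1.0
    assert unit_null.survival("chr1", 10_000, 1.0) == pytest.approx(math.exp(-1))
    # at the null median the survival is exactly 1/2
    k, lam = 2.0, 3.0
    median = lam * math.log(2) ** (1 / k)
    assert unit_null.survival("chr1", 20_000, median) == pytest.approx(0.5)


def test_pvalues_monotone_in_contact(unit_null):
    prof = LocusProfile(
        chrom="chr1", anchor=0, offsets=np.array([1, 1, 1]),
        distances=np.array([10_000] * 3), values=np.array([0.5, 1.0, 2.0]),
    )
    calls = interaction_pvalues(prof, unit_null, "e")
    p = calls["p_value"].to_numpy()
    assert p[0] > p[1] > p[2]


# ---------------------------------------------------------------------------
# BH correction
# ---------------------------------------------------------------------------


def test_bh_matches_hand_computed_step_up():
    calls = pd.DataFrame(
        {"element": "e", "chrom": "chr1", "anchor": 0, "bin": [1, 2, 3, 4],
         "distance": 10_000, "contact": 1.0,
         "p_value": [0.001, 0.01, 0.02, 0.9]}
    )
    out = correct_and_call(calls, fdr=0.01)
    np.testing.assert_allclose(
        out["q_value"], [0.004, 0.02, 0.02 * 4 / 3, 0.9], rtol=1e-12
    )
    assert out["significant"].tolist() == [True, False, False, False]


def test_all_p_one_nothing_significant():
    calls = pd.DataFrame(
        {"element": "e", "chrom": "chr1", "anchor": 0, "bin": range(10),
         "distance": 10_000, "contact": 0.0, "p_value": 1.0}
    )
    out = correct_and_call(calls)
    assert not out["significant"].any()


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------


@pytest.fixture()
def assignment_fixture():
    # GENE_A promoter at [48_000, 50_000) -> bin 4; GENE_B body hosts an exon
    gene_a = GeneModel("GENE_A", "chr1", "+", tss=50_000, tes=60_000,
                       exons=[(50_000, 60_000)])
    gene_b = GeneModel("GENE_B", "chr1", "+", tss=200_000, tes=210_000,
                       exons=[(200_000, 210_000)])
    elements = IntervalSet(
        ["chr1", "chr1", "chr1"],
        [305_000, 205_000, 405_000],
        [305_500, 205_200, 405_400],
        ["e_inter", "e_exonic", "e_silent"],
    )
    calls = pd.DataFrame(
        {
            "element": ["e_inter", "e_inter", "e_silent"],
            "chrom": "chr1",
            "anchor": [30, 30, 40],
            "bin": [4, 7, 9],
            "distance": [260_000, 230_000, 310_000],
            "contact": [5.0, 4.0, 0.1],
            "p_value": [1e-9, 1e-8, 0.9],
            "q_value": [1e-6, 1e-5, 0.99],
            "significant": [True, True, False],
        }
    )
    return calls, elements, [gene_a, gene_b]


def test_fetal_full_interaction_and_direct(assignment_fixture):
    calls, elements, genes = assignment_fixture
    tmap = assign_targets(calls, elements, genes, mode="fetal_full")
    rows = {(r.element, r.gene): r.evidence for r in tmap.itertuples(index=False)}
    # intergenic element with significant promoter-bin call -> interaction
    assert rows[("e_inter", "GENE_A")] == "interaction"
    # exonic element directly assigned
    assert rows[("e_exonic", "GENE_B")] == "coding_direct"
    # no target from the non-significant call
    assert "e_silent" not in {e for e, _ in rows}
    # bin 7 overlaps no promoter -> no extra pair
    assert len(rows) == 2


def test_adult_promoter_only_drops_direct(assignment_fixture):
    calls, elements, genes = assignment_fixture
    tmap = assign_targets(calls, elements, genes, mode="adult_promoter_only")
    assert set(tmap["evidence"]) <= {"interaction"}
    assert ("e_exonic" not in set(tmap["element"]))


def test_promoter_split_direct_assignment(assignment_fixture):
    calls, elements, genes = assignment_fixture
    elements2 = IntervalSet(
        ["chr1"], [48_500], [48_700], ["e_prom"]
    )
    tmap = assign_targets(calls, elements2, genes, mode="promoter_split")
    rows = {(r.element, r.gene): r.evidence for r in tmap.itertuples(index=False)}
    assert rows[("e_prom", "GENE_A")] == "coding_direct"


def test_assignment_stable_under_call_order(assignment_fixture):
    calls, elements, genes = assignment_fixture
    shuffled = calls.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = assign_targets(calls, elements, genes, mode="fetal_full")
    b = assign_targets(shuffled, elements, genes, mode="fetal_full")
    pd.testing.assert_frame_equal(a, b)


def test_multibin_element_collapses_min_q(assignment_fixture):
    _, _, genes = assignment_fixture
    elements = IntervalSet(["chr1"], [305_000], [325_000], ["e_wide"])
    calls = pd.DataFrame(
        {
            "element": ["e_wide", "e_wide"],
            "chrom": "chr1",
            "anchor": [30, 31],
            "bin": [4, 4],
            "distance": [260_000, 270_000],
            "contact": [5.0, 6.0],
            "p_value": [1e-9, 1e-10],
            "q_value": [1e-6, 1e-7],
            "significant": [True, True],
        }
    )
    tmap = assign_targets(calls, elements, genes, mode="fetal_full")
    assert len(tmap) == 1
    assert tmap.iloc[0]["q_value"] == pytest.approx(1e-7)
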