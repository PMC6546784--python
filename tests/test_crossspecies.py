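"""Stage Z-scores, delta expression Z, breakpoint/dNdS tests, modules."""

import numpy as np
import pandas as pd
import pytest

from evoreg.crossspecies import (
    DEFAULT_STAGE_PAIRS,
    StagePair,
    StagePairTable,
    breakpoint_shift,
    delta_z,
    dnds_contrast,
    module_enrichment,
    stage_zscores,
)


# ---------------------------------------------------------------------------
# stage Z-scores
# ---------------------------------------------------------------------------


def test_zscores_rows_standardised():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(5, 2, (20, 8)))
    z, excluded = stage_zscores(m)
    assert len(excluded) == 0
    np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


def test_zscores_monotone_preserved():
    m = pd.DataFrame([[1.0, 2, 4, 8, 16]])
    z, _ = stage_zscores(m)
    assert (np.diff(z.iloc[0]) > 0).all()


def test_zscores_constant_row_excluded():
    m = pd.DataFrame([[1.0, 1, 1], [1, 2, 3]], index=["flat", "ok"])
    z, excluded = stage_zscores(m)
    assert list(excluded) == ["flat"]
    assert list(z.index) == ["ok"]


def test_zscores_require_three_stages():
    with pytest.raises(ValueError):
        stage_zscores(pd.DataFrame([[1.0, 2]]))


# ---------------------------------------------------------------------------
# delta Z
# ---------------------------------------------------------------------------


def _identity_pairs(stages):
    return StagePairTable([StagePair(0.3 + 0.1 * i, 0.3 + 0.1 * i, s, s)
                           for i, s in enumerate(stages)])


def test_delta_z_identical_matrices_zero():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(0, 1, (50, 5)),
                     index=[f"g{i}" for i in range(50)],
                     columns=[f"s{i}" for i in range(5)])
    z, _ = stage_zscores(m)
    pairs = _identity_pairs([f"s{i}" for i in range(3)])
    res = delta_z(z, z, pairs, gene_set=[f"g{i}" for i in range(10)])
    assert np.allclose(res.delta.to_numpy(), 0)
    assert res.p_value > 0.9


def test_delta_z_antisymmetric_under_species_swap():
    rng = np.random.default_rng(2)
    h = pd.DataFrame(rng.normal(0, 1, (30, 5)),
                     index=[f"g{i}" for i in range(30)],
                     columns=[f"s{i}" for i in range(5)])
    m = pd.DataFrame(rng.normal(0, 1, (30, 5)), index=h.index, columns=h.columns)
    hz, _ = stage_zscores(h)
    mz, _ = stage_zscores(m)
    pairs = _identity_pairs(["s0", "s2", "s4"])
    fwd = delta_z(hz, mz, pairs, gene_set=[f"g{i}" for i in range(8)])
    rev = delta_z(mz, hz, pairs, gene_set=[f"g{i}" for i in range(8)])
    np.testing.assert_allclose(fwd.delta.to_numpy(), -rev.delta.to_numpy())
    assert fwd.set_mean == pytest.approx(-rev.set_mean)


def test_delta_z_missing_gene_excluded():
    rng = np.random.default_rng(3)
    h = pd.DataFrame(rng.normal(0, 1, (10, 4)),
                     index=[f"g{i}" for i in range(10)],
                     columns=list("abcd"))
    m = h.iloc[:8].copy()
    hz, _ = stage_zscores(h)
    mz, _ = stage_zscores(m)
    pairs = _identity_pairs(["a", "c"])
    res = delta_z(hz, mz, pairs, gene_set=["g0", "g1"])
    assert set(res.excluded_genes) == {"g8", "g9"}


def test_planted_delta_z_recovered(small_expression):
    expr = small_expression
    hz, _ = stage_zscores(expr.human_stages)
    mz, _ = stage_zscores(expr.macaque_stages)
    res = delta_z(hz, mz, DEFAULT_STAGE_PAIRS, expr.truth.dz_genes)
    shift = res.set_mean - res.background_mean
    # small fixture (150 of 800 genes): sampling error allows ~0.06;
    # the full-scale condition is checked in the acceptance suite
    assert abs(shift - expr.truth.dz_shift) < 0.06
    assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------


def test_breakpoint_null_behaviour():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(1000)]
    table = pd.Series(rng.normal(0, 0.1, 1000), index=genes)
    ps = []
    for k in range(40):
        sel = rng.choice(1000, 100, replace=False)
        gene_set = [genes[i] for i in sel]
        bg = [g for g in genes if g not in set(gene_set)]
        ps.append(breakpoint_shift(table, gene_set, bg)["p_value"])
    # null p-values roughly uniform: no pile-up below 0.05
    assert 0 <= np.mean(np.array(ps) < 0.05) <= 0.15


def test_breakpoint_planted_shift_detected(small_expression):
    expr = small_expression
    bg = [g for g in expr.ortholog_ids if g not in set(expr.truth.bp_genes)]
    res = breakpoint_shift(expr.breakpoints, expr.truth.bp_genes, bg)
    assert res["p_value"] < 0.01
    assert res["median_difference"] < 0
    assert res["direction"] == "earlier_in_human"


def test_breakpoint_overlapping_background_rejected():
    table = pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
    with pytest.raises(ValueError, match="disjoint"):
        breakpoint_shift(table, [f"g{i}" for i in range(10)],
                         [f"g{i}" for i in range(5, 20)])


# ---------------------------------------------------------------------------
# dN/dS
# ---------------------------------------------------------------------------


def test_dnds_log2_values():
    df = pd.DataFrame(
        {"gene": ["a", "b", "c"], "dN": [0.2, 0.1, 0.0], "dS": [0.2, 0.2, 0.1],
         "species_pair": "macaque"}
    )
    res = dnds_contrast(df, ["a"], ["b"], species_pair="macaque")
    assert res["median_set_log2"] == pytest.approx(0.0)  # dN = dS
    assert res["median_background_log2"] == pytest.approx(-1.0)  # ratio 0.5


def test_dnds_scale_invariance():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(200)]
    ds = rng.uniform(0.05, 0.5, 200)
    dn = ds * rng.uniform(0.1, 1.5, 200)
    df = pd.DataFrame({"gene": genes, "dN": dn, "dS": ds, "species_pair": "mouse"})
    df2 = df.assign(dN=df.dN * 7.3, dS=df.dS * 7.3)
    a = dnds_contrast(df, genes[:50], genes[50:])
    b = dnds_contrast(df2, genes[:50], genes[50:])
    assert a["p_value"] == pytest.approx(b["p_value"])
    assert a["median_set_log2"] == pytest.approx(b["median_set_log2"])


def test_dnds_planted_purifying_set(small_expression):
    expr = small_expression
    bg = [g for g in expr.ortholog_ids if g not in set(expr.truth.dnds_genes)]
    res = dnds_contrast(expr.dnds, expr.truth.dnds_genes, bg, species_pair="mouse")
    assert res["median_set_log2"] < res["median_background_log2"]
    assert res["purifying_selection"]
    assert res["p_value"] < 0.01


def test_dnds_ds_zero_excluded():
    df = pd.DataFrame(
        {"gene": ["a", "b", "c", "d"], "dN": [0.1] * 4,
         "dS": [0.2, 0.0, 0.2, 0.2], "species_pair": "mouse"}
    )
    res = dnds_contrast(df, ["a"], ["c", "d"])
    assert res["n_excluded_ds_zero"] == 1


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def test_module_set_equals_module_maximal():
    genes = [f"g{i}" for i in range(100)]
    membership = pd.Series(["M1"] * 20 + ["M2"] * 80, index=genes)
    res = module_enrichment(genes[:20], membership, genes)
    top = res.iloc[0]
    assert top["module"] == "M1"
    assert np.isinf(top["odds_ratio"])
    assert top["p_value"] < 1e-10


def test_module_no_overlap_or_zero():
    genes = [f"g{i}" for i in range(100)]
    membership = pd.Series(["M1"] * 20 + ["M2"] * 80, index=genes)
    res = module_enrichment(genes[20:40], membership, genes)
    m1 = res[res["module"] == "M1"].iloc[0]
    assert m1["odds_ratio"] == 0.0


def test_planted_module_ranks_first(small_expression):
    expr = small_expression
    res = module_enrichment(
        expr.truth.module_set_genes, expr.modules, expr.ortholog_ids
    )
    assert res.iloc[0]["module"] == expr.truth.module_id
    assert res.iloc[0]["q_value"] < 0.01
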