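"""Cross-species regulatory statistics.

Per-gene developmental stage Z-scores; the human-minus-macaque delta
expression Z-score at event-score-matched stages; breakpoint-shift and
dN/dS rank tests; and co-expression-module membership enrichment.

Developmental stages in the two species are aligned on an event score in
(0, 1); the default stage pairing matches human 0.46/0.54/0.76 (20 PCW,
26 PCW, 5 months after birth) to macaque 0.48/0.51/0.77.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import ContingencyTable, fisher_from_table, _woolf_ci

__all__ = [
    "StagePairTable",
    "DEFAULT_STAGE_PAIRS",
    "DeltaZResult",
    "stage_zscores",
    "delta_z",
    "breakpoint_shift",
    "dnds_contrast",
    "module_enrichment",
]


@dataclass(frozen=True)
class StagePair:
    human_score: float
    macaque_score: float
    human_stage: str
    macaque_stage: str

    def __post_init__(self) -> None:
        for s in (self.human_score, self.macaque_score):
            if not (0 < s < 1):
                raise ValueError("event scores must lie in (0, 1)")


@dataclass
class StagePairTable:
    pairs: list[StagePair]

    def __post_init__(self) -> None:
        keys = [(p.human_stage, p.macaque_stage) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate stage pairs")

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    @classmethod
    def read_tsv(cls, path) -> "StagePairTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                StagePair(
                    float(r.human_score), float(r.macaque_score),
                    str(r.human_stage), str(r.macaque_stage),
                )
                for r in df.itertuples(index=False)
            ]
        )


# the event-score-matched stages used for the prenatal / early-postnatal
# window (20 PCW - 5 months after birth)
DEFAULT_STAGE_PAIRS = StagePairTable(
    [
        StagePair(0.46, 0.48, "0.46", "0.48"),
        StagePair(0.54, 0.51, "0.54", "0.51"),
        StagePair(0.76, 0.77, "0.76", "0.77"),
    ]
)


def stage_zscores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-gene Z-score across developmental stages (row-wise scale()).

    Returns (Z, excluded): rows with zero across-stage variance are dropped
    from Z and reported in ``excluded``.  Requires >= 3 stages.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 stages")
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    z = matrix.loc[~constant].sub(matrix.loc[~constant].mean(axis=1), axis=0)
    z = z.div(sd[~constant], axis=0)
    return z, matrix.index[constant]


@dataclass
class DeltaZResult:
    """Per-gene delta expression Z at matched stages plus a gene-set test."""

    delta: pd.DataFrame  # genes x matched pairs, Z_human - Z_macaque
    set_mean: float
    background_mean: float
    t_statistic: float
    p_value: float
    n_set: int
    n_background: int
    excluded_genes: list[str] = field(default_factory=list)


def delta_z(
    human_z: pd.DataFrame,
    macaque_z: pd.DataFrame,
    pairs: StagePairTable,
    gene_set: Sequence[str],
    background: Sequence[str] | None = None,
) -> DeltaZResult:
    """Human-minus-macaque stage-matched expression Z-score contrast.

    delta(gene, pair) = Z_human(gene, human stage) - Z_macaque(gene, macaque
    stage).  A positive delta means the gene is more stage-enriched in human.
    The gene-set test is a two-sided two-sample t-test of the pooled gene-set
    deltas against the pooled background (non-set) deltas over the matched
    pairs.  Genes missing in either species are excluded and counted.
    """
    if len(pairs) == 0:
        raise ValueError("no matched stage pairs")
    shared = human_z.index.intersection(macaque_z.index)
    universe = (
        pd.Index(background) if background is not None else
        human_z.index.union(macaque_z.index)
    )
    excluded = [g for g in universe if g not in shared]
    genes = [g for g in universe if g in shared]
    cols = {}
    for p in pairs:
        if p.human_stage not in human_z.columns or p.macaque_stage not in macaque_z.columns:
            raise KeyError(f"stage pair {p.human_stage}/{p.macaque_stage} not in matrices")
        cols[f"{p.human_stage}|{p.macaque_stage}"] = (
            human_z.loc[genes, p.human_stage].to_numpy()
            - macaque_z.loc[genes, p.macaque_stage].to_numpy()
        )
    delta = pd.DataFrame(cols, index=genes)
    in_set = delta.index.isin(set(gene_set))
    set_vals = delta.loc[in_set].to_numpy().ravel()
    bg_vals = delta.loc[~in_set].to_numpy().ravel()
    set_vals = set_vals[np.isfinite(set_vals)]
    bg_vals = bg_vals[np.isfinite(bg_vals)]
    if len(set_vals) == 0 or len(bg_vals) == 0:
        raise ValueError("gene set or background empty after filtering")
    if set_vals.std() == 0 and bg_vals.std() == 0:
        # degenerate: both groups constant (e.g. identical atlases)
        t, p = 0.0, 1.0 if set_vals.mean() == bg_vals.mean() else 0.0
    else:
        t, p = stats.ttest_ind(set_vals, bg_vals, equal_var=False)
    return DeltaZResult(
        delta=delta,
        set_mean=float(set_vals.mean()),
        background_mean=float(bg_vals.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_set=int(in_set.sum()),
        n_background=int((~in_set).sum()),
        excluded_genes=excluded,
    )


def breakpoint_shift(
    table: pd.Series | Mapping[str, float],
    gene_set: Sequence[str],
    background: Sequence[str],
) -> dict:
    """Two-sided Wilcoxon rank-sum test on breakpoint differences.

    ``table`` maps gene -> delta breakpoint (human - rhesus, event-score
    units; negative = earlier in human).  ``background`` must be disjoint
    from ``gene_set``.  Reports the median difference and the direction
    implied by the sign convention.
    """
    table = pd.Series(table)
    set_genes = [g for g in gene_set if g in table.index]
    bg_genes = [g for g in background if g in table.index]
    if set(set_genes) & set(bg_genes):
        raise ValueError("background overlaps gene_set; disjointify first")
    if len(set_genes) < 5 or len(bg_genes) < 5:
        raise ValueError("both groups need >= 5 genes")
    x = table.loc[set_genes].to_numpy()
    y = table.loc[bg_genes].to_numpy()
    res = stats.ranksums(x, y)
    med_diff = float(np.median(x) - np.median(y))
    direction = "earlier_in_human" if med_diff < 0 else "later_in_human"
    return {
        "median_set": float(np.median(x)),
        "median_background": float(np.median(y)),
        "median_difference": med_diff,
        "direction": direction,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_set": len(set_genes),
        "n_background": len(bg_genes),
    }


def dnds_contrast(
    records: pd.DataFrame,
    gene_set: Sequence[str],
    background: Sequence[str],
    species_pair: str | None = None,
) -> dict:
    """log2(dN/dS) contrast of a gene set against background genes.

    ``records`` has columns gene, dN, dS, species_pair.  Rows with dS = 0 are
    excluded and counted.  A gene-set median log2(dN/dS) below 0 is reported
    as purifying selection.  Rank-sum test, two-sided.
    """
    df = records.copy()
    if species_pair is not None:
        df = df[df["species_pair"] == species_pair]
    n_excluded = int((df["dS"] <= 0).sum())
    df = df[df["dS"] > 0]
    if (df["dN"] < 0).any():
        raise ValueError("negative dN")
    ratio = pd.Series(
        np.log2(df["dN"].to_numpy() / df["dS"].to_numpy()), index=df["gene"].to_numpy()
    )
    set_vals = ratio.loc[ratio.index.isin(set(gene_set))].to_numpy()
    bg_vals = ratio.loc[ratio.index.isin(set(background))].to_numpy()
    set_vals = set_vals[np.isfinite(set_vals)]
    bg_vals = bg_vals[np.isfinite(bg_vals)]
    res = stats.ranksums(set_vals, bg_vals)
    med = float(np.median(set_vals))
    return {
        "median_set_log2": med,
        "median_background_log2": float(np.median(bg_vals)),
        "purifying_selection": med < 0,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_excluded_ds_zero": n_excluded,
        "n_set": len(set_vals),
        "n_background": len(bg_vals),
    }


def module_enrichment(
    gene_set: Sequence[str],
    module_membership: Mapping[str, str] | pd.Series,
    background: Sequence[str],
) -> pd.DataFrame:
    """Per-module 2x2 membership enrichment over an explicit background.

    Equivalent to covariate-free logistic regression of set membership on
    module membership (Fisher's exact test); BH correction across modules.
    Modules with no background member are skipped.
    """
    membership = pd.Series(module_membership)
    bg = pd.Index(background).unique()
    if not set(gene_set) <= set(bg):
        raise ValueError("background must contain the gene set")
    membership = membership.loc[membership.index.intersection(bg)]
    in_set = bg.isin(set(gene_set))
    rows = []
    for module in sorted(membership.unique()):
        in_mod = bg.isin(set(membership.index[membership == module]))
        A = int(np.sum(in_set & in_mod))
        B = int(np.sum(~in_set & in_mod))
        C = int(np.sum(in_set & ~in_mod))
        D = int(np.sum(~in_set & ~in_mod))
        table = ContingencyTable(A=A, B=B, C=C, D=D)
        _, p = stats.fisher_exact([[A, C], [B, D]], alternative="two-sided")
        lo, hi, flagged = _woolf_ci(A, B, C, D)
        rows.append(
            {
                "module": module, "A": A, "B": B, "C": C, "D": D,
                "odds_ratio": table.odds_ratio(),
                "ci_lo": lo, "ci_hi": hi,
                "p_value": float(p), "haldane": flagged,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["q_value"] = q
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out
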