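"""Developmental-trajectory and cell-type expression profiling.

Two centring conventions are implemented exactly as used downstream:

* bulk developmental samples: log2(x+1), then per-sample (column) centring
  with a +1 offset, so a gene at the sample mean sits at 1;
* single cells: per-cell centring without the offset, so each cell's mean
  over all genes is 0.

Group trajectories average the centred values over a gene set per sample;
class comparisons within a developmental period use one-way ANOVA with
post-hoc Tukey contrasts, FDR-adjusted across all contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StagedExpression",
    "CellExpression",
    "center_by_sample",
    "group_trajectory",
    "compare_trajectories",
    "celltype_profile",
]


@dataclass
class StagedExpression:
    """Gene x sample expression with per-sample stage metadata.

    ``metadata`` is indexed by sample id with columns ``stage`` (label),
    ``age`` (numeric), ``period`` ('prenatal' | 'postnatal').
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    species: str = "human"

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("stage", "period"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks column {col!r}")
        if self.metadata.loc[list(self.values.columns)].isna().any().any():
            raise ValueError("missing stage metadata")


@dataclass
class CellExpression:
    """Gene x cell expression with a cluster (cell type) label per cell."""

    values: pd.DataFrame
    clusters: pd.Series

    def __post_init__(self) -> None:
        unlabelled = set(self.values.columns) - set(self.clusters.index)
        if unlabelled:
            raise ValueError(f"cells without cluster label: {sorted(unlabelled)[:5]}")


def center_by_sample(
    values: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Per-sample centred expression, offset by +1.

    Optionally log2(x+1)-transforms first (requires non-negative input).
    After centring, each column's mean equals exactly 1.
    """
    if values.size == 0:
        raise ValueError("empty expression matrix")
    x = values.astype(float)
    if log_transform:
        if (x.to_numpy() < 0).any():
            raise ValueError("negative values under log transform")
        x = np.log2(x + 1)
    return x - x.mean(axis=0) + 1


def group_trajectory(
    centered: pd.DataFrame, gene_set: Sequence[str]
) -> pd.Series:
    """Per-sample mean centred expression over a gene set."""
    present = [g for g in gene_set if g in centered.index]
    if len(present) < 2:
        raise ValueError("fewer than 2 gene-set genes present in the matrix")
    return centered.loc[present].mean(axis=0)


def compare_trajectories(
    centered: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    metadata: pd.DataFrame,
    periods: Sequence[str] = ("prenatal", "postnatal"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare element-class trajectories within each developmental period.

    Returns (trajectories, contrasts): per-sample gene-set means for each
    class, and per-period one-way ANOVA with post-hoc Tukey pairwise
    contrasts, FDR-adjusted across all contrasts from all periods.
    """
    traj = pd.DataFrame(
        {name: group_trajectory(centered, genes) for name, genes in gene_sets.items()}
    )
    rows = []
    classes = list(gene_sets)
    for period in periods:
        samples = metadata.index[metadata["period"] == period]
        samples = [s for s in samples if s in traj.index]
        if len(samples) < 2:
            continue
        groups = [traj.loc[samples, c].to_numpy() for c in classes]
        f_stat, anova_p = stats.f_oneway(*groups)
        tk = stats.tukey_hsd(*groups)
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                rows.append(
                    {
                        "period": period,
                        "class_a": classes[i],
                        "class_b": classes[j],
                        "mean_a": groups[i].mean(),
                        "mean_b": groups[j].mean(),
                        "anova_F": f_stat,
                        "anova_p": anova_p,
                        "tukey_p": tk.pvalue[i, j],
                    }
                )
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        _, q, _, _ = multipletests(contrasts["tukey_p"].to_numpy(), method="fdr_bh")
        contrasts["tukey_q"] = q
    return traj, contrasts


def celltype_profile(
    cells: CellExpression, gene_set: Sequence[str]
) -> pd.Series:
    """Average cell-level centred expression of a gene set per cell type.

    Each cell is centred to its own mean over all genes (no offset); the
    gene-set mean per cell is then averaged within each cluster.  Empty
    clusters are excluded.
    """
    present = [g for g in gene_set if g in cells.values.index]
    if not present:
        raise ValueError("gene set absent from the matrix")
    centered = cells.values - cells.values.mean(axis=0)
    per_cell = centered.loc[present].mean(axis=0)
    labels = cells.clusters.loc[per_cell.index]
    return per_cell.groupby(labels).mean()
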