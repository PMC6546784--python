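"""Disease / constraint gene-set enrichment for element-associated genes.

Enrichment is a logistic regression of the element-associated ("target")
indicator on the curated-set indicator over an explicitly declared
background gene list, optionally adjusting for coding-sequence length (de
novo mutation rates scale with coding length, so exome-derived lists are
confounded with gene length).  Without the covariate the fitted OR equals
the sample 2x2 odds ratio, i.e. the test reduces to Fisher's exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .enrichment import EnrichmentResult
from .intervals import GeneModel, IntervalSet

__all__ = [
    "GeneSetAnnotation",
    "build_window_background",
    "logistic_enrichment",
    "correct_grid",
]


@dataclass
class GeneSetAnnotation:
    """Per-gene indicator vectors over a declared background.

    ``target``: element-associated gene flag; ``in_set``: curated-list
    member flag; ``covariate``: coding-sequence length (bp), required only
    when fitting with the covariate.
    """

    genes: pd.Index
    target: np.ndarray
    in_set: np.ndarray
    covariate: np.ndarray | None = None

    @classmethod
    def build(
        cls,
        background: list[str],
        target_genes: set[str] | list[str],
        set_genes: set[str] | list[str],
        covariate: pd.Series | None = None,
    ) -> "GeneSetAnnotation":
        genes = pd.Index(background).unique()
        target = genes.isin(set(target_genes)).astype(float)
        in_set = genes.isin(set(set_genes)).astype(float)
        cov = None
        if covariate is not None:
            cov = covariate.reindex(genes).fillna(0.0).to_numpy(dtype=float)
            if (cov < 0).any():
                raise ValueError("negative covariate values")
        return cls(genes=genes, target=np.asarray(target), in_set=np.asarray(in_set), covariate=cov)


def build_window_background(
    elements: IntervalSet,
    genes: list[GeneModel],
    window: int = 1_000_000,
) -> list[str]:
    """Genes whose body lies within ``window`` bp of any element.

    A gene qualifies when its body overlaps [element start - window,
    element end + window) for at least one element; the result is
    deduplicated and sorted.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        m = elements.chroms == chrom
        if not m.any():
            continue
        starts = elements.starts[m] - window
        ends = elements.ends[m] + window
        g_starts = np.array([g.start for g in glist])
        g_ends = np.array([g.end for g in glist])
        for s, e in zip(starts, ends):
            hit = (g_starts < e) & (g_ends > s)
            out.update(glist[i].gene_id for i in np.flatnonzero(hit))
    return sorted(out)


def logistic_enrichment(
    annotation: GeneSetAnnotation, use_covariate: bool = False
) -> EnrichmentResult:
    """Logistic regression of target membership on set membership.

    Model: target ~ set (+ log-transformed covariate).  OR is the
    exponentiated set coefficient with a Wald two-sided p-value and 95% CI.
    Complete separation yields a flagged result with an infinite OR rather
    than silent output.
    """
    y = annotation.target
    if len(y) < 50:
        raise ValueError("background must contain at least 50 genes")
    x_set = annotation.in_set
    for v, label in ((y, "target"), (x_set, "set")):
        if len(np.unique(v)) < 2:
            raise ValueError(f"{label} flag does not vary over the background")
    cols = [np.ones_like(y), x_set]
    if use_covariate:
        if annotation.covariate is None:
            raise ValueError("no covariate available")
        cov = np.log1p(annotation.covariate)  # log for numerical stability
        if np.ptp(cov) > 0:
            cols.append(cov)
    X = np.column_stack(cols)

    # detect complete separation of the set flag before fitting
    if y[x_set == 1].min() == 1 or y[x_set == 1].max() == 0:
        warnings.warn("complete separation on the set flag", stacklevel=2)
        or_inf = math.inf if y[x_set == 1].min() == 1 else 0.0
        return EnrichmentResult(
            method="logistic", odds_ratio=or_inf, ci95=(math.nan, math.nan),
            p_value=math.nan, flagged=True,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        warnings.warn("logistic fit failed (separation)", stacklevel=2)
        return EnrichmentResult(
            method="logistic", odds_ratio=math.inf, p_value=math.nan, flagged=True
        )
    beta = fit.params[1]
    se = fit.bse[1]
    return EnrichmentResult(
        method="logistic",
        odds_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.959963984540054 * se)),
              float(np.exp(beta + 1.959963984540054 * se))),
        p_value=float(fit.pvalues[1]),
    )


def correct_grid(
    grid: pd.DataFrame, method: str = "fdr_bh"
) -> pd.DataFrame:
    """Multiple-testing correction over the (element class) x (gene set) grid.

    ``grid`` must contain a ``p_value`` column with one row per tested cell;
    untested cells are rows with NaN p and are left NaN.  The adjustment
    family is all non-null cells; its size is recorded in ``family_size``.
    """
    out = grid.copy()
    tested = out["p_value"].notna().to_numpy()
    out["q_value"] = np.nan
    if tested.any():
        _, q, _, _ = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method=method
        )
        out.loc[tested, "q_value"] = q
    out.attrs["family_size"] = int(tested.sum())
    out.attrs["method"] = method
    out["family_size"] = int(tested.sum())
    return out
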