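"""Enrichment of element sets in regulatory annotations.

Three complementary statistics, all counting an element as "overlapping" an
annotation when they share at least 1 bp:

* :func:`binomial_enrichment` — region-based binomial tail: under the null,
  each element hits the annotation with probability p = annotation span /
  genome length; significance is Pr(k >= s | n, p).
* :func:`fisher_conserved` — 2x2 Fisher's exact test of elements vs a
  matched background region set (e.g. conserved regions), OR = AD/BC with a
  Woolf log-OR 95% CI (Haldane +0.5 for zero cells).
* :func:`permutation_or` — empirical null of odds ratios over matched
  control sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import IntervalSet, overlap_any

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ORDistribution",
    "DegenerateTableError",
    "binomial_enrichment",
    "fisher_conserved",
    "permutation_or",
]


class DegenerateTableError(ValueError):
    """A contingency-table margin is zero; the odds ratio is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for the elements-vs-background overlap table.

    A: elements overlapping the annotation; C: elements not overlapping;
    B: background regions overlapping; D: background regions not overlapping.
    """

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("negative cell count")

    def margins(self) -> tuple[int, int, int, int]:
        return self.A + self.C, self.B + self.D, self.A + self.B, self.C + self.D

    def odds_ratio(self) -> float:
        if self.B * self.C == 0:
            return math.inf if self.A * self.D > 0 else (0.0 if self.A == 0 or self.D == 0 else math.nan)
        return (self.A * self.D) / (self.B * self.C)


@dataclass
class EnrichmentResult:
    method: str
    odds_ratio: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)
    p_value: float = math.nan
    fold_enrichment: float = math.nan
    table: ContingencyTable | None = None
    n: int | None = None
    s: int | None = None
    p_genome: float | None = None
    flagged: bool = False


@dataclass
class ORDistribution:
    null_ors: np.ndarray
    observed: float
    empirical_p: float
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        assert self.empirical_p >= 1.0 / (len(self.null_ors) + self.n_degenerate + 1)


def binomial_enrichment(
    elements: IntervalSet, annotation: IntervalSet, genome_length: int
) -> EnrichmentResult:
    """Region-based binomial enrichment of elements in an annotation.

    p = merged annotation span / genome length; n = number of elements;
    s = elements overlapping by >= 1 bp; p_value = Pr(k >= s | n, p);
    fold enrichment = (s/n) / p.
    """
    n = len(elements)
    if n == 0:
        raise ValueError("empty element set")
    span = annotation.total_span()
    if genome_length < span:
        raise ValueError("genome_length smaller than annotation span")
    p = span / genome_length
    s = int(overlap_any(elements, annotation).sum())
    # upper tail Pr(k >= s); survival function is Pr(k > s-1)
    p_value = float(stats.binom.sf(s - 1, n, p)) if s > 0 else 1.0
    fold = (s / n) / p if p > 0 else math.nan
    return EnrichmentResult(
        method="binomial",
        p_value=p_value,
        fold_enrichment=fold,
        n=n,
        s=s,
        p_genome=p,
    )


def _woolf_ci(
    A: int, B: int, C: int, D: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Woolf normal-approximation CI on log OR; Haldane +0.5 on zero cells."""
    flagged = False
    a, b, c, d = float(A), float(B), float(C), float(D)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flagged = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se), flagged


def fisher_from_table(table: ContingencyTable) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a prepared 2x2 table."""
    r1, r2, c1, c2 = table.margins()
    for margin, label in ((r1, "element row"), (r2, "background row"),
                          (c1, "overlap column"), (c2, "non-overlap column")):
        if margin == 0:
            raise DegenerateTableError(f"zero margin: {label}")
    _, p = stats.fisher_exact(
        [[table.A, table.C], [table.B, table.D]], alternative="two-sided"
    )
    lo, hi, flagged = _woolf_ci(table.A, table.B, table.C, table.D)
    return EnrichmentResult(
        method="fisher",
        odds_ratio=table.odds_ratio(),
        ci95=(lo, hi),
        p_value=float(p),
        table=table,
        flagged=flagged,
    )


def build_table(
    elements: IntervalSet, annotation: IntervalSet, background: IntervalSet
) -> ContingencyTable:
    a_hit = int(overlap_any(elements, annotation).sum())
    b_hit = int(overlap_any(background, annotation).sum())
    return ContingencyTable(
        A=a_hit, B=b_hit, C=len(elements) - a_hit, D=len(background) - b_hit
    )


def fisher_conserved(
    elements: IntervalSet, annotation: IntervalSet, background: IntervalSet
) -> EnrichmentResult:
    """Fisher's exact test of elements vs matched background regions."""
    if len(background) == 0:
        raise ValueError("background region set is empty")
    return fisher_from_table(build_table(elements, annotation, background))


def permutation_or(
    elements: IntervalSet,
    annotation: IntervalSet,
    matched_sets: list[IntervalSet],
    background: IntervalSet,
) -> ORDistribution:
    """Empirical OR null from matched control sets.

    For each control set the same contingency construction as
    :func:`fisher_conserved` is applied with the set substituted for the
    elements.  Degenerate null tables are skipped and counted.  The empirical
    p is (1 + #{null OR >= observed}) / (n_valid + 1).
    """
    if len(matched_sets) < 100:
        raise ValueError("need at least 100 matched sets")
    observed = fisher_conserved(elements, annotation, background).odds_ratio
    b_hit = int(overlap_any(background, annotation).sum())
    b_tot = len(background)
    null = []
    n_degen = 0
    for ms in matched_sets:
        a_hit = int(overlap_any(ms, annotation).sum())
        table = ContingencyTable(
            A=a_hit, B=b_hit, C=len(ms) - a_hit, D=b_tot - b_hit
        )
        if 0 in table.margins():
            n_degen += 1
            continue
        null.append(table.odds_ratio())
    null_arr = np.array(null, dtype=float)
    emp_p = (1 + int(np.sum(null_arr >= observed))) / (len(null_arr) + 1)
    return ORDistribution(
        null_ors=null_arr,
        observed=observed,
        empirical_p=float(emp_p),
        n_degenerate=n_degen,
    )
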