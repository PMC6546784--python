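"""Genomic interval arithmetic, BED/GTF-subset I/O, and element classification.

All coordinates are 0-based half-open ([start, end)), the BED native
convention; GTF coordinates are converted on read (start − 1).  An
:class:`IntervalSet` is a thin columnar container (numpy arrays) kept sorted
by (chrom, start) so that overlap queries can use a sweep.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "ElementCategory",
    "CODING_CATEGORIES",
    "read_intervals",
    "write_intervals",
    "read_chrom_sizes",
    "read_gene_models",
    "write_gene_models",
    "promoter_regions",
    "downstream_regions",
    "classify_element",
    "classify_elements",
    "overlap_pairs",
    "overlap_any",
]


class BedParseError(ValueError):
    """Raised for malformed BED input (carries the offending line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Sorted columnar set of genomic intervals.

    Parameters
    ----------
    chroms, starts, ends : array-like
        Parallel columns; validated (0 <= start < end) and sorted by
        (chrom, start, end) on construction.
    names : array-like of str, optional
        Optional labels, carried through sorting.
    """

    def __init__(self, chroms, starts, ends, names=None):
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("column lengths differ")
        if np.any(starts < 0) or np.any(starts >= ends):
            bad = int(np.flatnonzero((starts < 0) | (starts >= ends))[0])
            raise ValueError(
                f"invalid interval at row {bad}: "
                f"{chroms[bad]}:[{starts[bad]},{ends[bad]})"
            )
        if names is not None:
            names = np.asarray(names, dtype=object)
            if len(names) != len(chroms):
                raise ValueError("names length differs")
        order = np.lexsort((ends, starts, chroms.astype(str)))
        self.chroms = chroms[order]
        self.starts = starts[order]
        self.ends = ends[order]
        self.names = names[order] if names is not None else None
        self._order = order  # original-row -> sorted-row permutation source

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        rows = list(records)
        if not rows:
            return cls([], [], [])
        has_name = len(rows[0]) > 3
        return cls(
            [r[0] for r in rows],
            [r[1] for r in rows],
            [r[2] for r in rows],
            [r[3] for r in rows] if has_name else None,
        )

    @classmethod
    def from_intervals(cls, ivs: Iterable[GenomicInterval]) -> "IntervalSet":
        ivs = list(ivs)
        names = [iv.name for iv in ivs]
        use_names = any(n is not None for n in names)
        return cls(
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            names if use_names else None,
        )

    # -- basics ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            str(self.chroms[i]),
            int(self.starts[i]),
            int(self.ends[i]),
            None if self.names is None else self.names[i],
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        same = (
            np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )
        if not same:
            return False
        if (self.names is None) != (other.names is None):
            return False
        return self.names is None or np.array_equal(self.names, other.names)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def total_span(self) -> int:
        """Total covered base pairs after merging overlaps."""
        total = 0
        for chrom in np.unique(self.chroms.astype(str)):
            m = self.chroms == chrom
            s, e = self.starts[m], self.ends[m]
            cur_s, cur_e = None, None
            for a, b in zip(s, e):
                if cur_e is None or a > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = a, b
                else:
                    cur_e = max(cur_e, b)
            if cur_e is not None:
                total += cur_e - cur_s
        return int(total)

    def subset(self, idx) -> "IntervalSet":
        idx = np.asarray(idx)
        return IntervalSet(
            self.chroms[idx],
            self.starts[idx],
            self.ends[idx],
            None if self.names is None else self.names[idx],
        )

    def validate_against(self, chrom_sizes: Mapping[str, int]) -> None:
        """Check every interval fits within its chromosome."""
        for chrom in np.unique(self.chroms.astype(str)):
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            m = self.chroms == chrom
            if int(self.ends[m].max()) > chrom_sizes[chrom]:
                raise ValueError(f"interval exceeds length of {chrom}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3/BED4 file into a sorted, validated :class:`IntervalSet`.

    Raises :class:`BedParseError` naming the 1-based line number for malformed
    lines or inverted coordinates.
    """
    chroms, starts, ends, names = [], [], [], []
    any_name = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            if not (0 <= s < e):
                raise BedParseError(
                    f"line {lineno}: invalid coordinates [{s},{e})"
                )
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            if len(parts) > 3 and parts[3] != "":
                names.append(parts[3])
                any_name = True
            else:
                names.append(None)
    return IntervalSet(chroms, starts, ends, names if any_name else None)


def write_intervals(ivs: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(ivs)):
            row = [str(ivs.chroms[i]), str(ivs.starts[i]), str(ivs.ends[i])]
            if ivs.names is not None:
                row.append("." if ivs.names[i] is None else str(ivs.names[i]))
            fh.write("\t".join(row) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One representative transcript per gene (5'-most TSS).

    ``tss``/``tes`` are strand-aware: the TSS is the 5' end with respect to
    strand, so for a '-' strand gene ``tss > tes``.  Exons are stored as
    half-open (start, end) tuples, sorted and non-overlapping.  ``cds_length``
    carries the coding-sequence-length covariate used by the gene-set
    enrichment model.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds_length < 0:
            raise ValueError(f"{self.gene_id}: negative cds_length")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def cds_exons(self) -> list[tuple[int, int]]:
        """Exonic intervals minus UTRs (the coding portions)."""
        cuts = sorted(self.utr5 + self.utr3)
        out = []
        for s, e in self.exons:
            pieces = [(s, e)]
            for cs, ce in cuts:
                nxt = []
                for ps, pe in pieces:
                    if ce <= ps or cs >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < cs:
                        nxt.append((ps, cs))
                    if ce < pe:
                        nxt.append((ce, pe))
                pieces = nxt
            out.extend(pieces)
        return sorted(out)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF subset (gene/exon/CDS/UTR feature lines).

    Only the ``gene_id`` attribute is parsed.  1-based GTF starts are
    converted to 0-based half-open.  The transcript structure is taken as the
    union of exon lines per gene (one representative model per gene).
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feat, start, end, _, strand, _, attrs = f[:9]
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                continue
            gid = m.group(1)
            rec = genes.setdefault(
                gid,
                {"chrom": chrom, "strand": strand, "exons": [],
                 "utr5": [], "utr3": [], "cds": 0,
                 "span": [int(start) - 1, int(end)]},
            )
            s, e = int(start) - 1, int(end)
            rec["span"][0] = min(rec["span"][0], s)
            rec["span"][1] = max(rec["span"][1], e)
            if feat == "exon":
                rec["exons"].append((s, e))
            elif feat == "CDS":
                rec["cds"] += e - s
            elif feat in ("five_prime_utr", "5UTR"):
                rec["utr5"].append((s, e))
            elif feat in ("three_prime_utr", "3UTR"):
                rec["utr3"].append((s, e))
    out = []
    for gid, rec in genes.items():
        lo, hi = rec["span"]
        tss, tes = (lo, hi) if rec["strand"] == "+" else (hi, lo)
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss=tss,
                tes=tes,
                exons=sorted(set(rec["exons"])),
                utr5=sorted(set(rec["utr5"])),
                utr3=sorted(set(rec["utr3"])),
                cds_length=rec["cds"],
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a GTF subset round-trippable by read_gene_models."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            rows = [("gene", g.start, g.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            rows += [("five_prime_utr", s, e) for s, e in g.utr5]
            rows += [("three_prime_utr", s, e) for s, e in g.utr3]
            for feat, s, e in rows:
                fh.write(
                    f"{g.chrom}\tevoreg\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            if g.cds_length:
                # single synthetic CDS line carrying the total coding length
                fh.write(
                    f"{g.chrom}\tevoreg\tCDS\t{g.start + 1}\t{g.start + g.cds_length}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# promoters / flanks
# ---------------------------------------------------------------------------


def promoter_regions(
    genes: Sequence[GeneModel],
    upstream_bp: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Fixed windows immediately upstream of each TSS (strand-aware).

    For a '+' strand gene the promoter is [tss − upstream_bp, tss); for '-'
    strand [tss, tss + upstream_bp).  Windows are clipped to [0, chrom length).
    Interval names carry the gene_id.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    recs = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - upstream_bp, g.tss
        else:
            s, e = g.tss, g.tss + upstream_bp
        s = max(s, 0)
        if chrom_sizes is not None:
            e = min(e, chrom_sizes[g.chrom])
        if s < e:
            recs.append((g.chrom, s, e, g.gene_id))
    return IntervalSet.from_records(recs)


def downstream_regions(
    genes: Sequence[GeneModel],
    downstream_bp: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Fixed windows immediately 3' of each TES (strand-aware), clipped."""
    recs = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tes, g.tes + downstream_bp
        else:
            s, e = g.tes - downstream_bp, g.tes
        s = max(s, 0)
        if chrom_sizes is not None:
            e = min(e, chrom_sizes[g.chrom])
        if s < e:
            recs.append((g.chrom, s, e, g.gene_id))
    return IntervalSet.from_records(recs)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

# precedence order; an element overlapping several features takes the first
CATEGORY_PRECEDENCE = (
    "exon",
    "utr5",
    "utr3",
    "promoter1kb",
    "downstream1kb",
    "intron",
    "intergenic",
)
CODING_CATEGORIES = frozenset(
    {"exon", "utr5", "utr3", "promoter1kb", "downstream1kb"}
)


@dataclass(frozen=True)
class ElementCategory:
    category: str
    gene_ids: tuple[str, ...] = ()

    @property
    def coding(self) -> bool:
        return self.category in CODING_CATEGORIES


def _overlaps(s: int, e: int, ivs: Iterable[tuple[int, int]]) -> bool:
    return any(s < ie and e > is_ for is_, ie in ivs)


def classify_element(
    element: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_bp: int = 1000,
    downstream_bp: int = 1000,
) -> ElementCategory:
    """Assign an element to its highest-precedence gene-feature category.

    Precedence: exon > utr5 > utr3 > promoter1kb > downstream1kb > intron >
    intergenic.  "exon" means the coding portion of exons (exon minus UTRs).
    An element overlapping a feature of several genes owns all of them.
    """
    s, e = element.start, element.end
    hits: dict[str, list[str]] = {c: [] for c in CATEGORY_PRECEDENCE[:-1]}
    for g in genes:
        if g.chrom != element.chrom:
            continue
        lo = g.start - max(promoter_bp, downstream_bp)
        hi = g.end + max(promoter_bp, downstream_bp)
        if e <= lo or s >= hi:
            continue
        if _overlaps(s, e, g.cds_exons()):
            hits["exon"].append(g.gene_id)
        if _overlaps(s, e, g.utr5):
            hits["utr5"].append(g.gene_id)
        if _overlaps(s, e, g.utr3):
            hits["utr3"].append(g.gene_id)
        if g.strand == "+":
            prom = (max(g.tss - promoter_bp, 0), g.tss)
            down = (g.tes, g.tes + downstream_bp)
        else:
            prom = (g.tss, g.tss + promoter_bp)
            down = (max(g.tes - downstream_bp, 0), g.tes)
        if s < prom[1] and e > prom[0]:
            hits["promoter1kb"].append(g.gene_id)
        if s < down[1] and e > down[0]:
            hits["downstream1kb"].append(g.gene_id)
        if _overlaps(s, e, g.introns()):
            hits["intron"].append(g.gene_id)
    for cat in CATEGORY_PRECEDENCE[:-1]:
        if hits[cat]:
            return ElementCategory(cat, tuple(sorted(set(hits[cat]))))
    return ElementCategory("intergenic")


def classify_elements(
    elements: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_bp: int = 1000,
    downstream_bp: int = 1000,
) -> list[ElementCategory]:
    """Vector version of :func:`classify_element` (per-chromosome gene index)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for iv in elements:
        out.append(
            classify_element(
                iv, by_chrom.get(iv.chrom, []), promoter_bp, downstream_bp
            )
        )
    return out


# ---------------------------------------------------------------------------
# overlap primitive
# ---------------------------------------------------------------------------


def overlap_pairs(a: IntervalSet, b: IntervalSet) -> list[tuple[int, int, int]]:
    """All (a-index, b-index, overlap-length) pairs with >= 1 bp overlap.

    Indices refer to the sorted order of each set.  Sweep per chromosome:
    candidates for a query [s, e) are b-intervals with start < e (searchsorted)
    and running-max end > s (searchsorted on the cummax of ends).
    """
    out: list[tuple[int, int, int]] = []
    a_chroms = a.chroms.astype(str)
    b_chroms = b.chroms.astype(str)
    for chrom in np.intersect1d(np.unique(a_chroms), np.unique(b_chroms)):
        ai = np.flatnonzero(a_chroms == chrom)
        bi = np.flatnonzero(b_chroms == chrom)
        bs, be = b.starts[bi], b.ends[bi]
        cummax_end = np.maximum.accumulate(be)
        for idx in ai:
            s, e = a.starts[idx], a.ends[idx]
            hi = np.searchsorted(bs, e, side="left")
            lo = np.searchsorted(cummax_end[:hi], s, side="right")
            if lo >= hi:
                continue
            cand = np.arange(lo, hi)
            mask = be[cand] > s
            for j in cand[mask]:
                ov = min(e, be[j]) - max(s, bs[j])
                out.append((int(idx), int(bi[j]), int(ov)))
    return out


def overlap_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean mask over a's rows: does each interval overlap b at all?

    Vectorised per chromosome; used by the enrichment counting loops where
    only membership matters.
    """
    res = np.zeros(len(a), dtype=bool)
    a_chroms = a.chroms.astype(str)
    b_chroms = b.chroms.astype(str)
    for chrom in np.unique(a_chroms):
        bi = np.flatnonzero(b_chroms == chrom)
        if len(bi) == 0:
            continue
        ai = np.flatnonzero(a_chroms == chrom)
        bs, be = b.starts[bi], b.ends[bi]
        cummax_end = np.maximum.accumulate(be)
        hi = np.searchsorted(bs, a.ends[ai], side="left")
        # any b interval with index < hi whose end > start?
        lo = np.searchsorted(cummax_end, a.starts[ai], side="right")
        res[ai] = lo < hi
    return res
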