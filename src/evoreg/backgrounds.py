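"""Matched random-region backgrounds.

Two null constructions are provided:

* :func:`sample_gc_length_matched` — per-element same-chromosome controls with
  the same length and GC content within a tolerance (default < 5 percentage
  points).  These controls supply the background contact profiles behind the
  Weibull interaction null.
* :func:`sample_conservation_matched` — genome-wide control sets matched on
  length and mean conservation score, used for the permutation odds-ratio
  null of the regulatory-annotation enrichment.

Both use rejection sampling with a per-element seeded substream, so adding or
removing elements does not perturb other elements' draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conservation import ConservationTrack
from .genome import GenomeSequence
from .intervals import IntervalSet

__all__ = [
    "MatchedRegionSet",
    "sample_gc_length_matched",
    "sample_conservation_matched",
]


@dataclass
class MatchedRegionSet:
    """GC/length-matched controls for a set of source elements.

    ``controls[i]`` holds the draws for source element i in draw order.
    ``pooled`` is the deduplicated union (exact (chrom, start, end)
    duplicates removed); ``total_drawn`` counts draws before dedup.
    """

    source: IntervalSet
    controls: list[IntervalSet]
    total_drawn: int
    pooled: IntervalSet
    n_dedup: int
    unmatched: list[int] = field(default_factory=list)
    attempts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_dedup == len(self.pooled)


def _element_rng(seed: int, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return np.random.Generator(np.random.PCG64(ss))


def sample_gc_length_matched(
    elements: IntervalSet,
    genome: GenomeSequence,
    reps: int,
    gc_tol: float = 0.05,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> MatchedRegionSet:
    """Draw ``reps`` same-chromosome, same-length, GC-matched controls per element.

    Rejection sampling uniform over start positions; a control is accepted
    when |GC(control) − GC(source)| < gc_tol.  If an element exhausts
    ``max_attempts`` candidate draws per missing control, the nearest-GC
    candidates seen so far are used and the element is recorded in
    ``unmatched`` with a warning.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 < gc_tol < 1):
        raise ValueError("gc_tol must be in (0, 1)")
    lengths = genome.lengths
    controls: list[IntervalSet] = []
    unmatched: list[int] = []
    attempts_per_element: list[int] = []
    total = 0

    for i in range(len(elements)):
        chrom = str(elements.chroms[i])
        s, e = int(elements.starts[i]), int(elements.ends[i])
        length = e - s
        src_gc = genome.gc_content(chrom, s, e)
        max_start = lengths[chrom] - length
        if max_start < 0:
            raise ValueError(f"element longer than chromosome {chrom}")
        rng = _element_rng(seed, i)
        accepted: list[int] = []
        best: list[tuple[float, int]] = []  # (|dGC|, start) fallback pool
        attempts = 0
        budget = reps * max_attempts
        while len(accepted) < reps and attempts < budget:
            batch = min(max(4 * (reps - len(accepted)), 64), budget - attempts)
            starts = rng.integers(0, max_start + 1, size=batch)
            attempts += batch
            gcs = genome.gc_content_batch(chrom, starts, starts + length)
            diff = np.abs(gcs - src_gc)
            ok = np.flatnonzero(diff < gc_tol)
            for j in ok:
                accepted.append(int(starts[j]))
                if len(accepted) == reps:
                    break
            if len(accepted) < reps:
                finite = np.isfinite(diff)
                for j in np.flatnonzero(finite)[:8]:
                    best.append((float(diff[j]), int(starts[j])))
        if len(accepted) < reps:
            unmatched.append(i)
            best.sort()
            fill = [st for _, st in best[: reps - len(accepted)]]
            accepted.extend(fill)
            warnings.warn(
                f"element {i} ({chrom}:{s}-{e}): GC match exhausted after "
                f"{attempts} attempts; {len(fill)} nearest-GC controls used",
                stacklevel=2,
            )
        attempts_per_element.append(attempts)
        total += len(accepted)
        name = (
            elements.names[i]
            if elements.names is not None and elements.names[i] is not None
            else f"elem{i}"
        )
        controls.append(
            IntervalSet(
                [chrom] * len(accepted),
                accepted,
                [st + length for st in accepted],
                [name] * len(accepted),
            )
        )

    # pool + dedup on exact (chrom, start, end)
    seen: set[tuple[str, int, int]] = set()
    recs = []
    for cs in controls:
        for iv in cs:
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                recs.append((iv.chrom, iv.start, iv.end, iv.name))
    pooled = IntervalSet.from_records(recs)
    return MatchedRegionSet(
        source=elements,
        controls=controls,
        total_drawn=total,
        pooled=pooled,
        n_dedup=len(pooled),
        unmatched=unmatched,
        attempts=attempts_per_element,
    )


def sample_conservation_matched(
    elements: IntervalSet,
    track: ConservationTrack,
    n_sets: int,
    seed: int = 0,
    match_tol: float = 0.05,
    max_attempts: int = 200,
) -> list[IntervalSet]:
    """Draw ``n_sets`` genome-wide control sets matched on size and mean score.

    Each set contains one control per element with the same length and a mean
    conservation score within ``match_tol`` of the source's.  Placement is
    genome-wide (chromosome chosen with probability proportional to placeable
    length).  Elements that cannot be matched fall back to the nearest-score
    candidate with a warning.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    lengths = track.lengths
    chrom_names = list(lengths)
    warned = False

    # per element: proposal batches, accepted draws distributed to the sets
    per_element: list[tuple[np.ndarray, np.ndarray]] = []
    budget = max_attempts * n_sets
    chunk = min(max(budget // 4, 4096), 200_000)
    for i in range(len(elements)):
        L = int(elements.ends[i] - elements.starts[i])
        src_mean = track.mean_score(
            str(elements.chroms[i]), int(elements.starts[i]), int(elements.ends[i])
        )
        placeable = np.array([max(lengths[c] - L + 1, 0) for c in chrom_names], float)
        if placeable.sum() == 0:
            raise ValueError("element longer than every chromosome")
        p_chrom = placeable / placeable.sum()
        rng = _element_rng(seed, i)
        acc_chrom: list[np.ndarray] = []
        acc_start: list[np.ndarray] = []
        n_acc = 0
        proposed = 0
        best_diff, best_chrom, best_start = np.inf, 0, 0
        while n_acc < n_sets and proposed < budget:
            m = min(chunk, budget - proposed)
            proposed += m
            ci = rng.choice(len(chrom_names), size=m, p=p_chrom)
            starts = np.empty(m, dtype=np.int64)
            means = np.empty(m, dtype=np.float64)
            for k in np.unique(ci):
                sel = ci == k
                smax = lengths[chrom_names[k]] - L
                st = rng.integers(0, smax + 1, size=int(sel.sum()))
                starts[sel] = st
                means[sel] = track.mean_score_batch(chrom_names[k], st, st + L)
            diff = np.abs(means - src_mean)
            ok = diff <= match_tol
            acc_chrom.append(ci[ok])
            acc_start.append(starts[ok])
            n_acc += int(ok.sum())
            j = int(np.argmin(diff))
            if diff[j] < best_diff:
                best_diff, best_chrom, best_start = float(diff[j]), int(ci[j]), int(starts[j])
        out_chrom = np.concatenate(acc_chrom)[:n_sets] if acc_chrom else np.empty(0, np.int64)
        out_start = np.concatenate(acc_start)[:n_sets] if acc_start else np.empty(0, np.int64)
        if len(out_chrom) < n_sets:
            short = n_sets - len(out_chrom)
            out_chrom = np.concatenate((out_chrom, np.full(short, best_chrom)))
            out_start = np.concatenate((out_start, np.full(short, best_start)))
            if not warned:
                warnings.warn(
                    f"conservation matching: {short} draws for element {i} "
                    "fell back to the nearest-score candidate",
                    stacklevel=2,
                )
                warned = True
        per_element.append((out_chrom.astype(np.int64), out_start.astype(np.int64)))

    sets: list[IntervalSet] = []
    elem_lengths = elements.lengths
    for k in range(n_sets):
        recs = []
        for i, (ci, st) in enumerate(per_element):
            recs.append(
                (
                    chrom_names[int(ci[k])],
                    int(st[k]),
                    int(st[k]) + int(elem_lengths[i]),
                    f"set{k}_elem{i}",
                )
            )
        sets.append(IntervalSet.from_records(recs))
    return sets
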