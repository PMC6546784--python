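"""Run-length encoded per-base conservation track (phastCons-like scores).

Scores live in [0, 1]; coverage gaps are score 0.  The track supports O(1)
mean-score queries via a prefix integral, conserved-region calling by run
scanning, and bedGraph round-tripping.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .intervals import IntervalSet

__all__ = ["ConservationTrack", "call_conserved_regions"]


class ConservationTrack:
    """Piecewise-constant score per chromosome.

    Internally each chromosome holds breakpoints ``b`` (b[0]=0 < ... <
    b[k]=length) and values ``v`` on [b[i], b[i+1]).
    """

    def __init__(self, pieces: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._b: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._integral: dict[str, np.ndarray] = {}
        for chrom, (b, v) in pieces.items():
            b = np.asarray(b, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if len(b) != len(v) + 1:
                raise ValueError("breakpoints must be one longer than values")
            if np.any(np.diff(b) <= 0) or b[0] != 0:
                raise ValueError("breakpoints must start at 0 and increase")
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError("scores must lie in [0, 1]")
            self._b[chrom] = b
            self._v[chrom] = v
            self._integral[chrom] = np.concatenate(
                ([0.0], np.cumsum(v * np.diff(b)))
            )

    @classmethod
    def from_arrays(cls, scores: Mapping[str, np.ndarray]) -> "ConservationTrack":
        """Build from dense per-base score arrays (RLE-compressed on entry)."""
        pieces = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=np.float64)
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            b = np.concatenate(([0], change, [len(arr)]))
            v = arr[b[:-1]]
            pieces[chrom] = (b, v)
        return cls(pieces)

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, chrom_sizes: Mapping[str, int]
    ) -> "ConservationTrack":
        """Read a bedGraph; uncovered bases get score 0."""
        segs: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, val = line.split()[:4]
                if chrom not in segs:
                    raise ValueError(f"bedGraph chromosome {chrom!r} not in sizes")
                segs[chrom].append((int(s), int(e), float(val)))
        pieces = {}
        for chrom, rows in segs.items():
            rows.sort()
            b, v = [0], []
            pos = 0
            for s, e, val in rows:
                if s < pos:
                    raise ValueError(f"overlapping bedGraph rows on {chrom}")
                if s > pos:
                    b.append(s)
                    v.append(0.0)
                b.append(e)
                v.append(val)
                pos = e
            if pos < chrom_sizes[chrom]:
                b.append(chrom_sizes[chrom])
                v.append(0.0)
            pieces[chrom] = (np.array(b), np.array(v))
        return cls(pieces)

    # ------------------------------------------------------------------

    @property
    def lengths(self) -> dict[str, int]:
        return {c: int(b[-1]) for c, b in self._b.items()}

    def mean_score(self, chrom: str, start: int, end: int) -> float:
        return float(self.mean_score_batch(chrom, np.array([start]), np.array([end]))[0])

    def mean_score_batch(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Mean score of same-chromosome intervals via the prefix integral."""
        b, v, integ = self._b[chrom], self._v[chrom], self._integral[chrom]
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(starts < 0) or np.any(ends > b[-1]) or np.any(starts >= ends):
            raise ValueError("interval outside track bounds")

        def integral_at(pos: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(b, pos, side="right") - 1
            idx = np.clip(idx, 0, len(v) - 1)
            return integ[idx] + v[idx] * (pos - b[idx])

        return (integral_at(ends) - integral_at(starts)) / (ends - starts)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self._b:
                b, v = self._b[chrom], self._v[chrom]
                for i in range(len(v)):
                    if v[i] != 0.0:
                        fh.write(f"{chrom}\t{b[i]}\t{b[i + 1]}\t{v[i]:g}\n")

    def values(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._b[chrom], self._v[chrom]


def call_conserved_regions(
    track: ConservationTrack, min_len: int = 20, threshold: float = 0.40
) -> IntervalSet:
    """Maximal runs of bases with score > threshold, kept iff longer than min_len.

    Both comparisons are strict, matching the "larger than 20 bp with a score
    >0.40" convention.
    """
    recs = []
    for chrom in track.lengths:
        b, v = track.values(chrom)
        above = v > threshold
        i = 0
        while i < len(v):
            if above[i]:
                j = i
                while j + 1 < len(v) and above[j + 1]:
                    j += 1
                s, e = int(b[i]), int(b[j + 1])
                if e - s > min_len:
                    recs.append((chrom, s, e))
                i = j + 1
            else:
                i += 1
    return IntervalSet.from_records(recs)
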