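"""Named genomic interval sets (BED semantics: 0-based, half-open).

The container behind DMR lists, selective-sweep regions, feature
annotations and the mappable universe used by the permutation tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntervalSet:
    """A set of genomic intervals, optionally scored.

    Intervals are stored as parallel arrays (chrom, start, end[, score])
    and kept sorted by (chrom, start). ``start < end`` is enforced:
    zero-length intervals are meaningless under half-open coordinates.
    """

    name: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != len(self.starts):
                raise ValueError("scores length mismatch")
        if len(self.chroms) != len(self.starts) or len(self.starts) != len(self.ends):
            raise ValueError("chroms/starts/ends length mismatch")
        bad = np.nonzero(self.starts >= self.ends)[0]
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"interval {self.chroms[i]}:{self.starts[i]}-{self.ends[i]} "
                "has start >= end"
            )
        self._sort()

    def _sort(self) -> None:
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        self.chroms = self.chroms[order]
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        if self.scores is not None:
            self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self):
        for i in range(len(self)):
            yield (self.chroms[i], int(self.starts[i]), int(self.ends[i]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )

    @classmethod
    def from_tuples(cls, name: str, intervals, scores=None) -> "IntervalSet":
        intervals = list(intervals)
        chroms = np.array([t[0] for t in intervals], dtype=object)
        starts = np.array([t[1] for t in intervals], dtype=np.int64)
        ends = np.array([t[2] for t in intervals], dtype=np.int64)
        return cls(name, chroms, starts, ends,
                   None if scores is None else np.asarray(scores, float))

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def total_length(self) -> int:
        return int(self.merge().lengths().sum())

    def merge(self, *, keep_max_score: bool = False) -> "IntervalSet":
        """Union of overlapping or book-ended intervals.

        With ``keep_max_score`` each merged region carries the maximum
        score of its constituent intervals.
        """
        if len(self) == 0:
            return IntervalSet(self.name, [], [], [],
                               np.array([]) if keep_max_score else None)
        out_c, out_s, out_e, out_sc = [], [], [], []
        cur_c, cur_s, cur_e = self.chroms[0], self.starts[0], self.ends[0]
        cur_sc = self.scores[0] if self.scores is not None else np.nan
        for i in range(1, len(self)):
            c, s, e = self.chroms[i], self.starts[i], self.ends[i]
            sc = self.scores[i] if self.scores is not None else np.nan
            if c == cur_c and s <= cur_e:
                cur_e = max(cur_e, e)
                cur_sc = max(cur_sc, sc)
            else:
                out_c.append(cur_c); out_s.append(cur_s); out_e.append(cur_e)
                out_sc.append(cur_sc)
                cur_c, cur_s, cur_e, cur_sc = c, s, e, sc
        out_c.append(cur_c); out_s.append(cur_s); out_e.append(cur_e)
        out_sc.append(cur_sc)
        return IntervalSet(
            self.name, np.array(out_c, dtype=object),
            np.array(out_s), np.array(out_e),
            np.array(out_sc) if keep_max_score and self.scores is not None else None,
        )

    def overlaps_point_set(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per own interval: does it overlap >= 1 bp of ``other``?"""
        merged = other.merge()
        hits = np.zeros(len(self), dtype=bool)
        by_chrom: dict = {}
        for c in np.unique(merged.chroms.astype(str)):
            mask = merged.chroms.astype(str) == c
            by_chrom[c] = (merged.starts[mask], merged.ends[mask])
        for i in range(len(self)):
            c = str(self.chroms[i])
            if c not in by_chrom:
                continue
            ts, te = by_chrom[c]
            # first target whose end > our start
            j = np.searchsorted(te, self.starts[i], side="right")
            hits[i] = j < len(ts) and ts[j] < self.ends[i]
        return hits

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total overlap (bp) of [start, end) on chrom with this (merged) set."""
        merged = self.merge()
        mask = merged.chroms.astype(str) == str(chrom)
        ts, te = merged.starts[mask], merged.ends[mask]
        lo = np.minimum(np.maximum(ts, start), end)
        hi = np.maximum(np.minimum(te, end), start)
        return int(np.maximum(hi - lo, 0).sum())
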