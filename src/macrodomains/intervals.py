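"""Half-open genomic interval algebra (union, intersect, subtract, complement).

The workhorse behind domain merging and dynamics classification. Interval sets
are stored per chromosome as sorted, merged ``(N, 2)`` int64 arrays; abutting
intervals are always coalesced on construction so interval counts are well
defined. Semantics match BEDTools on 0-based half-open coordinates.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import InvalidParameterError, InvalidRecordError

__all__ = ["IntervalSet", "interval_ops"]


def _merge_array(arr: np.ndarray, gap: int = 0) -> np.ndarray:
    """Merge a sorted (N,2) array, coalescing intervals separated by <= gap."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


class IntervalSet:
    """A sorted, disjoint, merged set of genomic intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = (), *, _raw=None):
        if _raw is not None:
            self._by_chrom: dict[str, np.ndarray] = _raw
            return
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start < 0 or start >= end:
                raise InvalidRecordError(f"malformed interval {chrom}:{start}-{end}")
            by.setdefault(str(chrom), []).append((start, end))
        self._by_chrom = {
            c: _merge_array(np.array(sorted(v), dtype=np.int64).reshape(-1, 2))
            for c, v in by.items()
        }

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_arrays(cls, by_chrom: Mapping[str, np.ndarray]) -> "IntervalSet":
        raw = {}
        for c, arr in by_chrom.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            arr = arr[np.argsort(arr[:, 0], kind="stable")]
            raw[c] = _merge_array(arr)
        return cls(_raw={c: a for c, a in raw.items() if len(a)})

    # -- basic protocol -------------------------------------------------------
    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for c in sorted(self._by_chrom):
            for s, e in self._by_chrom[c]:
                yield (c, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp()} bp)"

    def chrom_array(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def total_bp(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._by_chrom.values())
        )

    def lengths(self) -> np.ndarray:
        """Lengths of all intervals, in iteration order."""
        if not self._by_chrom:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [self._by_chrom[c][:, 1] - self._by_chrom[c][:, 0] for c in sorted(self._by_chrom)]
        )

    # -- set algebra ----------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        raw = {}
        for c in set(self._by_chrom) | set(other._by_chrom):
            both = np.vstack([self.chrom_array(c), other.chrom_array(c)])
            both = both[np.argsort(both[:, 0], kind="stable")]
            raw[c] = _merge_array(both)
        return IntervalSet(_raw={c: a for c, a in raw.items() if len(a)})

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        raw = {}
        for c in set(self._by_chrom) & set(other._by_chrom):
            a, b = self.chrom_array(c), other.chrom_array(c)
            out, i, j = [], 0, 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                raw[c] = _merge_array(np.array(out, dtype=np.int64))
        return IntervalSet(_raw=raw)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        raw = {}
        for c, a in self._by_chrom.items():
            b = other.chrom_array(c)
            if len(b) == 0:
                raw[c] = a.copy()
                continue
            out = []
            for s, e in a:
                cur = s
                # b intervals overlapping [s, e)
                k = np.searchsorted(b[:, 1], cur, side="right")
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        out.append((cur, b[k, 0]))
                    cur = max(cur, b[k, 1])
                    k += 1
                if cur < e:
                    out.append((cur, e))
            if out:
                raw[c] = _merge_array(np.array(out, dtype=np.int64))
        return IntervalSet(_raw=raw)

    def complement(self, chrom_lengths: Mapping[str, int]) -> "IntervalSet":
        """Genome minus this set, over the given chromosome extents."""
        raw = {}
        for c, L in chrom_lengths.items():
            a = self.chrom_array(c)
            out, cur = [], 0
            for s, e in a:
                if s > cur:
                    out.append((cur, min(s, L)))
                cur = max(cur, e)
            if cur < L:
                out.append((cur, L))
            if out:
                raw[c] = np.array(out, dtype=np.int64)
        return IntervalSet(_raw=raw)

    def merge(self, gap: int = 0) -> "IntervalSet":
        """Re-merge, additionally closing gaps of <= ``gap`` bp."""
        if gap < 0:
            raise InvalidParameterError("gap must be >= 0")
        return IntervalSet(
            _raw={c: _merge_array(a, gap=gap) for c, a in self._by_chrom.items()}
        )

    def jaccard(self, other: "IntervalSet") -> float:
        """Base-pair Jaccard index |A∩B| / |A∪B| (1.0 for two empty sets)."""
        u = self.union(other).total_bp()
        if u == 0:
            return 1.0
        return self.intersect(other).total_bp() / u

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self (iteration order): overlaps other >= 1 bp."""
        flags = []
        for c in sorted(self._by_chrom):
            a = self._by_chrom[c]
            b = other.chrom_array(c)
            if len(b) == 0:
                flags.append(np.zeros(len(a), dtype=bool))
                continue
            # overlap iff some b with b.start < a.end and b.end > a.start
            k = np.searchsorted(b[:, 0], a[:, 1], side="left")  # first b.start >= a.end
            prev_end_max = np.maximum.accumulate(b[:, 1])
            has = (k > 0) & (prev_end_max[np.maximum(k - 1, 0)] > a[:, 0])
            flags.append(has)
        if not flags:
            return np.empty(0, dtype=bool)
        return np.concatenate(flags)


def interval_ops(
    a: Iterable[tuple[str, int, int]],
    b: Iterable[tuple[str, int, int]] | Mapping[str, int],
    op: str,
) -> list[tuple[str, int, int]]:
    """Functional entry point for the interval algebra.

    ``op`` is one of ``union``, ``intersect``, ``subtract``, ``complement``.
    For ``complement``, ``b`` is a chrom -> length mapping. Outputs are
    sorted, disjoint and merged.
    """
    A = a if isinstance(a, IntervalSet) else IntervalSet(a)
    if op == "complement":
        return list(A.complement(b))
    B = b if isinstance(b, IntervalSet) else IntervalSet(b)
    if op == "union":
        return list(A.union(B))
    if op == "intersect":
        return list(A.intersect(B))
    if op == "subtract":
        return list(A.subtract(B))
    raise InvalidParameterError(f"unknown interval op {op!r}")
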