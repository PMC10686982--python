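"""Genomic interval set algebra: union, subtraction, membership.

A :class:`RegionSet` holds per-chromosome sorted, disjoint intervals as
numpy arrays. Overlapping or bookended (endpoint-sharing) intervals are
merged on construction, so invariants hold by construction.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np

from regspot.io import Interval

__all__ = ["RegionSet", "union", "subtract"]


class RegionSet:
    """Sorted disjoint intervals per chromosome with fast overlap queries."""

    def __init__(self, intervals: Iterable[Interval] = (), label: str = "") -> None:
        self.label = label
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            merged: list[list[int]] = []
            for s, e in rows:
                if merged and s <= merged[-1][1]:  # bookended intervals merge too
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self) -> list[Interval]:
        out = []
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append(Interval(chrom, int(s), int(e)))
        return out

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._starts.get(chrom, empty), self._ends.get(chrom, empty)

    def total_bases(self) -> int:
        return int(
            sum((self._ends[c] - self._starts[c]).sum() for c in self._starts)
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def overlaps(self, interval: Interval) -> bool:
        """True iff >=1 base of ``interval`` lies in this set."""
        starts, ends = self.arrays(interval.chrom)
        if len(starts) == 0:
            return False
        # candidate: last region starting before interval.end
        idx = int(np.searchsorted(starts, interval.end, side="left")) - 1
        return idx >= 0 and int(ends[idx]) > interval.start

    def genome_fraction(self, genome_sizes: Mapping[str, int]) -> float:
        """Covered bases / total genome bases."""
        total = sum(genome_sizes.values())
        if total <= 0:
            raise ValueError("genome_sizes must be positive")
        for chrom in self._starts:
            if chrom not in genome_sizes:
                raise ValueError(f"region chromosome {chrom!r} not in genome_sizes")
            if int(self._ends[chrom][-1]) > genome_sizes[chrom]:
                raise ValueError(
                    f"region on {chrom} extends past chromosome length "
                    f"{genome_sizes[chrom]}"
                )
        return self.total_bases() / total


def union(*interval_lists: Iterable[Interval], label: str = "") -> RegionSet:
    """Minimal disjoint cover of all input intervals."""
    flat: list[Interval] = []
    for lst in interval_lists:
        flat.extend(lst)
    return RegionSet(flat, label=label)


def subtract(a: RegionSet, b: RegionSet, label: Optional[str] = None) -> RegionSet:
    """Bases in ``a`` and not in ``b``."""
    out: list[Interval] = []
    for chrom in a.chroms:
        a_starts, a_ends = a.arrays(chrom)
        b_starts, b_ends = b.arrays(chrom)
        j = 0
        for s, e in zip(a_starts.tolist(), a_ends.tolist()):
            cur = s
            while j < len(b_starts) and b_ends[j] <= cur:
                j += 1
            k = j
            while k < len(b_starts) and b_starts[k] < e:
                bs, be = int(b_starts[k]), int(b_ends[k])
                if bs > cur:
                    out.append(Interval(chrom, cur, min(bs, e)))
                cur = max(cur, be)
                if cur >= e:
                    break
                k += 1
            if cur < e:
                out.append(Interval(chrom, cur, e))
    return RegionSet(out, label=a.label if label is None else label)
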