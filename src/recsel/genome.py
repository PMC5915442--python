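"""Genome layout and interval primitives.

Coordinate conventions, used consistently throughout the package:

* variant positions are 1-based (VCF convention);
* all intervals are 0-based half-open ``[start, end)`` (BED convention).

The single conversion between the two lives in :func:`pos1_to_index`; every
membership test goes through it so the off-by-one exists in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np


def pos1_to_index(pos: int | np.ndarray) -> int | np.ndarray:
    """Convert a 1-based variant position to a 0-based coordinate."""
    return pos - 1


@dataclass(frozen=True)
class Arm:
    """A chromosome-arm interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos1(self, pos: int | np.ndarray):
        idx = pos1_to_index(pos)
        return (idx >= self.start) & (idx < self.end)


class GenomeLayout:
    """Ordered chromosomes with lengths, partitioned into analyzable arms.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length)`` pairs. Order defines the concatenated
        coordinate system used by the rotation permutation.
    arms:
        ``Arm`` intervals; within a chromosome they must be non-overlapping
        and lie inside ``[0, length)``.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]], arms: Iterable[Arm]):
        self.chromosomes: list[tuple[str, int]] = [(str(c), int(l)) for c, l in chromosomes]
        self.arms: list[Arm] = list(arms)
        self._lengths = dict(self.chromosomes)
        self._validate()

    def _validate(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.total_length <= 0:
            raise ValueError("total genome length must be positive")
        by_chrom: dict[str, list[Arm]] = {}
        for arm in self.arms:
            if arm.chrom not in self._lengths:
                raise ValueError(f"arm on unknown chromosome {arm.chrom!r}")
            if not (0 <= arm.start < arm.end <= self._lengths[arm.chrom]):
                raise ValueError(f"arm {arm} outside chromosome bounds")
            by_chrom.setdefault(arm.chrom, []).append(arm)
        for chrom, arms in by_chrom.items():
            arms = sorted(arms, key=lambda a: a.start)
            for a, b in zip(arms, arms[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping arms on {chrom}: {a.label}, {b.label}")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @property
    def total_arm_length(self) -> int:
        return sum(a.length for a in self.arms)

    def chrom_length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def arms_of(self, chrom: str) -> list[Arm]:
        return sorted((a for a in self.arms if a.chrom == chrom), key=lambda a: a.start)

    def arm_of(self, chrom: str, pos: int) -> Arm | None:
        """Arm containing 1-based position ``pos``, or None if unanalyzable."""
        for arm in self.arms_of(chrom):
            if arm.contains_pos1(pos):
                return arm
        return None


def default_layout() -> GenomeLayout:
    """Small two-chromosome synthetic layout (10 Mbp, four arms)."""
    return GenomeLayout(
        chromosomes=[("chr1", 6_000_000), ("chr2", 4_000_000)],
        arms=[
            Arm("chr1", 0, 3_000_000, "1p"),
            Arm("chr1", 3_000_000, 6_000_000, "1q"),
            Arm("chr2", 0, 2_000_000, "2p"),
            Arm("chr2", 2_000_000, 4_000_000, "2q"),
        ],
    )


class IntervalSet:
    """A set of 0-based half-open genomic intervals (BED semantics).

    The constructor validates ``start < end``; :meth:`normalized` returns a
    sorted, merged, non-overlapping equivalent. Membership tests accept
    1-based variant positions and apply the half-open convention, so a
    variant at interval ``start + 1`` (1-based) is inside and one at
    ``end + 1`` is outside.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self.intervals: list[tuple[str, int, int]] = []
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"interval end <= start: {chrom}:{start}-{end}")
            self.intervals.append((str(chrom), start, end))
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return sorted(self.intervals) == sorted(other.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def normalized(self) -> "IntervalSet":
        """Sorted, merged, non-overlapping form (adjacent intervals fuse)."""
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                c, s, e = merged[-1]
                merged[-1] = (c, s, max(e, end))
            else:
                merged.append((chrom, start, end))
        return IntervalSet(merged)

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            norm = self.normalized()
            index: dict[str, list[list[int]]] = {}
            for chrom, start, end in norm:
                index.setdefault(chrom, [[], []])
                index[chrom][0].append(start)
                index[chrom][1].append(end)
            self._index = {
                chrom: (np.asarray(s), np.asarray(e)) for chrom, (s, e) in index.items()
            }
        return self._index

    def contains_pos1(self, chrom: str, pos: int | np.ndarray) -> bool | np.ndarray:
        """Membership of 1-based positions (vectorized over ``pos``)."""
        idx = np.atleast_1d(np.asarray(pos1_to_index(np.asarray(pos))))
        index = self._build_index()
        if chrom not in index:
            out = np.zeros(idx.shape, dtype=bool)
        else:
            starts, ends = index[chrom]
            k = np.searchsorted(starts, idx, side="right") - 1
            out = (k >= 0) & (idx < ends[np.clip(k, 0, len(ends) - 1)])
        if np.isscalar(pos) or np.asarray(pos).ndim == 0:
            return bool(out[0])
        return out
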