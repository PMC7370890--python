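"""Core genomic coordinate types shared by all pipeline stages.

All internal coordinates are 0-based half-open ([start, end)).  GTF I/O is
1-based inclusive and BED I/O is 0-based half-open; conversions happen at the
file boundary, never inside the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name; must be non-empty.
    start, end : int
        0-based half-open coordinates with ``start < end``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting (start, end) pairs into a disjoint union."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    block: tuple[int, int], cover: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Pieces of *block* not covered by the (sorted, disjoint) *cover* set."""
    s, e = block
    out = []
    pos = s
    for cs, ce in cover:
        if ce <= pos:
            continue
        if cs >= e:
            break
        if cs > pos:
            out.append((pos, cs))
        pos = max(pos, ce)
    if pos < e:
        out.append((pos, e))
    return out
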