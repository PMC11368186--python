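"""Core genomic data model: assemblies, intervals and region sets.

All coordinates are 0-based half-open throughout the package; 1-based
formats (GTF, RepeatMasker) are converted at their readers and writers
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from intervaltree import IntervalTree

from ._seq import VALID_BASES, encode
from .errors import FormatError


class GenomeAssembly:
    """A named set of chromosome sequences.

    Sequences are stored uppercase; soft-masked (lowercase) spans of the
    source FASTA are retained per chromosome as 0-based half-open
    ``(start, end)`` tuples in :attr:`softmask`.
    """

    def __init__(
        self,
        chromosomes: Mapping[str, str],
        softmask: Mapping[str, list[tuple[int, int]]] | None = None,
        name: str = "",
    ):
        self.name = name
        self.chromosomes: dict[str, str] = {}
        self.softmask: dict[str, list[tuple[int, int]]] = {}
        for chrom, seq in chromosomes.items():
            if chrom in self.chromosomes:
                raise FormatError(f"duplicate chromosome name {chrom!r}")
            up = seq.upper()
            bad = set(up) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(up) if c in bad)
                raise FormatError(
                    f"non-IUPAC character {seq[pos]!r} at {chrom}:{pos}"
                )
            self.chromosomes[chrom] = up
            self.softmask[chrom] = list((softmask or {}).get(chrom, []))
        self.lengths: dict[str, int] = {
            c: len(s) for c, s in self.chromosomes.items()
        }
        self._encoded: dict[str, object] = {}

    def encoded(self, chrom: str):
        """uint8 encoding of a chromosome (cached; A,C,G,T,N -> 0..4)."""
        if chrom not in self._encoded:
            self._encoded[chrom] = encode(self.chromosomes[chrom])
        return self._encoded[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __repr__(self) -> str:
        return (
            f"GenomeAssembly({self.name or 'unnamed'}, "
            f"{len(self.chromosomes)} chromosomes, "
            f"{sum(self.lengths.values())} bp)"
        )


@dataclass(frozen=True)
class Interval:
    """A labeled, optionally stranded genomic interval (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended intervals per chromosome.

    Strand and label are dropped on merge (region membership is
    strand-agnostic).
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


@dataclass
class RegionSet:
    """A strand-agnostic set of labeled intervals with containment queries."""

    intervals: list[Interval] = field(default_factory=list)
    class_tag: str = "custom"
    n_skipped: int = 0

    def __post_init__(self):
        self._trees: dict[str, IntervalTree] | None = None

    def _ensure_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in merge_intervals(self.intervals) if self.intervals else []:
                trees.setdefault(iv.chromosome, IntervalTree()).addi(
                    iv.start, iv.end
                )
            self._trees = trees
        return self._trees

    def contains(self, chromosome: str, start: int, end: int) -> bool:
        """True iff [start, end) lies fully inside the union of members.

        The union is pre-merged, so full containment within a single
        merged interval is equivalent to containment in the union.
        """
        tree = self._ensure_trees().get(chromosome)
        if tree is None:
            return False
        return any(
            hit.begin <= start and end <= hit.end
            for hit in tree.overlap(start, end)
        )

    def merged(self) -> "RegionSet":
        """Union of member intervals; idempotent."""
        return RegionSet(merge_intervals(self.intervals), self.class_tag)

    def restricted(self, chromosomes: Iterable[str]) -> "RegionSet":
        keep = set(chromosomes)
        return RegionSet(
            [iv for iv in self.intervals if iv.chromosome in keep],
            self.class_tag,
        )

    def total_span(self) -> int:
        return sum(len(iv) for iv in merge_intervals(self.intervals)) if self.intervals else 0

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)
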