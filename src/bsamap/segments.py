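"""Alternating gene/intergenic segmentation of a collinear genome pair.

Each chromosome with g ortholog pairs yields 2g+1 segments: g gene segments,
g-1 internal intergenic segments, and two terminal flank segments (emitted
as intergenic, flagged terminal) so that every position — and hence every
read start — belongs to exactly one segment per genome. Segment coordinates
tile each chromosome exactly in both genomes. Intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ReadAssignment
from .simulate import Gene, ParentalGenomePair


class CollinearityError(ValueError):
    """Ortholog order disagrees between the two genomes."""


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    segment_id: str
    kind: str            # 'gene' | 'intergenic'
    terminal: bool
    chrom: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    gene_a: Optional[str] = None
    gene_b: Optional[str] = None


@dataclass
class SegmentMap:
    segments: List[Segment]
    #: per chromosome, per genome: sorted arrays of segment start coords
    _starts: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)
    _by_chrom: Dict[str, List[Segment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg in self.segments:
            self._by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in self._by_chrom.items():
            segs.sort(key=lambda s: s.a_start)
            self._starts[(chrom, "A")] = np.array([s.a_start for s in segs])
            self._starts[(chrom, "B")] = np.array([s.b_start for s in segs])

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def chromosomes(self) -> List[str]:
        return list(self._by_chrom)

    def on_chromosome(self, chrom: str) -> List[Segment]:
        return self._by_chrom[chrom]

    def by_id(self, segment_id: str) -> Segment:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise KeyError(segment_id)

    def gene_segment(self, gene_id: str) -> Segment:
        for seg in self.segments:
            if seg.kind == "gene" and gene_id in (seg.gene_a, seg.gene_b):
                return seg
        raise KeyError(f"no gene segment for {gene_id}")

    def locate(self, chrom: str, pos: int, genome: str = "A") -> Segment:
        """The unique segment whose [start, end) interval contains ``pos``."""
        if chrom not in self._by_chrom:
            raise KeyError(f"unknown chromosome {chrom!r}")
        segs = self._by_chrom[chrom]
        starts = self._starts[(chrom, genome)]
        end = segs[-1].a_end if genome == "A" else segs[-1].b_end
        if pos < 0 or pos >= end:
            raise ValueError(f"position {pos} outside {chrom} (genome {genome})")
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return segs[i]


def build_segments(ortholog_map: Sequence[Tuple[str, str]],
                   genes_a: Mapping[str, Gene],
                   genes_b: Mapping[str, Gene],
                   chrom_lengths_a: Mapping[str, int],
                   chrom_lengths_b: Mapping[str, int]) -> SegmentMap:
    """Partition both genomes into paired gene/intergenic segments.

    Raises :class:`CollinearityError` if the ortholog order differs between
    genomes, and :class:`SegmentationError` for overlapping genes.
    """
    by_chrom: Dict[str, List[Tuple[str, str]]] = {}
    for ga, gb in ortholog_map:
        a, b = genes_a[ga], genes_b[gb]
        if a.chrom != b.chrom:
            raise CollinearityError(
                f"ortholog pair ({ga}, {gb}) sits on different chromosomes "
                f"({a.chrom} vs {b.chrom})")
        by_chrom.setdefault(a.chrom, []).append((ga, gb))

    segments: List[Segment] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        pairs = by_chrom[chrom]
        order_a = sorted(pairs, key=lambda p: genes_a[p[0]].start)
        order_b = sorted(pairs, key=lambda p: genes_b[p[1]].start)
        for pa, pb in zip(order_a, order_b):
            if pa != pb:
                raise CollinearityError(
                    f"ortholog order differs on {chrom}: pair {pa} (genome A) "
                    f"vs {pb} (genome B)")
        la, lb = chrom_lengths_a[chrom], chrom_lengths_b[chrom]
        prev_a, prev_b = 0, 0
        n = 0
        for i, (ga, gb) in enumerate(order_a):
            a, b = genes_a[ga], genes_b[gb]
            if a.start < prev_a or b.start < prev_b:
                raise SegmentationError(
                    f"gene {ga}/{gb} overlaps the preceding segment on {chrom}")
            segments.append(Segment(
                f"{chrom}.s{n:03d}", "intergenic", i == 0, chrom,
                prev_a, a.start, prev_b, b.start))
            n += 1
            segments.append(Segment(
                f"{chrom}.s{n:03d}", "gene", False, chrom,
                a.start, a.end, b.start, b.end, ga, gb))
            n += 1
            prev_a, prev_b = a.end, b.end
        if prev_a > la or prev_b > lb:
            raise SegmentationError(f"genes extend past the end of {chrom}")
        segments.append(Segment(
            f"{chrom}.s{n:03d}", "intergenic", True, chrom,
            prev_a, la, prev_b, lb))
    return SegmentMap(segments)


def _chrom_key(chrom: str):
    digits = "".join(c for c in chrom if c.isdigit())
    return (0, int(digits)) if digits else (1, chrom)


def build_segments_from_pair(pair: ParentalGenomePair) -> SegmentMap:
    return build_segments(
        pair.ortholog_map, pair.genes_a, pair.genes_b,
        {c: len(s) for c, s in pair.genome_a.items()},
        {c: len(s) for c, s in pair.genome_b.items()})


# ---------------------------------------------------------------------------
# counting


@dataclass
class SegmentCountMatrix:
    """Per-segment exclusive-read counts.

    ``counts`` is indexed by segment id with a (library, genome) column
    MultiIndex. ``totals[(library, genome)]`` is the total number of reads
    from that library retained as exclusive to that genome — the library-size
    normalizer of the ratio computation. Each pool-to-reference mapping is
    its own library of mapped reads, so the expected pool/parent ratio at an
    unbiased segment is 1.
    """
    counts: pd.DataFrame
    totals: Dict[Tuple[str, str], int]

    @property
    def libraries(self) -> List[str]:
        return sorted({lib for lib, _ in self.counts.columns})


def count_per_segment(assignments_by_library: Mapping[str, Iterable[ReadAssignment]],
                      segment_map: SegmentMap) -> SegmentCountMatrix:
    """Credit each exclusive read to the segment containing its start.

    exclusive_A reads are located with genome-A coordinates, exclusive_B
    reads with genome-B coordinates; all other categories are ignored.
    Reads spanning a boundary belong to the segment of their start.
    """
    seg_ids = [s.segment_id for s in segment_map.segments]
    seg_index = {}
    for chrom in segment_map.chromosomes:
        for j, seg in enumerate(segment_map.on_chromosome(chrom)):
            seg_index[(chrom, j)] = seg.segment_id
    libraries = sorted(assignments_by_library)
    columns = pd.MultiIndex.from_product([libraries, ["A", "B"]],
                                         names=["library", "genome"])
    mat = pd.DataFrame(0, index=pd.Index(seg_ids, name="segment"),
                       columns=columns)
    totals: Dict[Tuple[str, str], int] = {}
    for lib, assignments in assignments_by_library.items():
        per_chrom: Dict[Tuple[str, str], List[int]] = {}
        totals[(lib, "A")] = 0
        totals[(lib, "B")] = 0
        for a in assignments:
            if a.category == "exclusive_A":
                genome = "A"
            elif a.category == "exclusive_B":
                genome = "B"
            else:
                continue
            if a.chrom not in segment_map._by_chrom:
                raise KeyError(f"assignment references unknown chromosome {a.chrom!r}")
            per_chrom.setdefault((a.chrom, genome), []).append(a.start)
            totals[(lib, genome)] += 1
        for (chrom, genome), starts in per_chrom.items():
            starts_arr = np.asarray(starts)
            seg_starts = segment_map._starts[(chrom, genome)]
            idx = np.searchsorted(seg_starts, starts_arr, side="right") - 1
            ids, counts = np.unique(idx, return_counts=True)
            for j, c in zip(ids, counts):
                mat.loc[seg_index[(chrom, int(j))], (lib, genome)] += int(c)
    return SegmentCountMatrix(mat, totals)
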