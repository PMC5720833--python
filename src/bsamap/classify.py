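"""Exclusive assignment of reads to one of two parental genomes.

The retention rule mirrors the experiment: a read is kept only if it has a
single perfect (zero-mismatch, full-length) match to one genome, over both
strands, and no perfect match anywhere in the other genome. Reads perfect in
both genomes are ``shared``; reads with two or more matches within their only
matching genome are ``multimapped``; everything else is ``unmatched``.
Reads containing N never match.

The index is an exact-substring hash over every window of the query length
on the forward strand of each chromosome; reverse-strand hits are found by
looking up the reverse complement of the read, so a self-reverse-complement
(palindromic) read hitting one site on both strands counts as two
occurrences and is multimapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .simulate import ReadSet, revcomp

CATEGORIES = ("exclusive_A", "exclusive_B", "shared", "multimapped", "unmatched")

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    category: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    strand: Optional[str] = None


class GenomeIndex:
    """Exact-substring lookup over one genome for queries of a fixed length.

    Results are identical to a naive scan of every position on both strands.
    Indexes for other query lengths are built lazily on first use.
    """

    def __init__(self, chromosomes: Dict[str, str], k: int):
        if not chromosomes or all(len(s) == 0 for s in chromosomes.values()):
            raise ValueError("cannot index an empty genome")
        if k < 1:
            raise ValueError("window length must be positive")
        self.chromosomes = dict(chromosomes)
        self.k = k
        self._tables: Dict[int, Dict[str, List[Tuple[str, int]]]] = {}
        self._build(k)

    def _build(self, k: int) -> None:
        table: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.chromosomes.items():
            for i in range(len(seq) - k + 1):
                window = seq[i:i + k]
                if "N" in window:
                    continue
                table.setdefault(window, []).append((chrom, i))
        self._tables[k] = table

    def occurrences(self, query: str) -> List[Tuple[str, int, str]]:
        """Every perfect occurrence of ``query`` as (chrom, start, strand)."""
        bad = set(query) - _VALID
        if bad:
            raise ValueError(f"query contains non-ACGTN characters: {sorted(bad)}")
        k = len(query)
        if k == 0:
            raise ValueError("empty query")
        if "N" in query:
            return []
        if k not in self._tables:
            self._build(k)
        table = self._tables[k]
        hits = [(c, p, "+") for c, p in table.get(query, ())]
        rc = revcomp(query)
        hits += [(c, p, "-") for c, p in table.get(rc, ())]
        hits.sort()
        return hits


def build_index(chromosomes: Dict[str, str], read_length: int) -> GenomeIndex:
    return GenomeIndex(chromosomes, read_length)


def classify_read(read: str, index_a: GenomeIndex,
                  index_b: GenomeIndex, read_id: str = "") -> ReadAssignment:
    """Assign one read to exactly one of the five categories."""
    hits_a = index_a.occurrences(read)
    hits_b = index_b.occurrences(read)
    return _categorize(read_id, hits_a, hits_b)


def _categorize(read_id: str, hits_a, hits_b) -> ReadAssignment:
    na, nb = len(hits_a), len(hits_b)
    if na and nb:
        return ReadAssignment(read_id, "shared")
    if na == 1:
        c, p, s = hits_a[0]
        return ReadAssignment(read_id, "exclusive_A", c, p, s)
    if nb == 1:
        c, p, s = hits_b[0]
        return ReadAssignment(read_id, "exclusive_B", c, p, s)
    if na >= 2 or nb >= 2:
        return ReadAssignment(read_id, "multimapped")
    return ReadAssignment(read_id, "unmatched")


def classify_library(reads: ReadSet, index_a: GenomeIndex,
                     index_b: GenomeIndex) -> Tuple[List[ReadAssignment], Counter]:
    """Classify every read of a library; tallies sum to the library size."""
    assignments: List[ReadAssignment] = []
    tally: Counter = Counter({c: 0 for c in CATEGORIES})
    # table lookups are inlined: this loop dominates pipeline runtime
    ta = index_a._tables[index_a.k]
    tb = index_b._tables[index_b.k]
    k = index_a.k
    empty = ()
    for read_id, seq in zip(reads.ids, reads.sequences):
        if len(seq) == k and k == index_b.k and "N" not in seq:
            rc = revcomp(seq)
            hits_a = [(c, p, "+") for c, p in ta.get(seq, empty)] + \
                     [(c, p, "-") for c, p in ta.get(rc, empty)]
            hits_b = [(c, p, "+") for c, p in tb.get(seq, empty)] + \
                     [(c, p, "-") for c, p in tb.get(rc, empty)]
            a = _categorize(read_id, hits_a, hits_b)
        else:
            a = classify_read(seq, index_a, index_b, read_id)
        assignments.append(a)
        tally[a.category] += 1
    return assignments, tally
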