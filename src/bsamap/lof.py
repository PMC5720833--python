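"""Screen ortholog pairs for disabling coding differences.

Aligns the two coding sequences of each ortholog pair globally
(match +1, mismatch -1, gap open -4, gap extend -1; affine, so a gap of
length L scores -(4 + L - 1)), extracts indel events with their frame
effect, predicts translation products, and ranks pairs by severity:
frameshift > premature stop > in-frame indel > substitutions only.

Gap placement inside a repeat run is degenerate; every gap run is
normalized to its leftmost equivalent position, so reported indel
coordinates are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Seq import Seq

from .segments import SegmentMap
from .simulate import ParentalGenomePair

SEVERITY_ORDER = ("frameshift", "premature_stop", "inframe_indel",
                  "substitutions_only", "identical")


@dataclass(frozen=True)
class CdsAlignment:
    """A global pairwise alignment; degapping recovers the inputs exactly."""
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass(frozen=True)
class IndelEvent:
    pos_a: int          # 1-based CDS coordinate in A of/after the event
    pos_b: int          # 1-based CDS coordinate in B of/after the event
    length: int
    sign: int           # +1 insertion in B (gap in A), -1 deletion from B
    frame_change: int   # length % 3
    cumulative_frame: int  # running frame state after this event
    frame_restoring: bool  # True when this event returns the frame to 0

    @property
    def is_frameshift(self) -> bool:
        return self.frame_change != 0


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    length: int              # residues, stop codon excluded
    stopless: bool           # no in-frame stop found
    non_atg_start: bool
    trailing_bases: bool     # CDS length not divisible by 3


@dataclass(frozen=True)
class PairReport:
    gene_a: str
    gene_b: str
    severity: str
    indels: Tuple[IndelEvent, ...]
    protein_length_a: int
    protein_length_b: int
    n_substitutions: int
    premature_stop_in: Optional[str]  # 'A', 'B' or None
    alignment: CdsAlignment


@dataclass
class LofReport:
    pairs: List[PairReport]

    def ranked(self) -> List[PairReport]:
        rank = {s: i for i, s in enumerate(SEVERITY_ORDER)}
        return sorted(self.pairs, key=lambda p: rank[p.severity])


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -4
    al.extend_gap_score = -1
    return al


def _left_normalize(a: str, b: str) -> Tuple[str, str]:
    """Shift every gap run to its leftmost equivalent placement."""
    a_list, b_list = list(a), list(b)
    for gapped, other in ((a_list, b_list), (b_list, a_list)):
        moved = True
        while moved:
            moved = False
            i = 0
            n = len(gapped)
            while i < n:
                if gapped[i] != "-":
                    i += 1
                    continue
                j = i
                while j < n and gapped[j] == "-":
                    j += 1
                # gap run [i, j): slide left one column if the column before
                # the run equals the column just past it in the other sequence
                if i > 0 and gapped[i - 1] != "-" and other[i - 1] == other[j - 1]:
                    gapped[j - 1] = gapped[i - 1]
                    gapped[i - 1] = "-"
                    moved = True
                    i = max(i - 1, 0)
                else:
                    i = j
    return "".join(a_list), "".join(b_list)


def align_cds_pair(cds_a: str, cds_b: str) -> CdsAlignment:
    """Optimal global alignment of two coding sequences.

    Deterministic: of the optimal alignments Biopython enumerates first, gap
    runs are then left-normalized within repeat context.
    """
    for name, s in (("A", cds_a), ("B", cds_b)):
        if not s:
            raise ValueError(f"empty CDS for sequence {name}")
        bad = set(s) - set("ACGT")
        if bad:
            raise ValueError(f"CDS {name} contains non-ACGT characters {sorted(bad)}")
    aln = _aligner().align(cds_a, cds_b)[0]
    a_gapped, b_gapped = str(aln[0]), str(aln[1])
    a_gapped, b_gapped = _left_normalize(a_gapped, b_gapped)
    return CdsAlignment(a_gapped, b_gapped, float(aln.score))


def detect_frameshifts(alignment: CdsAlignment) -> List[IndelEvent]:
    """Maximal gap runs as indel events with cumulative frame bookkeeping."""
    a, b = alignment.aligned_a, alignment.aligned_b
    events: List[IndelEvent] = []
    i = 0
    pos_a = pos_b = 0  # bases consumed so far
    cumulative = 0
    n = len(a)
    while i < n:
        if a[i] == "-":  # insertion in B
            j = i
            while j < n and a[j] == "-":
                j += 1
            length = j - i
            cumulative = (cumulative + length) % 3
            events.append(IndelEvent(pos_a + 1, pos_b + 1, length, +1,
                                     length % 3, cumulative,
                                     cumulative == 0 and length % 3 != 0))
            pos_b += length
            i = j
        elif b[i] == "-":  # deletion from B
            j = i
            while j < n and b[j] == "-":
                j += 1
            length = j - i
            cumulative = (cumulative - length) % 3
            events.append(IndelEvent(pos_a + 1, pos_b + 1, length, -1,
                                     length % 3, cumulative,
                                     cumulative == 0 and length % 3 != 0))
            pos_a += length
            i = j
        else:
            pos_a += 1
            pos_b += 1
            i += 1
    return events


def translate_orf(cds: str) -> TranslationResult:
    """Translate from position 1 to the first in-frame stop.

    Length excludes the stop codon. A non-ATG start and a length not
    divisible by 3 are flagged but do not abort translation.
    """
    if not cds:
        raise ValueError("empty CDS")
    non_atg = not cds.startswith("ATG")
    trailing = len(cds) % 3 != 0
    usable = len(cds) - len(cds) % 3
    protein = str(Seq(cds[:usable]).translate())
    stop_at = protein.find("*")
    if stop_at == -1:
        return TranslationResult(protein, len(protein), True, non_atg, trailing)
    return TranslationResult(protein[:stop_at], stop_at, False, non_atg, trailing)


def _classify_pair(gene_a: str, gene_b: str, cds_a: str,
                   cds_b: str) -> PairReport:
    aln = align_cds_pair(cds_a, cds_b)
    events = detect_frameshifts(aln)
    tr_a = translate_orf(cds_a)
    tr_b = translate_orf(cds_b)
    n_sub = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                if x != "-" and y != "-" and x != y)
    # premature stop relative to the longer ortholog's own reading frame
    full_a = len(cds_a) // 3 - 1
    full_b = len(cds_b) // 3 - 1
    premature = None
    if tr_a.length < full_a and tr_a.length <= tr_b.length:
        premature = "A"
    if tr_b.length < full_b and (premature is None or tr_b.length < tr_a.length):
        premature = "B"
    net_frameshift = any(e.cumulative_frame != 0 for e in events)
    if net_frameshift or any(e.is_frameshift for e in events):
        severity = "frameshift"
    elif premature is not None:
        severity = "premature_stop"
    elif events:
        severity = "inframe_indel"
    elif n_sub > 0:
        severity = "substitutions_only"
    else:
        severity = "identical"
    return PairReport(gene_a, gene_b, severity, tuple(events),
                      tr_a.length, tr_b.length, n_sub, premature, aln)


def screen_region(peak, pair: ParentalGenomePair,
                  segment_map: SegmentMap) -> LofReport:
    """Align and classify every ortholog pair inside a peak's segment run.

    ``peak`` is a :class:`bsamap.asymmetry.Peak` (or anything with a
    ``segment_ids`` attribute). A peak with no gene segments yields an
    empty report.
    """
    reports: List[PairReport] = []
    for sid in peak.segment_ids:
        seg = segment_map.by_id(sid)
        if seg.kind != "gene":
            continue
        if seg.gene_a not in pair.genes_a or seg.gene_b not in pair.genes_b:
            raise KeyError(f"peak segment {sid} references unannotated genes")
        cds_a = pair.genes_a[seg.gene_a].cds(pair.genome_a)
        cds_b = pair.genes_b[seg.gene_b].cds(pair.genome_b)
        reports.append(_classify_pair(seg.gene_a, seg.gene_b, cds_a, cds_b))
    return LofReport(LofReport(reports).ranked())
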