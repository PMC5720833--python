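"""Standard-format I/O: FASTA, GFF3, FASTQ, ortholog/segment/count TSV.

Gzip is accepted transparently on read for FASTA and FASTQ. GFF3 is the
gene-feature dialect this pipeline needs (one ``gene`` feature per gene,
1-based inclusive coordinates on emission, converted to 0-based half-open
on read).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import ReadAssignment
from .segments import Segment, SegmentCountMatrix, SegmentMap
from .simulate import Gene, ParentalGenomePair, ReadSet

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(chromosomes: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in chromosomes.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: PathLike) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(genes: Mapping[str, Gene], chrom_lengths: Mapping[str, int],
               path: PathLike, source: str = "bsamap") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in sorted(genes.values(), key=lambda g: (g.chrom, g.start)):
            fh.write("\t".join([
                gene.chrom, source, "gene",
                str(gene.start + 1), str(gene.end),  # 1-based inclusive
                ".", gene.strand, ".",
                f"ID={gene.gene_id}",
            ]) + "\n")


def read_gff3(path: PathLike) -> Dict[str, Gene]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: Dict[str, Gene] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.id
        genes[gid] = Gene(gid, feat.seqid, feat.start - 1, feat.end, feat.strand)
    return genes


# ---------------------------------------------------------------------------
# ortholog map TSV

ORTHOLOG_COLUMNS = ["gene_A", "chrom_A", "start_A", "end_A", "strand_A",
                    "gene_B", "chrom_B", "start_B", "end_B", "strand_B"]


def write_ortholog_map(pair: ParentalGenomePair, path: PathLike) -> None:
    rows = []
    for ga, gb in pair.ortholog_map:
        a, b = pair.genes_a[ga], pair.genes_b[gb]
        rows.append([ga, a.chrom, a.start, a.end, a.strand,
                     gb, b.chrom, b.start, b.end, b.strand])
    pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: PathLike) -> List[Tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ortholog map missing columns {sorted(missing)}")
    return list(zip(df["gene_A"], df["gene_B"]))


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(reads: ReadSet, path: PathLike, quality_char: str = "I") -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in zip(reads.ids, reads.sequences):
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: PathLike, library: str) -> ReadSet:
    ids: List[str] = []
    seqs: List[str] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
    return ReadSet(library, seqs, ids, [])


# ---------------------------------------------------------------------------
# assignments, segments, counts, ratios

def write_assignments(assignments: Iterable[ReadAssignment], path: PathLike) -> None:
    rows = [[a.read_id, a.category,
             a.chrom or ".", -1 if a.start is None else a.start, a.strand or "."]
            for a in assignments]
    pd.DataFrame(rows, columns=["read_id", "category", "chrom", "start", "strand"]
                 ).to_csv(path, sep="\t", index=False)


def write_segment_map(segment_map: SegmentMap, path: PathLike) -> None:
    rows = [[s.segment_id, s.kind, int(s.terminal), s.chrom,
             s.a_start, s.a_end, s.b_start, s.b_end,
             s.gene_a or ".", s.gene_b or "."]
            for s in segment_map.segments]
    pd.DataFrame(rows, columns=["segment", "kind", "terminal", "chrom",
                                "start_A", "end_A", "start_B", "end_B",
                                "gene_A", "gene_B"]
                 ).to_csv(path, sep="\t", index=False)


def write_counts(matrix: SegmentCountMatrix, path: PathLike) -> None:
    flat = matrix.counts.copy()
    flat.columns = [f"{lib}:{genome}" for lib, genome in flat.columns]
    flat.to_csv(path, sep="\t")
    totals_path = Path(path).with_suffix(".totals.json")
    totals_path.write_text(json.dumps(
        {f"{lib}:{genome}": n for (lib, genome), n in matrix.totals.items()},
        indent=2, sort_keys=True))


def read_counts(path: PathLike) -> SegmentCountMatrix:
    flat = pd.read_csv(path, sep="\t", index_col=0)
    cols = pd.MultiIndex.from_tuples([tuple(c.split(":")) for c in flat.columns],
                                     names=["library", "genome"])
    flat.columns = cols
    totals = json.loads(Path(path).with_suffix(".totals.json").read_text())
    return SegmentCountMatrix(
        flat, {tuple(k.split(":")): int(v) for k, v in totals.items()})


def write_bedgraph(profile: pd.Series, segment_map: SegmentMap,
                   path: PathLike, genome: str = "A") -> None:
    with _open_text(path, "wt") as fh:
        fh.write('track type=bedGraph name="asymmetry"\n')
        for seg in segment_map.segments:
            start = seg.a_start if genome == "A" else seg.b_start
            end = seg.a_end if genome == "A" else seg.b_end
            if end > start:
                fh.write(f"{seg.chrom}\t{start}\t{end}\t"
                         f"{float(profile[seg.segment_id]):.6g}\n")


def write_peaks(peaks, path: PathLike) -> None:
    rows = []
    for p in peaks:
        pair = "." if p.apex_ortholog_pair is None else \
            f"{p.apex_ortholog_pair[0]}|{p.apex_ortholog_pair[1]}"
        rows.append([p.rank, p.chrom, p.apex_segment, f"{p.apex_value:.6g}",
                     len(p.segment_ids), ",".join(p.segment_ids), pair])
    pd.DataFrame(rows, columns=["rank", "chrom", "apex_segment", "apex_value",
                                "n_segments", "segments", "apex_ortholog_pair"]
                 ).to_csv(path, sep="\t", index=False)


def write_lof_report(report, path: PathLike) -> None:
    rows = []
    for p in report.pairs:
        indels = ";".join(
            f"{'ins' if e.sign > 0 else 'del'}@A{e.pos_a}/B{e.pos_b}"
            f"+{e.length}nt(frame{e.frame_change}"
            f"{',restoring' if e.frame_restoring else ''})"
            for e in p.indels) or "."
        rows.append([p.gene_a, p.gene_b, p.severity, len(p.indels), indels,
                     p.protein_length_a, p.protein_length_b,
                     p.n_substitutions, p.premature_stop_in or "."])
    pd.DataFrame(rows, columns=["gene_A", "gene_B", "severity", "n_indels",
                                "indels", "protein_len_A", "protein_len_B",
                                "n_substitutions", "premature_stop_in"]
                 ).to_csv(path, sep="\t", index=False)


def write_truth(pair: ParentalGenomePair, segregants, pools,
                path: PathLike) -> None:
    truth = {
        "causal": None if pair.causal is None else {
            "gene": pair.causal.gene_id,
            "cds_offset": pair.causal.cds_offset,
            "inserted_base": pair.causal.inserted_base,
            "chrom": pair.causal.chrom,
            "genomic_pos": pair.causal.genomic_pos,
        },
        "segregants": [
            {
                "id": s.segregant_id,
                "phenotype": s.phenotype,
                "mating_type": s.mating_type,
                "mosaic": {c: [[a0, a1, lab] for a0, a1, lab in iv]
                           for c, iv in s.mosaic.items()},
            }
            for s in segregants
        ],
        "pools": pools.pools,
    }
    Path(path).write_text(json.dumps(truth, indent=1))
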