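"""End-to-end orchestration: simulate -> classify -> count -> score -> screen.

Every stage writes its artifacts under an output directory and appends to a
JSON run manifest (config snapshot, seed, file checksums, per-stage tallies,
and — in simulated mode — a recovery verdict comparing the top peak against
the planted causal gene). Re-running with the same config and seed
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import io as bio
from .asymmetry import (asymmetry_profile, compute_ratios, merge_mating_types,
                        rank_peaks)
from .classify import GenomeIndex, classify_library
from .config import LIBRARIES, SimulationConfig
from .lof import screen_region
from .segments import (CollinearityError, SegmentMap, build_segments,
                       build_segments_from_pair, count_per_segment)
from .simulate import (ParentalGenomePair, build_pools, generate_parental_pair,
                       simulate_cross, simulate_parent_reads,
                       simulate_pool_reads)

logger = logging.getLogger("bsamap")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: List[dict] = field(default_factory=list)
    files: Dict[str, str] = field(default_factory=dict)
    verdict: Optional[dict] = None

    def add_stage(self, name: str, **tallies) -> None:
        self.stages.append({"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                            **tallies})
        logger.info("[%s] %s", name, tallies)

    def add_file(self, path: Path) -> None:
        self.files[path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({
            "config": self.config, "seed": self.seed, "stages": self.stages,
            "files": self.files, "verdict": self.verdict}, indent=1))


def run_pipeline(config: SimulationConfig, outdir, *,
                 write_fastq: bool = False,
                 pseudocount: float = 0.0) -> RunManifest:
    """Simulated-mode pipeline; returns the manifest (also written to disk).

    ``write_fastq`` controls whether the (large) per-library FASTQ artifacts
    are written; classification always runs on the in-memory reads, so the
    result is identical either way.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest = RunManifest(config.to_dict(), config.seed)

    # --- simulate
    pair = generate_parental_pair(config)
    segregants = simulate_cross(pair, config)
    pools = build_pools(segregants, config.pool_sizes, config.seed)
    reads = simulate_pool_reads(pair, segregants, pools, config)
    reads.update(simulate_parent_reads(pair, config))
    manifest.add_stage("simulate",
                       n_segregants=len(segregants),
                       pool_sizes={k: len(v) for k, v in pools.pools.items()},
                       reads={k: len(v) for k, v in reads.items()})

    bio.write_fasta(pair.genome_a, outdir / "genome_A.fasta")
    bio.write_fasta(pair.genome_b, outdir / "genome_B.fasta")
    bio.write_gff3(pair.genes_a, {c: len(s) for c, s in pair.genome_a.items()},
                   outdir / "genes_A.gff3")
    bio.write_gff3(pair.genes_b, {c: len(s) for c, s in pair.genome_b.items()},
                   outdir / "genes_B.gff3")
    bio.write_ortholog_map(pair, outdir / "orthologs.tsv")
    bio.write_truth(pair, segregants, pools, outdir / "truth.json")
    if write_fastq:
        for lib, rs in reads.items():
            bio.write_fastq(rs, outdir / f"{lib}.fastq")

    # --- classify
    index_a = GenomeIndex(pair.genome_a, config.read_length)
    index_b = GenomeIndex(pair.genome_b, config.read_length)
    assignments = {}
    tallies = {}
    for lib, rs in reads.items():
        assignments[lib], tallies[lib] = classify_library(rs, index_a, index_b)
    manifest.add_stage("classify", tallies={k: dict(v) for k, v in tallies.items()})

    # --- segment & count
    segment_map = build_segments_from_pair(pair)
    counts = count_per_segment(assignments, segment_map)
    bio.write_segment_map(segment_map, outdir / "segments.tsv")
    bio.write_counts(counts, outdir / "counts.tsv")
    manifest.add_stage("count", n_segments=len(segment_map),
                       totals={f"{lib}:{g}": n
                               for (lib, g), n in counts.totals.items()})

    # --- score
    merged = merge_mating_types(counts)
    ratios = compute_ratios(merged, pseudocount=pseudocount)
    profile = asymmetry_profile(ratios)
    peaks = rank_peaks(profile, segment_map)
    ratios.to_csv(outdir / "ratios.tsv", sep="\t")
    profile.to_frame().to_csv(outdir / "asymmetry.tsv", sep="\t")
    bio.write_bedgraph(profile, segment_map, outdir / "asymmetry_A.bedgraph", "A")
    bio.write_bedgraph(profile, segment_map, outdir / "asymmetry_B.bedgraph", "B")
    bio.write_peaks(peaks, outdir / "peaks.tsv")
    manifest.add_stage("score", n_peaks=len(peaks),
                       top_apex=None if not peaks else peaks[0].apex_segment)

    # --- screen the top peak
    if peaks:
        report = screen_region(peaks[0], pair, segment_map)
        bio.write_lof_report(report, outdir / "lof_report.tsv")
        manifest.add_stage("screen", n_pairs=len(report.pairs))
    else:
        report = None
        manifest.add_stage("screen", n_pairs=0)

    # --- verdict against truth
    if config.causal_gene is not None:
        causal_seg = segment_map.gene_segment(config.causal_gene).segment_id
        in_top = bool(peaks) and causal_seg in peaks[0].segment_ids
        is_apex = bool(peaks) and peaks[0].apex_segment == causal_seg
        manifest.verdict = {
            "causal_gene": config.causal_gene,
            "causal_segment": causal_seg,
            "causal_in_top_peak": in_top,
            "causal_is_top_apex": is_apex,
        }
        if report is not None and report.pairs:
            top_pair = report.ranked()[0]
            manifest.verdict["screen_top_gene"] = top_pair.gene_a
            manifest.verdict["screen_top_severity"] = top_pair.severity

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.add_file(f)
    manifest.write(outdir / "manifest.json")
    return manifest


def analyze_simulation(config: SimulationConfig, *,
                       shuffle_seed: Optional[int] = None) -> dict:
    """One in-memory end-to-end run; no files written.

    With ``shuffle_seed`` set, phenotype labels are permuted across
    segregants before pooling (the null-model control in which genotype and
    phenotype are independent).

    Returns the segment map, asymmetry profile, ranked peaks and — when a
    causal gene is configured — whether its segment lies inside / at the
    apex of the top-ranked peak.
    """
    from .simulate import shuffle_phenotypes

    config.validate()
    pair = generate_parental_pair(config)
    segregants = simulate_cross(pair, config)
    if shuffle_seed is not None:
        segregants = shuffle_phenotypes(segregants, shuffle_seed)
    pools = build_pools(segregants, config.pool_sizes, config.seed)
    reads = simulate_pool_reads(pair, segregants, pools, config)
    reads.update(simulate_parent_reads(pair, config))
    index_a = GenomeIndex(pair.genome_a, config.read_length)
    index_b = GenomeIndex(pair.genome_b, config.read_length)
    assignments = {lib: classify_library(rs, index_a, index_b)[0]
                   for lib, rs in reads.items()}
    segment_map = build_segments_from_pair(pair)
    counts = count_per_segment(assignments, segment_map)
    ratios = compute_ratios(merge_mating_types(counts))
    profile = asymmetry_profile(ratios)
    peaks = rank_peaks(profile, segment_map)
    out = {"pair": pair, "segment_map": segment_map, "counts": counts,
           "ratios": ratios, "profile": profile, "peaks": peaks}
    if config.causal_gene is not None:
        causal_seg = segment_map.gene_segment(config.causal_gene).segment_id
        out["causal_segment"] = causal_seg
        out["causal_in_top_peak"] = bool(peaks) and causal_seg in peaks[0].segment_ids
        out["causal_is_top_apex"] = bool(peaks) and peaks[0].apex_segment == causal_seg
    return out


# ---------------------------------------------------------------------------
# input validation (real-data mode)


@dataclass
class ValidationIssue:
    fatal: bool
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(i.fatal for i in self.issues)

    def add(self, fatal: bool, message: str) -> None:
        self.issues.append(ValidationIssue(fatal, message))
        (logger.error if fatal else logger.warning)("validate: %s", message)


def validate_inputs(fasta_a, fasta_b, gff_a, gff_b,
                    orthologs_tsv) -> ValidationReport:
    """Parse checks, chromosome cross-consistency and collinearity."""
    report = ValidationReport()
    try:
        genome_a = bio.read_fasta(fasta_a)
        genome_b = bio.read_fasta(fasta_b)
    except Exception as exc:  # malformed FASTA
        report.add(True, f"FASTA parse failure: {exc}")
        return report
    try:
        genes_a = bio.read_gff3(gff_a)
        genes_b = bio.read_gff3(gff_b)
    except Exception as exc:
        report.add(True, f"GFF3 parse failure: {exc}")
        return report
    for label, genome, genes in (("A", genome_a, genes_a), ("B", genome_b, genes_b)):
        for g in genes.values():
            if g.chrom not in genome:
                report.add(True, f"gene {g.gene_id} (genome {label}) on unknown "
                                 f"chromosome {g.chrom}")
            elif g.end > len(genome[g.chrom]):
                report.add(True, f"gene {g.gene_id} (genome {label}) extends past "
                                 f"the end of {g.chrom}")
    try:
        orthologs = bio.read_ortholog_map(orthologs_tsv)
    except Exception as exc:
        report.add(True, f"ortholog map parse failure: {exc}")
        return report
    try:
        build_segments(orthologs, genes_a, genes_b,
                       {c: len(s) for c, s in genome_a.items()},
                       {c: len(s) for c, s in genome_b.items()})
    except CollinearityError as exc:
        report.add(True, f"collinearity failure: {exc}")
    except Exception as exc:
        report.add(True, f"segmentation failure: {exc}")
    return report


def load_genome_pair(fasta_a, fasta_b, gff_a, gff_b,
                     orthologs_tsv) -> ParentalGenomePair:
    """Real-data loader; the truth alignment and causal record stay empty."""
    genome_a = bio.read_fasta(fasta_a)
    genome_b = bio.read_fasta(fasta_b)
    genes_a = bio.read_gff3(gff_a)
    genes_b = bio.read_gff3(gff_b)
    orthologs = bio.read_ortholog_map(orthologs_tsv)
    return ParentalGenomePair(genome_a, genome_b, genes_a, genes_b,
                              orthologs, blocks={}, causal=None)
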