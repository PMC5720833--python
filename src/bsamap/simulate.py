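"""Synthetic interspecies cross with known ground truth.

Generates everything the real bulk-segregant experiment provided: two
collinear parental genomes (~10% diverged, micro-indels confined to
intergenic DNA so the true alignment stays trivial), a planted 1-bp causal
insertion in parent B's copy of a target gene, haploid meiotic segregants
with Poisson crossovers, phenotype/mating-type assignment, four
phenotype x mating-type pools, and unpaired error-bearing short reads.

Coordinates are 0-based half-open internally. The per-chromosome alignment
between the two genomes is carried as a list of 1:1 match blocks
(a_start, a_end, b_start, b_end); indels appear as discontinuities
between blocks. This block map is the ground-truth alignment used by the
test oracles and by mosaic-sequence construction; it never feeds the
read classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from bisect import bisect_right
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ConfigError, POOL_SPECS, SimulationConfig, parse_gene_id

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODONS_NONSTOP = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                   if a + b + c not in _STOPS]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PoolError(RuntimeError):
    """A phenotype x mating-type class cannot fill its requested pool."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int   # 0-based, half-open
    end: int
    strand: str  # '+' or '-'

    def cds(self, genome: Dict[str, str]) -> str:
        seq = genome[self.chrom][self.start:self.end]
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class CausalMutation:
    gene_id: str
    cds_offset: int       # 1-based position of the inserted base in the mutant CDS
    inserted_base: str    # in CDS orientation
    chrom: str
    genomic_pos: int      # 0-based position of the inserted base in genome B


Block = Tuple[int, int, int, int]  # a_start, a_end, b_start, b_end


@dataclass
class ParentalGenomePair:
    """Two collinear genomes, their gene annotations, ortholog map and truth."""

    genome_a: Dict[str, str]
    genome_b: Dict[str, str]
    genes_a: Dict[str, Gene]
    genes_b: Dict[str, Gene]
    ortholog_map: List[Tuple[str, str]]     # ordered, collinear; here ids coincide
    blocks: Dict[str, List[Block]]          # ground-truth alignment per chromosome
    causal: Optional[CausalMutation] = None

    @property
    def chromosomes(self) -> List[str]:
        return list(self.genome_a)

    def genes_on(self, chrom: str, genome: str = "A") -> List[Gene]:
        table = self.genes_a if genome == "A" else self.genes_b
        return sorted((g for g in table.values() if g.chrom == chrom),
                      key=lambda g: g.start)

    def project_a_to_b(self, chrom: str, pos: int) -> int:
        """Map an A coordinate to the corresponding B coordinate.

        Positions falling inside an A-only (deleted-in-B) stretch snap to the
        start of the next block; the chromosome-end position maps to the B end.
        """
        blocks = self.blocks[chrom]
        if pos >= len(self.genome_a[chrom]):
            return len(self.genome_b[chrom])
        i = bisect_right(blocks, pos, key=lambda blk: blk[0]) - 1
        if i < 0:
            return 0
        a0, a1, b0, b1 = blocks[i]
        if pos < a1:
            return b0 + (pos - a0)
        return b1  # in the gap after block i; snap to following B position


# ---------------------------------------------------------------------------
# genome generation


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """An intact ORF: ATG + non-stop codons + one stop. length % 3 == 0."""
    n_internal = length // 3 - 2
    idx = rng.integers(0, len(_CODONS_NONSTOP), n_internal)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(_CODONS_NONSTOP[i] for i in idx) + stop


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _substitute_positions(seq: List[str], positions: np.ndarray,
                          rng: np.random.Generator) -> None:
    """Replace each listed position with a uniformly chosen different base."""
    for p in positions:
        old = seq[p]
        choices = [b for b in _BASES if b != old]
        seq[p] = choices[rng.integers(0, 3)]


def _diverge_cds(cds_a: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute sites of a CDS without creating internal stops.

    The start and stop codons are kept untouched so every non-causal ORF in
    genome B stays intact; any substitution that creates an in-frame stop is
    redrawn.
    """
    seq = list(cds_a)
    n = len(seq)
    mask = rng.random(n) < rate
    mask[:3] = False
    mask[-3:] = False
    positions = np.flatnonzero(mask)
    _substitute_positions(seq, positions, rng)
    changed = set(int(p) for p in positions)
    for codon_start in range(3, n - 3, 3):
        guard = 0
        while "".join(seq[codon_start:codon_start + 3]) in _STOPS:
            movable = [p for p in range(codon_start, codon_start + 3) if p in changed]
            if not movable:  # cannot happen: A had no internal stop
                for p in range(codon_start, codon_start + 3):
                    seq[p] = cds_a[p]
                break
            p = movable[rng.integers(0, len(movable))]
            _substitute_positions(seq, np.array([p]), rng)
            guard += 1
            if guard > 100:
                seq[codon_start:codon_start + 3] = cds_a[codon_start:codon_start + 3]
                break
    return "".join(seq)


def _diverge_intergenic(seq_a: str, sub_rate: float, indel_rate: float,
                        rng: np.random.Generator,
                        a_offset: int, b_offset: int,
                        blocks: List[Block]) -> Tuple[str, int]:
    """Derive the B copy of an intergenic stretch; append match blocks.

    Substitutions at sub_rate; 1-bp insertions/deletions each at
    indel_rate / 2 per site. Returns (b_sequence, new_b_offset).
    """
    n = len(seq_a)
    if n == 0:
        return "", b_offset
    seq = list(seq_a)
    sub_pos = np.flatnonzero(rng.random(n) < sub_rate)
    _substitute_positions(seq, sub_pos, rng)
    indel_pos = np.flatnonzero(rng.random(n) < indel_rate)
    indel_ins = rng.random(len(indel_pos)) < 0.5
    ins_bases = [_BASES[i] for i in rng.integers(0, 4, len(indel_pos))]

    parts: List[str] = []
    prev = 0
    b_cur = b_offset
    for p, is_ins, base in zip(indel_pos, indel_ins, ins_bases):
        p = int(p)
        if p > prev:
            block_seq = "".join(seq[prev:p])
            blocks.append((a_offset + prev, a_offset + p, b_cur, b_cur + len(block_seq)))
            parts.append(block_seq)
            b_cur += len(block_seq)
        if is_ins:  # extra base in B before A position p; A base p still matches
            parts.append(base)
            b_cur += 1
            blocks.append((a_offset + p, a_offset + p + 1, b_cur, b_cur + 1))
            parts.append(seq[p])
            b_cur += 1
        # deletion: A base p absent from B, no block emitted
        prev = p + 1
    if prev < n:
        block_seq = "".join(seq[prev:n])
        blocks.append((a_offset + prev, a_offset + n, b_cur, b_cur + len(block_seq)))
        parts.append(block_seq)
        b_cur += len(block_seq)
    return "".join(parts), b_cur


def generate_parental_pair(config: SimulationConfig) -> ParentalGenomePair:
    """Build genome A de novo, derive genome B at the configured divergence,
    and plant the causal frameshift (when a causal gene is configured).

    Deterministic: byte-identical output for identical (config, seed).
    """
    config.validate()
    rng = np.random.default_rng([config.seed % 2**31, 11])
    genome_a: Dict[str, str] = {}
    genome_b: Dict[str, str] = {}
    genes_a: Dict[str, Gene] = {}
    genes_b: Dict[str, Gene] = {}
    blocks: Dict[str, List[Block]] = {}
    ortholog_map: List[Tuple[str, str]] = []
    ig_lo, ig_hi = config.intergenic_length_range
    g_lo, g_hi = config.gene_length_range

    for ci in range(1, config.n_chromosomes + 1):
        chrom = f"chr{ci}"
        parts_a: List[str] = []
        parts_b: List[str] = []
        chrom_blocks: List[Block] = []
        a_cur = 0
        b_cur = 0

        def emit_intergenic(length: int) -> None:
            nonlocal a_cur, b_cur
            seg_a = _random_dna(rng, length)
            seg_b, b_new = _diverge_intergenic(
                seg_a, config.divergence_rate, config.micro_indel_rate,
                rng, a_cur, b_cur, chrom_blocks)
            parts_a.append(seg_a)
            parts_b.append(seg_b)
            a_cur += length
            b_cur = b_new

        for gi in range(1, config.genes_per_chromosome + 1):
            emit_intergenic(int(rng.integers(ig_lo, ig_hi + 1)))
            gene_id = f"c{ci}g{gi:02d}"
            if gene_id == config.causal_gene:
                length = config.causal_cds_length
            else:
                length = int(rng.integers(g_lo, g_hi + 1)) // 3 * 3
            cds_a = _random_orf(rng, length)
            cds_b = _diverge_cds(cds_a, config.divergence_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            seq_a = cds_a if strand == "+" else revcomp(cds_a)
            seq_b = cds_b if strand == "+" else revcomp(cds_b)
            genes_a[gene_id] = Gene(gene_id, chrom, a_cur, a_cur + length, strand)
            genes_b[gene_id] = Gene(gene_id, chrom, b_cur, b_cur + length, strand)
            chrom_blocks.append((a_cur, a_cur + length, b_cur, b_cur + length))
            parts_a.append(seq_a)
            parts_b.append(seq_b)
            a_cur += length
            b_cur += length
            ortholog_map.append((gene_id, gene_id))
        emit_intergenic(int(rng.integers(ig_lo, ig_hi + 1)))

        genome_a[chrom] = "".join(parts_a)
        genome_b[chrom] = "".join(parts_b)
        blocks[chrom] = chrom_blocks

    pair = ParentalGenomePair(genome_a, genome_b, genes_a, genes_b,
                              ortholog_map, blocks)
    if config.causal_gene is not None:
        pair = plant_causal_frameshift(pair, config.causal_gene,
                                       config.causal_insertion_offset)
    return pair


# ---------------------------------------------------------------------------
# causal frameshift


def insert_base_b(pair: ParentalGenomePair, chrom: str, pos: int,
                  base: str) -> ParentalGenomePair:
    """Insert one base into genome B at a genomic position, shifting all
    downstream B coordinates and splitting the containing alignment block."""
    seq = pair.genome_b[chrom]
    if not 0 <= pos <= len(seq):
        raise ValueError(f"insertion position {pos} outside {chrom}")
    genome_b = dict(pair.genome_b)
    genome_b[chrom] = seq[:pos] + base + seq[pos:]
    genes_b = {}
    for gid, g in pair.genes_b.items():
        if g.chrom != chrom:
            genes_b[gid] = g
        else:
            start = g.start + 1 if g.start >= pos else g.start
            end = g.end + 1 if g.end > pos else g.end
            genes_b[gid] = dataclasses.replace(g, start=start, end=end)
    blocks = dict(pair.blocks)
    new_blocks: List[Block] = []
    for (a0, a1, b0, b1) in blocks[chrom]:
        if b1 <= pos:
            new_blocks.append((a0, a1, b0, b1))
        elif b0 >= pos:
            new_blocks.append((a0, a1, b0 + 1, b1 + 1))
        else:
            d = pos - b0
            new_blocks.append((a0, a0 + d, b0, pos))
            new_blocks.append((a0 + d, a1, pos + 1, b1 + 1))
    blocks[chrom] = new_blocks
    return dataclasses.replace(pair, genome_b=genome_b, genes_b=genes_b,
                               blocks=blocks)


def delete_base_b(pair: ParentalGenomePair, chrom: str, pos: int) -> ParentalGenomePair:
    """Inverse of :func:`insert_base_b` (removes the base at ``pos``)."""
    seq = pair.genome_b[chrom]
    if not 0 <= pos < len(seq):
        raise ValueError(f"deletion position {pos} outside {chrom}")
    genome_b = dict(pair.genome_b)
    genome_b[chrom] = seq[:pos] + seq[pos + 1:]
    genes_b = {}
    for gid, g in pair.genes_b.items():
        if g.chrom != chrom:
            genes_b[gid] = g
        else:
            start = g.start - 1 if g.start > pos else g.start
            end = g.end - 1 if g.end > pos else g.end
            genes_b[gid] = dataclasses.replace(g, start=start, end=end)
    blocks = dict(pair.blocks)
    new_blocks = []
    for (a0, a1, b0, b1) in blocks[chrom]:
        if b1 <= pos:
            new_blocks.append((a0, a1, b0, b1))
        elif b0 > pos:
            new_blocks.append((a0, a1, b0 - 1, b1 - 1))
        else:
            # the deleted base sat inside this block: drop the aligned column
            d = pos - b0
            if d > 0:
                new_blocks.append((a0, a0 + d, b0, pos))
            if a0 + d + 1 < a1:
                new_blocks.append((a0 + d + 1, a1, pos, b1 - 1))
    blocks[chrom] = new_blocks
    return dataclasses.replace(pair, genome_b=genome_b, genes_b=genes_b,
                               blocks=blocks)


def plant_causal_frameshift(pair: ParentalGenomePair, gene_id: str,
                            offset: int) -> ParentalGenomePair:
    """Insert one base into genome B's copy of ``gene_id`` so that the new
    base occupies 1-based CDS position ``offset`` of the mutant allele.

    The inserted base is T when that placement is unambiguous, otherwise the
    first base differing from both CDS neighbours, so the alignment gap has a
    unique leftmost position.
    """
    if gene_id not in dict(pair.ortholog_map):
        raise KeyError(f"gene {gene_id} not in ortholog map")
    gene = pair.genes_b[gene_id]
    cds = gene.cds(pair.genome_b)
    if not 1 <= offset <= len(cds):
        raise ValueError(
            f"insertion offset {offset} outside CDS of {gene_id} (length {len(cds)})")
    left = cds[offset - 2] if offset >= 2 else ""
    right = cds[offset - 1]
    base = next(b for b in "TACG" if b != left and b != right)
    if gene.strand == "+":
        gpos = gene.start + (offset - 1)
        gbase = base
    else:
        gpos = gene.end - offset + 1
        gbase = base.translate(_COMPLEMENT)
    out = insert_base_b(pair, gene.chrom, gpos, gbase)
    if gene.strand == "-" and gpos == gene.end:
        # insertion at CDS position 1 of a minus-strand gene lands at the
        # gene's genomic end boundary; grow the gene to absorb it
        out.genes_b[gene_id] = dataclasses.replace(out.genes_b[gene_id],
                                                   end=gene.end + 1)
    out.causal = CausalMutation(gene_id, offset, base, gene.chrom, gpos)
    return out


# ---------------------------------------------------------------------------
# meiosis, phenotype, pools


@dataclass
class Segregant:
    segregant_id: str
    #: per chromosome: list of (a_start, a_end, parent-label) tiling A coords
    mosaic: Dict[str, List[Tuple[int, int, str]]]
    phenotype: str       # 'switcher' | 'non_switcher'
    mating_type: str     # 'a' | 'alpha'

    def genotype_at(self, chrom: str, pos: int) -> str:
        for a0, a1, label in self.mosaic[chrom]:
            if a0 <= pos < a1:
                return label
        raise ValueError(f"position {pos} outside {chrom}")

    def genotype_at_gene(self, pair: ParentalGenomePair, gene_id: str) -> str:
        g = pair.genes_a[gene_id]
        return self.genotype_at(g.chrom, (g.start + g.end) // 2)


@dataclass
class SegregantSet:
    segregants: List[Segregant]

    def __len__(self) -> int:
        return len(self.segregants)

    def __iter__(self):
        return iter(self.segregants)


@dataclass
class PoolDesign:
    """Four pools keyed by library name; values are segregant ids."""
    pools: Dict[str, List[str]]


def _draw_mosaic(rng: np.random.Generator, length: int,
                 rate: float) -> List[Tuple[int, int, str]]:
    k = rng.poisson(rate)
    cuts = sorted(set(int(c) for c in rng.integers(1, length, k))) if k else []
    labels = ("A", "B") if rng.random() < 0.5 else ("B", "A")
    bounds = [0] + cuts + [length]
    return [(bounds[i], bounds[i + 1], labels[i % 2]) for i in range(len(bounds) - 1)]


def simulate_cross(pair: ParentalGenomePair, config: SimulationConfig) -> SegregantSet:
    """Haploid segregants from the A x B diploid.

    Crossovers per chromosome are Poisson with uniform positions and no
    interference. Phenotype: carrying the A (functional) allele at the causal
    gene makes a switcher with probability ``penetrance``; non-carriers never
    switch; the observed label is then flipped with probability
    ``misclassification_rate``. Mating type is a neutral marker gene. With an
    incompatibility pair set, segregants carrying the A allele at the first
    gene together with the B allele at the second are discarded (rejection).
    """
    if config.causal_gene is not None and pair.causal is None:
        raise ValueError("causal gene configured but not planted in the genome pair")
    rng = np.random.default_rng([config.seed % 2**31, 13])
    lengths = {c: len(pair.genome_a[c]) for c in pair.chromosomes}
    out: List[Segregant] = []
    attempts = 0
    while len(out) < config.n_segregants:
        attempts += 1
        if attempts > 50 * config.n_segregants:
            raise RuntimeError("incompatibility rejection rate too high")
        mosaic = {c: _draw_mosaic(rng, lengths[c], config.crossovers_per_chromosome)
                  for c in pair.chromosomes}
        seg = Segregant(f"seg{len(out):04d}", mosaic, "", "")
        if config.incompatibility_pair is not None:
            g1, g2 = config.incompatibility_pair
            if (seg.genotype_at_gene(pair, g1) == "A"
                    and seg.genotype_at_gene(pair, g2) == "B"):
                continue
        if config.causal_gene is not None:
            functional = seg.genotype_at_gene(pair, config.causal_gene) == "A"
        else:
            functional = rng.random() < 0.5
        switcher = functional and (rng.random() < config.penetrance)
        if rng.random() < config.misclassification_rate:
            switcher = not switcher
        seg.phenotype = "switcher" if switcher else "non_switcher"
        mt_allele = seg.genotype_at_gene(pair, config.mating_type_locus)
        seg.mating_type = "a" if mt_allele == "A" else "alpha"
        out.append(seg)
    return SegregantSet(out)


def shuffle_phenotypes(segregants: SegregantSet, seed: int) -> SegregantSet:
    """Permute phenotype labels across segregants (null-model control)."""
    rng = np.random.default_rng(seed % 2**31)
    labels = [s.phenotype for s in segregants]
    perm = rng.permutation(len(labels))
    shuffled = [
        dataclasses.replace(s, phenotype=labels[perm[i]])
        for i, s in enumerate(segregants)
    ]
    return SegregantSet(shuffled)


def build_pools(segregants: SegregantSet,
                pool_sizes: Sequence[int],
                seed: int) -> PoolDesign:
    """Sample each phenotype x mating-type pool without replacement."""
    rng = np.random.default_rng(seed % 2**31)
    by_class: Dict[Tuple[str, str], List[str]] = {}
    for s in segregants:
        by_class.setdefault((s.phenotype, s.mating_type), []).append(s.segregant_id)
    pools: Dict[str, List[str]] = {}
    for (phen, mt, lib), size in zip(POOL_SPECS, pool_sizes):
        avail = by_class.get((phen, mt), [])
        if len(avail) < size:
            raise PoolError(
                f"pool {lib} needs {size} clones but only {len(avail)} "
                f"{phen}/{mt} segregants are available")
        chosen = rng.choice(len(avail), size=size, replace=False) if size else []
        pools[lib] = sorted(avail[i] for i in chosen)
    return PoolDesign(pools)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSet:
    """Unpaired reads plus hidden provenance (never used downstream)."""
    library: str
    sequences: List[str]
    ids: List[str]
    provenance: List[Tuple[str, str, int, str]]  # clone, chrom, start, strand

    def __len__(self) -> int:
        return len(self.sequences)


def clone_sequences(pair: ParentalGenomePair,
                    segregant: Segregant) -> Dict[str, str]:
    """Assemble the mosaic chromosome sequences of one segregant."""
    out = {}
    for chrom, intervals in segregant.mosaic.items():
        parts = []
        for a0, a1, label in intervals:
            if label == "A":
                parts.append(pair.genome_a[chrom][a0:a1])
            else:
                b0 = pair.project_a_to_b(chrom, a0)
                b1 = pair.project_a_to_b(chrom, a1)
                parts.append(pair.genome_b[chrom][b0:b1])
        out[chrom] = "".join(parts)
    return out


def _reads_from_sequences(chrom_seqs: Dict[str, str], clone_id: str,
                          coverage: float, config: SimulationConfig,
                          rng: np.random.Generator,
                          library: str, start_index: int,
                          out: ReadSet) -> int:
    rl = config.read_length
    usable = {c: len(s) - rl + 1 for c, s in chrom_seqs.items() if len(s) >= rl}
    if not usable:
        return start_index
    total_len = sum(len(s) for s in chrom_seqs.values())
    n_reads = int(round(coverage * total_len / rl))
    if n_reads == 0:
        return start_index
    chroms = list(usable)
    probs = np.array([len(chrom_seqs[c]) for c in chroms], dtype=float)
    probs /= probs.sum()
    per_chrom = rng.multinomial(n_reads, probs)
    err = config.sequencing_error_rate
    idx = start_index
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        seq = chrom_seqs[chrom]
        starts = rng.integers(0, usable[chrom], n)
        rev = rng.random(n) < 0.5
        n_errs = rng.binomial(rl, err, n) if err > 0 else np.zeros(n, dtype=int)
        for s, is_rev, ne in zip(starts, rev, n_errs):
            s = int(s)
            read = seq[s:s + rl]
            if is_rev:
                read = revcomp(read)
            if ne:
                rl_positions = rng.integers(0, rl, ne)
                lst = list(read)
                _substitute_positions(lst, rl_positions, rng)
                read = "".join(lst)
            out.sequences.append(read)
            out.ids.append(f"{library}:{idx}")
            out.provenance.append((clone_id, chrom, s, "-" if is_rev else "+"))
            idx += 1
    return idx


def simulate_pool_reads(pair: ParentalGenomePair, segregants: SegregantSet,
                        pools: PoolDesign,
                        config: SimulationConfig) -> Dict[str, ReadSet]:
    """Reads for each pool, clones weighted equally (optional dispersion)."""
    by_id = {s.segregant_id: s for s in segregants}
    out: Dict[str, ReadSet] = {}
    for pi, (lib, members) in enumerate(sorted(pools.pools.items())):
        rng = np.random.default_rng([config.seed % 2**31, 17, pi])
        rs = ReadSet(lib, [], [], [])
        if config.clone_weight_dispersion > 0 and members:
            d = config.clone_weight_dispersion
            w = rng.gamma(1.0 / d, d, len(members))
            weights = w / w.mean()
        else:
            weights = np.ones(len(members))
        idx = 0
        for clone_id, w in zip(members, weights):
            seqs = clone_sequences(pair, by_id[clone_id])
            idx = _reads_from_sequences(seqs, clone_id,
                                        config.per_clone_coverage * float(w),
                                        config, rng, lib, idx, rs)
        out[lib] = rs
    return out


def simulate_parent_reads(pair: ParentalGenomePair,
                          config: SimulationConfig) -> Dict[str, ReadSet]:
    """Reads for the two parental libraries (single non-recombinant clone)."""
    out: Dict[str, ReadSet] = {}
    for pi, (lib, genome) in enumerate(
            [("parent_A", pair.genome_a), ("parent_B", pair.genome_b)]):
        rng = np.random.default_rng([config.seed % 2**31, 19, pi])
        rs = ReadSet(lib, [], [], [])
        _reads_from_sequences(dict(genome), lib, config.parent_coverage,
                              config, rng, lib, 0, rs)
        out[lib] = rs
    return out


def simulate_reads(source, pair: ParentalGenomePair,
                   config: SimulationConfig,
                   segregants: Optional[SegregantSet] = None) -> Dict[str, ReadSet]:
    """Dispatch: a PoolDesign yields pool libraries, a ParentalGenomePair
    (passed as ``source``) yields the two parental libraries."""
    if isinstance(source, PoolDesign):
        if segregants is None:
            raise ValueError("pool read simulation needs the SegregantSet")
        return simulate_pool_reads(pair, segregants, source, config)
    if isinstance(source, ParentalGenomePair):
        return simulate_parent_reads(source, config)
    raise TypeError(f"cannot simulate reads from {type(source).__name__}")
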