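"""Unit tests for the synthetic-cross generator."""

import dataclasses
import math

import numpy as np
import pytest

from bsamap import (PoolError, SimulationConfig, build_pools, clone_sequences,
                    generate_parental_pair, plant_causal_frameshift, revcomp,
                    simulate_cross, simulate_parent_reads, simulate_pool_reads,
                    translate_orf)
from bsamap.config import ConfigError
from bsamap.simulate import delete_base_b


def test_zero_divergence_genomes_identical_outside_insertion(small_config):
    cfg = dataclasses.replace(small_config, divergence_rate=0.0,
                              micro_indel_rate=0.0)
    pair = generate_parental_pair(cfg)
    mut = pair.causal
    for chrom in pair.chromosomes:
        a, b = pair.genome_a[chrom], pair.genome_b[chrom]
        if chrom == mut.chrom:
            assert b[:mut.genomic_pos] == a[:mut.genomic_pos]
            assert b[mut.genomic_pos + 1:] == a[mut.genomic_pos:]
        else:
            assert a == b


def test_divergence_rate_recovered_over_truth_alignment(small_config):
    """Mismatch fraction over aligned orthologous positions ~ 10%."""
    cfg = dataclasses.replace(small_config, n_chromosomes=7,
                              genes_per_chromosome=10, seed=7)
    pair = generate_parental_pair(cfg)
    mismatches = total = 0
    for chrom, blocks in pair.blocks.items():
        for a0, a1, b0, b1 in blocks:
            sa = pair.genome_a[chrom][a0:a1]
            sb = pair.genome_b[chrom][b0:b1]
            assert len(sa) == len(sb)
            mismatches += sum(x != y for x, y in zip(sa, sb))
            total += len(sa)
    assert total > 30_000
    assert abs(mismatches / total - cfg.divergence_rate) < 0.01


def test_generation_is_deterministic(small_config):
    p1 = generate_parental_pair(small_config)
    p2 = generate_parental_pair(small_config)
    assert p1.genome_a == p2.genome_a
    assert p1.genome_b == p2.genome_b
    assert p1.genes_b == p2.genes_b
    assert p1.blocks == p2.blocks


def test_all_noncausal_orfs_stay_intact(small_pair, small_config):
    for gid, gene in small_pair.genes_b.items():
        cds = gene.cds(small_pair.genome_b)
        if gid == small_config.causal_gene:
            continue
        tr = translate_orf(cds)
        assert not tr.non_atg_start
        assert tr.length == len(cds) // 3 - 1, f"{gid} truncated"


def test_causal_insertion_truth_and_inverse(small_pair, small_config):
    mut = small_pair.causal
    assert mut.gene_id == small_config.causal_gene
    cds_b = small_pair.genes_b[mut.gene_id].cds(small_pair.genome_b)
    assert len(cds_b) == small_config.causal_cds_length + 1
    assert cds_b[mut.cds_offset - 1] == mut.inserted_base
    # deleting the inserted base restores the pre-insertion chromosome
    restored = delete_base_b(small_pair, mut.chrom, mut.genomic_pos)
    again = plant_causal_frameshift(restored, mut.gene_id, mut.cds_offset)
    assert again.genome_b[mut.chrom] == small_pair.genome_b[mut.chrom]
    assert again.genes_b == small_pair.genes_b


def test_insertion_offset_outside_cds_rejected(small_pair, small_config):
    with pytest.raises(ValueError, match="outside CDS"):
        plant_causal_frameshift(small_pair, small_config.causal_gene, 10_000)


def test_frameshifted_translation_matches_hand_derivation():
    """CDS ATGAAATAA with a T inserted after position 4 reads ATGA-T-AATAA."""
    assert translate_orf("ATGAAATAA").protein == "MK"
    mutant = "ATGA" + "T" + "AATAA"
    tr = translate_orf(mutant)
    assert tr.protein != "MK"
    assert tr.protein == "MII"  # ATG ATA ATA, trailing A ignored
    assert tr.stopless and tr.trailing_bases


def test_no_recombination_inherits_whole_chromosomes(small_pair, small_config):
    cfg = dataclasses.replace(small_config, crossovers_per_chromosome=0.0,
                              n_segregants=40)
    segregants = simulate_cross(small_pair, cfg)
    for s in segregants:
        for chrom, intervals in s.mosaic.items():
            assert len(intervals) == 1
            label = intervals[0][2]
            for gid, g in small_pair.genes_a.items():
                if g.chrom == chrom:
                    assert s.genotype_at_gene(small_pair, gid) == label


def test_full_penetrance_phenotype_equals_genotype(small_pair, small_config):
    segregants = simulate_cross(small_pair, small_config)
    for s in segregants:
        carrier = s.genotype_at_gene(small_pair, small_config.causal_gene) == "A"
        assert (s.phenotype == "switcher") == carrier


def test_segregation_is_mendelian(small_pair, small_config):
    """Each locus inherits the A allele at frequency ~0.5."""
    cfg = dataclasses.replace(small_config, n_segregants=400)
    segregants = simulate_cross(small_pair, cfg)
    for gid in small_pair.genes_a:
        freq = np.mean([s.genotype_at_gene(small_pair, gid) == "A"
                        for s in segregants])
        assert abs(freq - 0.5) < 0.1


def test_coinheritance_matches_uniform_crossover_model():
    """Recombination fraction between two loci follows the closed form
    P_rec = (1 - exp(-2 * lambda * d / L)) / 2 for Poisson(lambda)
    crossovers placed uniformly."""
    cfg = SimulationConfig(
        n_chromosomes=1, genes_per_chromosome=2,
        gene_length_range=(300, 360), intergenic_length_range=(19_000, 21_000),
        causal_gene=None, mating_type_locus="c1g01",
        n_segregants=10_000, pool_sizes=(0, 0, 0, 0),
        crossovers_per_chromosome=1.0, micro_indel_rate=0.0, seed=11)
    pair = generate_parental_pair(cfg)
    segregants = simulate_cross(pair, cfg)
    g1, g2 = pair.genes_a["c1g01"], pair.genes_a["c1g02"]
    L = len(pair.genome_a["chr1"])
    d = abs((g2.start + g2.end) / 2 - (g1.start + g1.end) / 2)
    expected = (1 - math.exp(-2 * 1.0 * d / L)) / 2
    rec = np.mean([
        s.genotype_at_gene(pair, "c1g01") != s.genotype_at_gene(pair, "c1g02")
        for s in segregants])
    se = math.sqrt(expected * (1 - expected) / len(segregants))
    assert abs(rec - expected) < 4 * se + 0.005


def test_incompatibility_pair_never_survives(small_pair, small_config):
    cfg = dataclasses.replace(small_config, incompatibility_pair=("c1g01", "c2g03"),
                              n_segregants=120)
    segregants = simulate_cross(small_pair, cfg)
    assert len(segregants) == 120
    for s in segregants:
        lethal = (s.genotype_at_gene(small_pair, "c1g01") == "A"
                  and s.genotype_at_gene(small_pair, "c2g03") == "B")
        assert not lethal


def test_pools_have_exact_sizes(small_cross):
    segregants, pools = small_cross
    assert {k: len(v) for k, v in pools.pools.items()} == {
        "SW_alpha": 8, "NS_alpha": 8, "SW_a": 8, "NS_a": 8}
    all_ids = [sid for members in pools.pools.values() for sid in members]
    assert len(all_ids) == len(set(all_ids))  # at most one pool each


def test_pool_exhaustion_reports_the_failing_pool(small_pair, small_config):
    segregants = simulate_cross(small_pair, small_config)
    with pytest.raises(PoolError, match="NS_a"):
        build_pools(segregants, (8, 8, 8, 5_000), small_config.seed)


def test_empty_pool_is_allowed(small_pair, small_config):
    segregants = simulate_cross(small_pair, small_config)
    pools = build_pools(segregants, (0, 8, 8, 8), small_config.seed)
    assert pools.pools["SW_alpha"] == []


def test_error_free_parent_reads_are_exact_substrings(small_pair, small_config):
    cfg = dataclasses.replace(small_config, sequencing_error_rate=0.0)
    reads = simulate_parent_reads(small_pair, cfg)["parent_A"]
    genome = small_pair.genome_a
    for seq, (clone, chrom, start, strand) in zip(reads.sequences,
                                                  reads.provenance):
        window = genome[chrom][start:start + cfg.read_length]
        assert seq == (window if strand == "+" else revcomp(window))


def test_read_count_matches_coverage_expectation(small_pair, small_config):
    cfg = dataclasses.replace(small_config, parent_coverage=10.0)
    reads = simulate_parent_reads(small_pair, cfg)["parent_A"]
    genome_len = sum(len(s) for s in small_pair.genome_a.values())
    expected = 10.0 * genome_len / cfg.read_length
    assert abs(len(reads) - expected) <= 0.01 * expected


def test_read_simulation_deterministic_and_conserved(small_pair, small_config,
                                                     small_cross):
    segregants, pools = small_cross
    r1 = simulate_pool_reads(small_pair, segregants, pools, small_config)
    r2 = simulate_pool_reads(small_pair, segregants, pools, small_config)
    for lib in r1:
        assert r1[lib].sequences == r2[lib].sequences
        assert r1[lib].ids == r2[lib].ids
        # every emitted read is accounted to a pooled clone
        clones = {p[0] for p in r1[lib].provenance}
        assert clones <= set(pools.pools[lib])


def test_clone_sequences_tile_to_parent_lengths(small_pair, small_cross):
    segregants, _ = small_cross
    s = segregants.segregants[0]
    seqs = clone_sequences(small_pair, s)
    for chrom in small_pair.chromosomes:
        la = len(small_pair.genome_a[chrom])
        lb = len(small_pair.genome_b[chrom])
        assert min(la, lb) - 5 <= len(seqs[chrom]) <= max(la, lb) + 5


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(divergence_rate=1.5).validate()
    with pytest.raises(ConfigError):
        SimulationConfig(n_segregants=100).validate()  # pools sum to 152
    with pytest.raises(ConfigError):
        SimulationConfig(causal_gene="c99g01").validate()
    with pytest.raises(ConfigError):
        SimulationConfig(gene_length_range=(3, 6)).validate()
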