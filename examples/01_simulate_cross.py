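"""Simulate an interspecies cross with a planted causal frameshift.

Builds a small genome pair (2 chromosomes x 3 genes) at 10% divergence,
crosses them, and shows the ground truth the generator records: the causal
insertion, segregant phenotypes, and the four phenotype x mating-type pools.
"""

from bsamap import SimulationConfig, build_pools, generate_parental_pair, simulate_cross

config = SimulationConfig(
    n_chromosomes=2, genes_per_chromosome=3,
    gene_length_range=(300, 450), intergenic_length_range=(120, 240),
    causal_gene="c2g02", causal_cds_length=399, causal_insertion_offset=200,
    mating_type_locus="c1g02", n_segregants=80, pool_sizes=(8, 8, 8, 8),
    seed=5)

pair = generate_parental_pair(config)
print("chromosome lengths A:", {c: len(s) for c, s in pair.genome_a.items()})
print("chromosome lengths B:", {c: len(s) for c, s in pair.genome_b.items()})
print("planted mutation:", pair.causal)
# The causal record says which gene carries the extra base, at which 1-based
# CDS position, and where it sits genomically in genome B.

segregants = simulate_cross(pair, config)
n_sw = sum(s.phenotype == "switcher" for s in segregants)
print(f"\n{len(segregants)} segregants, {n_sw} switchers "
      f"({n_sw / len(segregants):.0%}; ~50% expected: one causal locus)")

pools = build_pools(segregants, config.pool_sizes, config.seed)
for lib, members in sorted(pools.pools.items()):
    print(f"pool {lib}: {len(members)} clones, e.g. {members[:3]}")
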