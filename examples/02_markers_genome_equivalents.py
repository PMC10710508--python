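"""Genome equivalents and species counts from SC-RBP marker genes.

The mean count of the 16 single-copy ribosomal proteins estimates how
many genomes a metagenome sampled; greedy 99%-identity clustering of the
L3/L4/L6/S8 pools estimates how many species.
"""

from glycomet.markers import (
    cluster_marker_genes,
    genome_equivalents,
    species_count,
)
from glycomet.synthetic import make_community, make_genes, make_marker_pools

community = make_community(n_species=6, seed=4)
genes, _ = make_genes(community, n_reads=300, seed=5)

ge = genome_equivalents(genes)
print(f"genome equivalents (mean SC-RBP count): {ge:.2f}")
print("  -> the denominator for every per-microbial-genome normalization")

pools = make_marker_pools(community, copies_per_species=3, seed=6)
print(f"\ntrue species in the community: {community.n_species}")
for marker, pool in pools.items():
    n = len(cluster_marker_genes(pool, 99.0))
    print(f"  {marker}: {len(pool)} sequences -> {n} clusters")
print(f"species count (mean over L3/L4/L6/S8): {species_count(pools):.2f}")
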