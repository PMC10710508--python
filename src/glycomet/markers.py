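"""Single-copy ribosomal protein (SC-RBP) marker-gene bookkeeping.

Sixteen universal single-copy ribosomal protein genes serve as proxies:
the mean count of the 16 markers in a metagenome estimates the number of
genomes sequenced (genome equivalents, the denominator for per-genome
normalization), and greedy identity clustering of the four species-level
markers L3, L4, L6 and S8 estimates the species count. Community
composition profiles are built on the L6 clusters, with a majority-vote
taxonomy per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .io_formats import GeneRecord
from .taxonomy import TaxonomyTree, lca

__all__ = [
    "SC_RBP_NAMES",
    "SPECIES_MARKERS",
    "MarkerGeneSet",
    "GeneCluster",
    "genome_equivalents",
    "pairwise_identity",
    "cluster_marker_genes",
    "species_count",
    "majority_vote",
    "composition_profile",
]

# The canonical 16 single-copy ribosomal proteins used for genome counting
# and concatenated-marker phylogenetics.
SC_RBP_NAMES: tuple[str, ...] = (
    "L2", "L3", "L4", "L5", "L6", "L14", "L15", "L16",
    "L18", "L22", "L24", "S3", "S8", "S10", "S17", "S19",
)

# Species-delineating subset, clustered at gene-specific ANI thresholds.
SPECIES_MARKERS: tuple[str, ...] = ("L3", "L4", "L6", "S8")


@dataclass(frozen=True)
class MarkerGeneSet:
    """The marker configuration: names, species subset and per-marker ANI
    clustering thresholds (percent identity; default 99.0 for all four)."""

    marker_names: tuple[str, ...] = SC_RBP_NAMES
    species_subset: tuple[str, ...] = SPECIES_MARKERS
    ani_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {m: 99.0 for m in SPECIES_MARKERS}
    )

    def __post_init__(self) -> None:
        if not set(self.species_subset) <= set(self.marker_names):
            raise ValueError("species_subset must be a subset of marker_names")
        for m, t in self.ani_thresholds.items():
            if not 0.0 < t <= 100.0:
                raise ValueError(f"ANI threshold for {m} outside (0, 100]")


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    member_gene_ids: frozenset
    centroid_gene_id: str
    taxid: int | None = None

    def __post_init__(self) -> None:
        if not self.member_gene_ids:
            raise ValueError("cluster has no members")
        if self.centroid_gene_id not in self.member_gene_ids:
            raise ValueError("centroid must be a member")


def genome_equivalents(
    genes: Iterable[GeneRecord],
    markers: MarkerGeneSet = MarkerGeneSet(),
    weights: Mapping[str, float] | None = None,
) -> float:
    """Mean per-marker count (or summed weight) over the 16 SC-RBP names.

    Counting is the primary definition; passing per-gene ``weights``
    (e.g. sequencing depth) gives the depth-weighted reading instead.
    Raises if no marker gene is present at all.
    """
    totals = {m: 0.0 for m in markers.marker_names}
    for g in genes:
        for m in markers.marker_names:
            if m in g.labels:
                totals[m] += weights[g.gene_id] if weights is not None else 1.0
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no SC-RBP marker genes present; genome equivalents undefined")
    return grand / len(markers.marker_names)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
# free end gaps: identity is judged on the overlapping aligned region
_aligner.end_insertion_score = 0
_aligner.end_deletion_score = 0


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of a global, end-gap-free pairwise alignment.

    Scoring: match +1, mismatch -1, gap -2, terminal gaps free. Identity is
    matches / alignment columns over ALL columns (end-gap columns
    included), so a spurious short overlap between unrelated sequences
    scores low rather than 100%.
    """
    if not a or not b:
        return 0.0
    aln = _aligner.align(a, b)[0]
    ta, qa = aln[0], aln[1]
    cols = len(ta)
    matches = sum(1 for x, y in zip(ta, qa) if x == y and x != "-")
    return 100.0 * matches / cols


def cluster_marker_genes(
    sequences: Mapping[str, str], threshold: float
) -> list[GeneCluster]:
    """Greedy centroid clustering of one marker's nucleotide sequences.

    Sequences are processed longest-first (ties broken by gene id); each
    joins the first existing centroid whose global-alignment identity is
    >= ``threshold`` percent, else founds a new cluster.
    """
    order = sorted(sequences, key=lambda gid: (-len(sequences[gid]), gid))
    centroids: list[str] = []
    members: list[list[str]] = []
    for gid in order:
        seq = sequences[gid]
        for i, cid in enumerate(centroids):
            if pairwise_identity(sequences[cid], seq) >= threshold:
                members[i].append(gid)
                break
        else:
            centroids.append(gid)
            members.append([gid])
    return [
        GeneCluster(
            cluster_id=f"cluster_{i}",
            member_gene_ids=frozenset(mem),
            centroid_gene_id=cid,
        )
        for i, (cid, mem) in enumerate(zip(centroids, members))
    ]


def species_count(
    pools: Mapping[str, Mapping[str, str]],
    markers: MarkerGeneSet = MarkerGeneSet(),
) -> float:
    """Mean cluster count over the four species markers (L3, L4, L6, S8)."""
    counts = []
    for m in markers.species_subset:
        if m not in pools:
            raise ValueError(f"missing sequence pool for species marker {m}")
        counts.append(
            len(cluster_marker_genes(pools[m], markers.ani_thresholds.get(m, 99.0)))
        )
    return sum(counts) / len(counts)


def majority_vote(taxids: Sequence[int], tree: TaxonomyTree) -> int:
    """Strictly most frequent taxid; ties resolve to the LCA of the tied."""
    if not taxids:
        raise ValueError("majority vote over an empty collection")
    counts = Counter(taxids)
    top = max(counts.values())
    tied = [t for t, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    return lca(tied, tree)


def assign_cluster_taxonomy(
    clusters: Iterable[GeneCluster],
    gene_taxids: Mapping[str, int | None],
    tree: TaxonomyTree,
) -> list[GeneCluster]:
    """Attach a majority-vote taxon to each cluster from its members'
    read-derived classifications (unclassified members abstain)."""
    out = []
    for c in clusters:
        votes = [
            gene_taxids[g]
            for g in sorted(c.member_gene_ids)
            if gene_taxids.get(g) is not None
        ]
        taxid = majority_vote(votes, tree) if votes else None
        out.append(
            GeneCluster(c.cluster_id, c.member_gene_ids, c.centroid_gene_id, taxid)
        )
    return out


def composition_profile(
    l6_clusters: Iterable[GeneCluster],
    weights: Mapping[str, float] | None = None,
) -> dict[int | None, float]:
    """Per-taxon relative abundance from L6 cluster weights.

    Each gene contributes weight 1 (metagenome mode) or its TPM
    (metatranscriptome mode); cluster weights are aggregated by cluster
    taxid and normalized to sum to 1.
    """
    by_taxon: dict[int | None, float] = {}
    for c in l6_clusters:
        w = sum(
            (weights[g] if weights is not None else 1.0)
            for g in c.member_gene_ids
        )
        by_taxon[c.taxid] = by_taxon.get(c.taxid, 0.0) + w
    total = sum(by_taxon.values())
    if total <= 0:
        raise ValueError("total L6 weight is zero; composition undefined")
    return {t: w / total for t, w in by_taxon.items()}
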