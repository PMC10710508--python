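"""Hit filtering and two-stage last-common-ancestor classification.

Long reads carry several predicted genes; each gene accumulates protein
alignment hits against a taxonomically labelled database. Classification
proceeds in two LCA stages: the filtered hits of one gene are reduced to a
single gene-level taxon, and the classified genes of one read are reduced
to a single read-level taxon, which is then propagated back onto all genes
of the read.

Threshold comparisons in the hit filter are strict (identity > 65,
e-value < 1e-10, query cover > 50 by default); boundary values are
rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit, GeneRecord

__all__ = [
    "TaxonomyTree",
    "HitFilter",
    "GeneClassification",
    "ReadClassification",
    "filter_hits",
    "lca",
    "classify_gene",
    "classify_read",
    "classify_all",
    "propagate_read_taxonomy",
]

UNCLASSIFIED = None  # sentinel taxid for unclassified genes/reads


class TaxonomyTree:
    """A rooted taxonomy: ``nodes[taxid] = (parent_taxid, rank, name)``.

    The root is the unique node whose parent is itself. Construction
    validates single-rootedness and that every ancestor chain terminates
    at the root (no cycles, no orphans).
    """

    def __init__(self, nodes: Mapping[int, tuple[int, str, str]]):
        self.nodes = dict(nodes)
        roots = [t for t, (p, _, _) in self.nodes.items() if p == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for taxid in self.nodes:
            self._walk_to_root(taxid)

    def _walk_to_root(self, taxid: int) -> None:
        seen = set()
        node = taxid
        while node != self.root:
            if node in seen:
                raise ValueError(f"cycle in taxonomy at taxid {node}")
            seen.add(node)
            parent = self.nodes.get(node, (None,))[0]
            if parent is None or parent not in self.nodes:
                raise ValueError(f"taxid {node} has no parent in the tree")
            node = parent

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid][0]

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid][1]

    def name(self, taxid: int) -> str:
        return self.nodes[taxid][2]

    def path_to_root(self, taxid: int) -> list[int]:
        """Ancestor chain ``[taxid, ..., root]`` (self-inclusive)."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def depth(self, taxid: int) -> int:
        return len(self.path_to_root(taxid)) - 1

    def lineage(self, taxid: int) -> str:
        """Human-readable root-to-taxon lineage string."""
        return ";".join(
            self.name(t) for t in reversed(self.path_to_root(taxid))
        )

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The ancestor-or-self with the given rank, or None if the
        classification sits above that rank."""
        for t in self.path_to_root(taxid):
            if self.rank(t) == rank:
                return t
        return None

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        return ancestor in self.path_to_root(taxid)


@dataclass(frozen=True)
class HitFilter:
    """Secondary alignment-hit filter; all comparisons strict."""

    min_identity: float = 65.0
    max_evalue: float = 1e-10
    min_query_cover: float = 50.0

    def __post_init__(self) -> None:
        for v, name in (
            (self.min_identity, "min_identity"),
            (self.min_query_cover, "min_query_cover"),
        ):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} {v} outside [0, 100]")
        if not math.isfinite(self.max_evalue):
            raise ValueError("max_evalue must be finite")

    def keeps(self, hit: AlignmentHit) -> bool:
        return (
            hit.percent_identity > self.min_identity
            and hit.evalue < self.max_evalue
            and hit.query_coverage > self.min_query_cover
        )


@dataclass(frozen=True)
class GeneClassification:
    gene_id: str
    taxid: int | None  # None = unclassified
    n_hits_used: int


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    taxid: int | None
    n_genes_used: int


def filter_hits(
    hits: Iterable[AlignmentHit], f: HitFilter = HitFilter()
) -> list[AlignmentHit]:
    """Retain hits passing all three strict thresholds, order preserved."""
    return [h for h in hits if f.keeps(h)]


def lca(taxa: Iterable[int], tree: TaxonomyTree) -> int:
    """Deepest node that is an ancestor-or-self of every input taxon."""
    taxa = set(taxa)
    if not taxa:
        raise ValueError("lca of an empty taxon set is undefined")
    for t in taxa:
        if t not in tree:
            raise KeyError(f"unknown taxid {t}")
    it = iter(taxa)
    common = tree.path_to_root(next(it))
    common_set = set(common)
    for t in it:
        common_set &= set(tree.path_to_root(t))
    # path_to_root is ordered deepest-first; first member still common wins
    for node in common:
        if node in common_set:
            return node
    return tree.root  # unreachable: root is always common


def classify_gene(
    gene_hits: Sequence[AlignmentHit],
    f: HitFilter,
    tree: TaxonomyTree,
) -> GeneClassification:
    """LCA of subject taxids of the filtered hits of one gene."""
    ids = {h.query_gene_id for h in gene_hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple query genes: {sorted(ids)}")
    gene_id = next(iter(ids)) if ids else ""
    kept = filter_hits(gene_hits, f)
    if not kept:
        return GeneClassification(gene_id, UNCLASSIFIED, 0)
    taxid = lca({h.subject_taxid for h in kept}, tree)
    return GeneClassification(gene_id, taxid, len(kept))


def classify_read(
    read_id: str,
    gene_classifications: Iterable[GeneClassification],
    tree: TaxonomyTree,
) -> ReadClassification:
    """LCA over the CLASSIFIED genes of one read; unclassified genes are
    excluded so they cannot drag the read toward the root."""
    taxa = [g.taxid for g in gene_classifications if g.taxid is not UNCLASSIFIED]
    if not taxa:
        return ReadClassification(read_id, UNCLASSIFIED, 0)
    return ReadClassification(read_id, lca(taxa, tree), len(taxa))


def propagate_read_taxonomy(
    read: ReadClassification,
    genes: Sequence[GeneRecord],
    gene_classifications: Mapping[str, GeneClassification] | None = None,
) -> dict[str, int | None]:
    """Per-gene taxid table after read-level propagation.

    A classified read overrides per-gene calls for all its genes; for an
    unclassified read the genes keep their own gene-level classification.
    """
    if read.taxid is not UNCLASSIFIED:
        return {g.gene_id: read.taxid for g in genes}
    gene_classifications = gene_classifications or {}
    return {
        g.gene_id: (
            gene_classifications[g.gene_id].taxid
            if g.gene_id in gene_classifications
            else UNCLASSIFIED
        )
        for g in genes
    }


def classify_all(
    hits: Sequence[AlignmentHit],
    genes: Sequence[GeneRecord],
    tree: TaxonomyTree,
    f: HitFilter = HitFilter(),
) -> tuple[dict[str, GeneClassification], dict[str, ReadClassification], dict[str, int | None]]:
    """Run the full two-stage classification over a hit table.

    Returns (gene classifications, read classifications, propagated
    per-gene taxid table). Reads are taken from the ``parent_id`` of the
    gene annotation; genes without hits are unclassified.
    """
    hits_by_gene: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        hits_by_gene.setdefault(h.query_gene_id, []).append(h)

    gene_cls: dict[str, GeneClassification] = {}
    for g in genes:
        gh = hits_by_gene.get(g.gene_id, [])
        if gh:
            gene_cls[g.gene_id] = classify_gene(gh, f, tree)
        else:
            gene_cls[g.gene_id] = GeneClassification(g.gene_id, UNCLASSIFIED, 0)

    genes_by_read: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_read.setdefault(g.parent_id, []).append(g)

    read_cls: dict[str, ReadClassification] = {}
    propagated: dict[str, int | None] = {}
    for read_id, rgenes in genes_by_read.items():
        rc = classify_read(
            read_id, [gene_cls[g.gene_id] for g in rgenes], tree
        )
        read_cls[read_id] = rc
        propagated.update(propagate_read_taxonomy(rc, rgenes, gene_cls))
    return gene_cls, read_cls, propagated
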