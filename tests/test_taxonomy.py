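"""Hit filtering and two-stage LCA classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycomet.io_formats import AlignmentHit
from glycomet.synthetic import make_taxonomy
from glycomet.taxonomy import (
    HitFilter,
    TaxonomyTree,
    classify_gene,
    classify_read,
    filter_hits,
    lca,
    propagate_read_taxonomy,
)


def hit(gene="g1", taxid=11, ident=80.0, evalue=1e-20, qcov=70.0):
    return AlignmentHit(
        query_gene_id=gene,
        subject_id=f"ref{taxid}",
        percent_identity=ident,
        evalue=evalue,
        query_coverage=qcov,
        bitscore=200.0,
        subject_taxid=taxid,
    )


def lca_bruteforce(taxa, tree):
    """Independent oracle: intersect root-paths, take the deepest member."""
    common = set(tree.path_to_root(next(iter(taxa))))
    for t in taxa:
        common &= set(tree.path_to_root(t))
    return max(common, key=tree.depth)


class TestHitFilter:
    def test_passing_hit_retained(self):
        assert filter_hits([hit(ident=70, evalue=1e-20, qcov=60)]) == [
            hit(ident=70, evalue=1e-20, qcov=60)
        ]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ident": 65.0},  # boundary identity: strict >
            {"evalue": 1e-10},  # boundary e-value: strict <
            {"qcov": 50.0},  # boundary cover: strict >
            {"ident": 40.0},
            {"evalue": 1e-3},
            {"qcov": 10.0},
        ],
    )
    def test_boundary_and_failing_hits_discarded(self, kwargs):
        assert filter_hits([hit(**kwargs)]) == []

    def test_matches_bruteforce_predicate_on_random_hits(self):
        rng = np.random.default_rng(42)
        hits = [
            hit(
                ident=float(rng.uniform(0, 100)),
                evalue=float(10.0 ** rng.uniform(-30, 0)),
                qcov=float(rng.uniform(0, 100)),
            )
            for _ in range(1000)
        ]
        f = HitFilter()
        expected = [
            h
            for h in hits
            if h.percent_identity > 65 and h.evalue < 1e-10 and h.query_coverage > 50
        ]
        assert filter_hits(hits, f) == expected


class TestTreeStructure:
    def test_single_root_enforced(self):
        with pytest.raises(ValueError):
            TaxonomyTree({1: (1, "root", "r"), 2: (2, "root", "r2")})

    def test_orphan_parent_rejected(self):
        with pytest.raises(ValueError):
            TaxonomyTree({1: (1, "root", "r"), 2: (99, "phylum", "p")})

    def test_lineage_and_rank_walk(self, small_tree):
        assert small_tree.ancestor_at_rank(11, "genus") == 8
        assert small_tree.ancestor_at_rank(11, "family") == 6
        assert small_tree.ancestor_at_rank(3, "genus") is None


class TestLca:
    def test_singleton(self, small_tree):
        assert lca({11}, small_tree) == 11

    def test_siblings_meet_at_parent(self, small_tree):
        assert lca({11, 12}, small_tree) == 8

    def test_cross_family(self, small_tree):
        assert lca({11, 14}, small_tree) == 5

    def test_unknown_taxid_named_in_error(self, small_tree):
        with pytest.raises(KeyError, match="999"):
            lca({11, 999}, small_tree)

    def test_empty_set_rejected(self, small_tree):
        with pytest.raises(ValueError):
            lca(set(), small_tree)

    def test_idempotent_and_ancestor_containing(self, small_tree):
        # adding an ancestor of a member never deepens the result
        assert lca({11, 8}, small_tree) == 8
        assert lca({11, 12, 8}, small_tree) == 8

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n_species=st.integers(1, 40),
        set_size=st.integers(1, 6),
    )
    def test_matches_bruteforce_on_random_trees(self, seed, n_species, set_size):
        tree, species = make_taxonomy(n_species, seed)
        rng = np.random.default_rng(seed + 1)
        taxids = list(tree.nodes)
        picked = {taxids[i] for i in rng.integers(0, len(taxids), size=set_size)}
        assert lca(picked, tree) == lca_bruteforce(picked, tree)


class TestClassification:
    def test_unanimous_hits_give_species(self, small_tree):
        c = classify_gene([hit(taxid=11), hit(taxid=11)], HitFilter(), small_tree)
        assert c.taxid == 11 and c.n_hits_used == 2

    def test_no_surviving_hits_unclassified(self, small_tree):
        c = classify_gene([hit(ident=50.0)], HitFilter(), small_tree)
        assert c.taxid is None and c.n_hits_used == 0

    def test_congeneric_species_meet_at_genus(self, small_tree):
        c = classify_gene([hit(taxid=11), hit(taxid=12)], HitFilter(), small_tree)
        assert c.taxid == 8

    def test_mixed_query_ids_rejected(self, small_tree):
        with pytest.raises(ValueError):
            classify_gene(
                [hit(gene="a"), hit(gene="b")], HitFilter(), small_tree
            )

    def test_unclassified_genes_excluded_from_read_lca(self, small_tree):
        gene_cls = [
            classify_gene([hit(gene="a", taxid=11)], HitFilter(), small_tree),
            classify_gene([hit(gene="b", taxid=11)], HitFilter(), small_tree),
            classify_gene([hit(gene="c", ident=10.0)], HitFilter(), small_tree),
        ]
        rc = classify_read("r1", gene_cls, small_tree)
        assert rc.taxid == 11 and rc.n_genes_used == 2

    def test_read_with_no_classified_genes_unclassified(self, small_tree):
        gene_cls = [classify_gene([hit(ident=10.0)], HitFilter(), small_tree)]
        rc = classify_read("r1", gene_cls, small_tree)
        assert rc.taxid is None and rc.n_genes_used == 0

    def test_read_lca_order_invariant(self, small_tree):
        cls = [
            classify_gene([hit(gene=g, taxid=t)], HitFilter(), small_tree)
            for g, t in [("a", 11), ("b", 13), ("c", 12)]
        ]
        fwd = classify_read("r", cls, small_tree)
        rev = classify_read("r", cls[::-1], small_tree)
        assert fwd == rev


class TestPropagation:
    def test_classified_read_overrides_genes(self, small_tree, gene_factory):
        from glycomet.taxonomy import ReadClassification

        genes = [gene_factory(gene_id=f"g{i}", ordinal=i) for i in range(7)]
        table = propagate_read_taxonomy(
            ReadClassification("r0", 8, 7), genes
        )
        assert table == {f"g{i}": 8 for i in range(7)}

    def test_unclassified_read_keeps_gene_calls(self, small_tree, gene_factory):
        from glycomet.taxonomy import GeneClassification, ReadClassification

        genes = [gene_factory(gene_id="g0"), gene_factory(gene_id="g1", ordinal=1)]
        gene_cls = {"g0": GeneClassification("g0", 13, 1)}
        table = propagate_read_taxonomy(
            ReadClassification("r0", None, 0), genes, gene_cls
        )
        assert table == {"g0": 13, "g1": None}

    def test_propagation_never_loses_classified_genes(self, small_tree):
        """Count of classified genes never decreases after propagation."""
        from glycomet.synthetic import make_community, make_genes, make_hits
        from glycomet.taxonomy import classify_all

        community = make_community(n_species=10, seed=3)
        genes, truth = make_genes(community, 50, seed=4)
        hits = make_hits(community, genes, truth, noise=0.3, seed=5)
        gene_cls, _, propagated = classify_all(hits, genes, community.tree)
        before = sum(1 for c in gene_cls.values() if c.taxid is not None)
        after = sum(1 for t in propagated.values() if t is not None)
        assert after >= before
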