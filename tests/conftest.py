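import pytest

from glycomet.io_formats import GeneRecord
from glycomet.taxonomy import TaxonomyTree


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """A fixed seven-rank toy taxonomy.

    root(1) - domain(2) - phylum(3) - class(4) - order(5)
      order 5 -> families 6, 7
      family 6 -> genera 8, 9 ; family 7 -> genus 10
      genus 8 -> species 11, 12 ; genus 9 -> species 13 ; genus 10 -> species 14
    """
    nodes = {
        1: (1, "root", "root"),
        2: (1, "domain", "Bacteria"),
        3: (2, "phylum", "Bacteroidota"),
        4: (3, "class", "Bacteroidia"),
        5: (4, "order", "Flavobacteriales"),
        6: (5, "family", "Flavobacteriaceae"),
        7: (5, "family", "Crocinitomicaceae"),
        8: (6, "genus", "Aurantivirga"),
        9: (6, "genus", "Polaribacter"),
        10: (7, "genus", "Fluviicola"),
        11: (8, "species", "Aurantivirga sp1"),
        12: (8, "species", "Aurantivirga sp2"),
        13: (9, "species", "Polaribacter sp1"),
        14: (10, "species", "Fluviicola sp1"),
    }
    return TaxonomyTree(nodes)


def make_gene(gene_id="g0", parent="r0", ordinal=0, length=900, labels=()):
    return GeneRecord(
        gene_id=gene_id,
        parent_id=parent,
        ordinal=ordinal,
        length_bp=length,
        labels=frozenset(labels),
    )


@pytest.fixture
def gene_factory():
    return make_gene
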