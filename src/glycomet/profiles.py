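"""Community-level functional profiling.

Gene-family abundances are normalized by the sample's genome equivalents
(PMG — per microbial genome), converted to relative shares, and attributed
to taxa at a chosen rank by walking each classified gene's lineage.
MAG-level gene-group summaries normalize counts by genome size (Mbp).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .io_formats import GeneRecord
from .pul import cazyme_class
from .taxonomy import TaxonomyTree

__all__ = [
    "family_abundance_pmg",
    "family_shares",
    "family_taxon_breakdown",
    "gene_group_summary",
    "cazyme_family_counts",
    "UNRESOLVED",
]

UNRESOLVED = "unresolved"


def cazyme_family_counts(
    genes: Iterable[GeneRecord],
    classes: Iterable[str] | None = None,
    collapse_subfamilies: bool = False,
) -> dict[str, float]:
    """Count genes per CAZyme family label.

    ``classes`` restricts to given CAZyme classes (default: all annotated
    classes, CBM included). Sub-family labels (GH16_3) stay distinct unless
    ``collapse_subfamilies`` folds them into the parent family (GH16).
    """
    classes = set(classes) if classes is not None else None
    counts: dict[str, float] = {}
    for g in genes:
        for lab in g.labels:
            cls = cazyme_class(lab)
            if cls is None:
                continue
            if classes is not None and cls not in classes:
                continue
            fam = lab.split("_")[0] if collapse_subfamilies else lab
            counts[fam] = counts.get(fam, 0.0) + 1.0
    return counts


def family_abundance_pmg(
    gene_counts: Mapping[str, float], genome_equiv: float
) -> dict[str, float]:
    """Per-family gene count normalized per microbial genome (PMG)."""
    if genome_equiv <= 0:
        raise ValueError(f"genome equivalents must be positive, got {genome_equiv}")
    return {f: c / genome_equiv for f, c in gene_counts.items()}


def family_shares(values: Mapping[str, float]) -> dict[str, float]:
    """Relative proportions of per-family abundance or TPM (sum to 1)."""
    total = sum(values.values())
    if total <= 0:
        raise ValueError("total family value is zero; shares undefined")
    return {f: v / total for f, v in values.items()}


def family_taxon_breakdown(
    gene_taxids: Mapping[str, int | None],
    weights: Mapping[str, float],
    rank: str,
    tree: TaxonomyTree,
) -> dict[str, float]:
    """Per-taxon shares of one family's genes at a chosen rank.

    Each gene's weight (count 1 or TPM) is attributed to its ancestor at
    ``rank``; genes classified above that rank (or unclassified) pool into
    the ``unresolved`` bucket. Shares sum to 1.
    """
    agg: dict[str, float] = {}
    for gid, taxid in gene_taxids.items():
        w = weights.get(gid, 0.0)
        if taxid is None:
            key = UNRESOLVED
        else:
            at_rank = tree.ancestor_at_rank(taxid, rank)
            key = tree.name(at_rank) if at_rank is not None else UNRESOLVED
        agg[key] = agg.get(key, 0.0) + w
    total = sum(agg.values())
    if total <= 0:
        raise ValueError("total weight is zero; breakdown undefined")
    return {k: v / total for k, v in agg.items()}


_GROUP_LABELS = {
    "CAZyme": lambda labels: any(cazyme_class(lab) for lab in labels),
    "sulfatase": lambda labels: "sulfatase" in labels,
    "peptidase": lambda labels: "peptidase" in labels,
    "TBDT": lambda labels: "TBDT" in labels or "susC" in labels,
}


def gene_group_summary(
    mag_genes: Sequence[GeneRecord],
    tpms: Mapping[str, float],
    genome_size_mbp: float,
    groups: Iterable[str] = ("CAZyme", "sulfatase", "peptidase", "TBDT"),
) -> dict:
    """Per-group gene density and transcription for one MAG.

    For each functional group: gene count per Mbp of genome and summed
    TPM; also reports the peptidase:CAZyme count ratio.
    """
    if genome_size_mbp <= 0:
        raise ValueError("genome size must be positive")
    out: dict[str, dict] = {}
    counts: dict[str, int] = {}
    for grp in groups:
        pred = _GROUP_LABELS[grp]
        members = [g for g in mag_genes if pred(g.labels)]
        counts[grp] = len(members)
        out[grp] = {
            "count": len(members),
            "count_per_mbp": len(members) / genome_size_mbp,
            "tpm_sum": sum(tpms.get(g.gene_id, 0.0) for g in members),
        }
    if counts.get("CAZyme"):
        out["peptidase_cazyme_ratio"] = (
            counts.get("peptidase", 0) / counts["CAZyme"]
        )
    else:
        out["peptidase_cazyme_ratio"] = None
    return out
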