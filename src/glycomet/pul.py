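"""Rule-based polysaccharide utilization locus (PUL) detection.

A PUL couples a SusC/SusD-like transport pair with degradative
carbohydrate-active enzymes. Detection runs on ordered gene annotations of
one contig and fires on either of two clauses:

1. an adjacent susC/susD gene pair (consecutive ordinals, either order)
   with at least two degradative CAZymes within ``max_gap`` intervening
   genes of the pair's boundary, or
2. at least three degradative CAZymes forming a chain in which consecutive
   members are separated by at most ``max_gap`` intervening genes.

Degradative CAZyme classes default to GH, PL and CE; carbohydrate-binding
modules (CBM) bind rather than cleave and do not count. Overlapping clause
hits merge into a single call spanning their union, so each gene belongs
to at most one PUL. Strand is ignored: the rule is symmetric under
reversal of gene order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneRecord

__all__ = [
    "DEGRADATIVE_CLASSES",
    "CAZYME_CLASSES",
    "Locus",
    "PulCall",
    "assign_roles",
    "detect_puls",
    "pul_transcription",
    "render_locus",
]

CAZYME_CLASSES = ("GH", "PL", "CE", "CBM", "GT", "AA")
DEGRADATIVE_CLASSES = frozenset({"GH", "PL", "CE"})

_CAZYME_RE = re.compile(r"^(GH|PL|CE|CBM|GT|AA)(\d+)(_\d+)?$")


def cazyme_class(label: str) -> str | None:
    """The CAZyme class of a family label, e.g. 'GH16_3' -> 'GH'."""
    m = _CAZYME_RE.match(label)
    return m.group(1) if m else None


@dataclass(frozen=True)
class LocusGene:
    """A gene of a locus with its PUL-relevant role flags."""

    gene: GeneRecord
    role: str  # susC | susD | degradative_cazyme | other
    is_susC: bool
    is_susD: bool
    is_degradative: bool  # counts toward CAZyme chains (clause 2)

    @property
    def ordinal(self) -> int:
        return self.gene.ordinal


@dataclass(frozen=True)
class Locus:
    contig_id: str
    genes: tuple[LocusGene, ...]  # ordered by strictly increasing ordinal

    def __post_init__(self) -> None:
        ords = [g.ordinal for g in self.genes]
        if any(b <= a for a, b in zip(ords, ords[1:])):
            raise ValueError("locus ordinals must be strictly increasing")


@dataclass(frozen=True)
class PulCall:
    contig_id: str
    member_gene_ids: tuple[str, ...]  # contiguous window, locus order
    clauses: frozenset  # subset of {"susCD_pair", "cazyme_cluster"}
    cazyme_families: tuple[str, ...]

    @property
    def trigger_clause(self) -> str:
        return "susCD_pair" if "susCD_pair" in self.clauses else "cazyme_cluster"


def assign_roles(
    genes: Sequence[GeneRecord],
    degradative_classes: Iterable[str] = DEGRADATIVE_CLASSES,
) -> Locus:
    """Derive per-gene PUL roles from functional labels.

    A gene carrying both a susC label and a degradative CAZyme family
    keeps the susC role for clause 1 but still counts as a CAZyme for
    clause 2 chains.
    """
    degradative_classes = frozenset(degradative_classes)
    if not genes:
        raise ValueError("empty gene list")
    contigs = {g.parent_id for g in genes}
    if len(contigs) > 1:
        raise ValueError(f"genes span multiple contigs: {sorted(contigs)}")
    out = []
    for g in sorted(genes, key=lambda g: g.ordinal):
        is_susC = "susC" in g.labels
        is_susD = "susD" in g.labels
        is_degr = any(
            (cazyme_class(lab) in degradative_classes) for lab in g.labels
        )
        if is_susC:
            role = "susC"
        elif is_susD:
            role = "susD"
        elif is_degr:
            role = "degradative_cazyme"
        else:
            role = "other"
        out.append(LocusGene(g, role, is_susC, is_susD, is_degr))
    return Locus(next(iter(contigs)), tuple(out))


def _clause1_spans(locus: Locus, max_gap: int) -> list[tuple[int, int]]:
    spans = []
    genes = locus.genes
    # degradative genes whose ROLE is degradative (pair members never count)
    caz = [g.ordinal for g in genes if g.role == "degradative_cazyme"]
    for a, b in zip(genes, genes[1:]):
        if b.ordinal - a.ordinal != 1:
            continue
        if not ((a.is_susC and b.is_susD) or (a.is_susD and b.is_susC)):
            continue
        lo, hi = a.ordinal, b.ordinal
        near = [
            c
            for c in caz
            if (c < lo and lo - c - 1 <= max_gap)
            or (c > hi and c - hi - 1 <= max_gap)
        ]
        if len(near) >= 2:
            spans.append((min([lo] + near), max([hi] + near)))
    return spans


def _clause2_spans(locus: Locus, max_gap: int) -> list[tuple[int, int]]:
    caz = [g.ordinal for g in locus.genes if g.is_degradative]
    spans = []
    chain = []
    for c in caz:
        if chain and c - chain[-1] - 1 > max_gap:
            if len(chain) >= 3:
                spans.append((chain[0], chain[-1]))
            chain = []
        chain.append(c)
    if len(chain) >= 3:
        spans.append((chain[0], chain[-1]))
    return spans


def detect_puls(locus: Locus, max_gap: int = 6) -> list[PulCall]:
    """Apply the two-clause PUL rule to one ordered locus."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    tagged = [(s, "susCD_pair") for s in _clause1_spans(locus, max_gap)]
    tagged += [(s, "cazyme_cluster") for s in _clause2_spans(locus, max_gap)]
    if not tagged:
        return []
    tagged.sort(key=lambda t: t[0])

    # merge ordinal-overlapping spans (shared genes => one call)
    merged: list[tuple[int, int, set]] = []
    for (lo, hi), clause in tagged:
        if merged and lo <= merged[-1][1]:
            plo, phi, clauses = merged[-1]
            merged[-1] = (plo, max(phi, hi), clauses | {clause})
        else:
            merged.append((lo, hi, {clause}))

    calls = []
    for lo, hi, clauses in merged:
        members = [g for g in locus.genes if lo <= g.ordinal <= hi]
        fams = sorted(
            {
                lab
                for g in members
                if g.is_degradative
                for lab in g.gene.labels
                if cazyme_class(lab) is not None
            }
        )
        calls.append(
            PulCall(
                contig_id=locus.contig_id,
                member_gene_ids=tuple(g.gene.gene_id for g in members),
                clauses=frozenset(clauses),
                cazyme_families=tuple(fams),
            )
        )
    return calls


def pul_transcription(
    pulcall: PulCall, tpms: Mapping[str, float]
) -> tuple[float, float]:
    """(sum, per-gene mean) TPM over the members of one PUL call."""
    missing = [g for g in pulcall.member_gene_ids if g not in tpms]
    if missing:
        raise KeyError(f"no TPM value for PUL member genes {missing}")
    vals = [tpms[g] for g in pulcall.member_gene_ids]
    return sum(vals), sum(vals) / len(vals)


def render_locus(locus: Locus, calls: Sequence[PulCall] = ()) -> str:
    """Plain-text locus diagram with PUL spans bracketed.

    Example: ``susC>-susD>-[GH16_3]-[GH17]-.`` with a second line marking
    PUL membership.
    """
    glyphs = []
    for g in locus.genes:
        if g.role == "susC":
            glyphs.append("susC")
        elif g.role == "susD":
            glyphs.append("susD")
        elif g.role == "degradative_cazyme":
            fams = [lab for lab in sorted(g.gene.labels) if cazyme_class(lab)]
            glyphs.append(fams[0] if fams else "CAZy")
        else:
            glyphs.append(".")
    line1 = "-".join(glyphs)
    in_pul = set()
    for call in calls:
        in_pul.update(call.member_gene_ids)
    marks = [
        ("^" * len(glyph) if g.gene.gene_id in in_pul else " " * len(glyph))
        for g, glyph in zip(locus.genes, glyphs)
    ]
    line2 = " ".join(marks)
    return f"{locus.contig_id}\n{line1}\n{line2}"
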