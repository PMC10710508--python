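"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: a taxonomy tree,
a multi-species community with Dirichlet relative abundances, per-gene
alignment-hit tables, per-base depth tracks, transcript counts, PUL-bearing
gene annotations, marker-gene sequence pools and glycan microarray signal
tables. Each generator is a pure function of its arguments and a seed —
identical inputs give identical outputs — and each emits a truth table
alongside, so recovery tests consume truth rather than re-deriving it.

``make_study`` composes everything into one coherent synthetic study
(8 samples at 2 depth layers by default) written as the plain-text files
the command-line pipeline reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import AlignmentHit, DepthInterval, GeneRecord
from .markers import SC_RBP_NAMES, SPECIES_MARKERS
from .taxonomy import TaxonomyTree

__all__ = [
    "RANKS",
    "CommunitySpec",
    "ExpressionSpec",
    "make_taxonomy",
    "make_community",
    "make_hits",
    "make_depth_tracks",
    "make_transcripts",
    "make_marker_pools",
    "make_marker_sequences_for_genes",
    "make_genes",
    "make_loci",
    "make_microarray",
    "make_study",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

# CAZyme families seen in marine particulate-organic-matter degraders;
# sub-families kept distinct from parents on purpose.
DEFAULT_CAZYME_CATALOG = (
    "GH16_3", "GH17", "GH30", "GH29", "GH95", "GH92", "GH13", "GH3",
    "PL7", "PL17", "PL6", "CE2", "CE6", "CBM32", "GT2", "AA3",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunitySpec:
    """A synthetic multi-species community with known ground truth."""

    tree: TaxonomyTree
    species_taxids: tuple[int, ...]
    abundances: tuple[float, ...]  # sums to 1, aligned with species_taxids
    genome_lengths: tuple[int, ...]
    cazyme_weights: tuple[dict, ...]  # per-species family -> weight
    seed: int

    @property
    def n_species(self) -> int:
        return len(self.species_taxids)

    def species_id(self, i: int) -> str:
        return f"sp{i:03d}"


@dataclass(frozen=True)
class ExpressionSpec:
    """Per-gene expected transcription rates and noise for count draws."""

    rates: Mapping[str, float]  # gene_id -> expected transcript rate (>= 0)
    # NB size parameter; variance = mu + mu^2/size. 100 models the mild
    # overdispersion of deeply sequenced metatranscriptomes.
    dispersion: float = 100.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")


def make_taxonomy(n_species: int, seed: int) -> tuple[TaxonomyTree, list[int]]:
    """Random rooted taxonomy with ranks domain..species.

    Level widths shrink roughly geometrically from species up; each node
    picks a random parent in the level above. Returns the tree and the
    species taxids in order.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    widths = []
    w = n_species
    for _ in RANKS[::-1]:  # species up to domain
        widths.append(w)
        w = max(1, math.ceil(w / 2))
    widths = widths[::-1]  # domain..species

    nodes: dict[int, tuple[int, str, str]] = {1: (1, "root", "root")}
    next_id = 2
    level_ids: list[list[int]] = []
    for rank, width in zip(RANKS, widths):
        ids = []
        parents = level_ids[-1] if level_ids else [1]
        for j in range(width):
            parent = int(parents[rng.integers(len(parents))])
            nodes[next_id] = (parent, rank, f"{rank}_{j}")
            ids.append(next_id)
            next_id += 1
        level_ids.append(ids)
    return TaxonomyTree(nodes), list(level_ids[-1])


def make_community(
    n_species: int = 20,
    seed: int = 0,
    concentration: float = 2.0,
    genome_length: int = 100_000,
    cazyme_catalog: Sequence[str] = DEFAULT_CAZYME_CATALOG,
) -> CommunitySpec:
    """Community with Dirichlet(concentration) relative abundances.

    Every species carries all 16 SC-RBP markers exactly once in its genome
    and a species-specific CAZyme family weighting used by the gene and
    transcript generators.
    """
    rng = np.random.default_rng(seed)
    tree, species = make_taxonomy(n_species, seed)
    ab = rng.dirichlet(np.full(n_species, concentration))
    lengths = tuple(int(genome_length) for _ in range(n_species))
    weights = []
    for _ in range(n_species):
        fams = rng.choice(len(cazyme_catalog), size=rng.integers(4, 9), replace=False)
        weights.append(
            {cazyme_catalog[f]: float(rng.uniform(0.5, 3.0)) for f in fams}
        )
    return CommunitySpec(
        tree=tree,
        species_taxids=tuple(int(s) for s in species),
        abundances=tuple(float(a) for a in ab),
        genome_lengths=lengths,
        cazyme_weights=tuple(weights),
        seed=int(seed),
    )


def _sample_reads(
    community: CommunitySpec, n_reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Species index per read, proportional to relative abundance."""
    return rng.choice(
        community.n_species, size=n_reads, p=np.asarray(community.abundances)
    )


def make_genes(
    community: CommunitySpec,
    n_reads: int,
    seed: int,
    genes_per_read: int = 5,
    p_marker: float = 0.10,
    p_cazyme: float = 0.15,
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Annotated genes on synthetic reads plus the read -> true-species
    taxid truth table.

    Each read carries ``genes_per_read`` genes; a gene is an SC-RBP marker
    with probability ``p_marker`` (uniform over the 16), a CAZyme of the
    species' weighted families with probability ``p_cazyme``, else drawn
    from sulfatase/peptidase/susC/susD/TBDT/other filler.
    """
    rng = np.random.default_rng(seed)
    assign = _sample_reads(community, n_reads, rng)
    other_tags = ("sulfatase", "peptidase", "susC", "susD", "TBDT", "other")
    genes: list[GeneRecord] = []
    truth: dict[str, int] = {}
    for i, sp in enumerate(assign):
        read_id = f"read{i:05d}"
        truth[read_id] = community.species_taxids[sp]
        fams = list(community.cazyme_weights[sp])
        for j in range(genes_per_read):
            u = rng.random()
            if u < p_marker:
                label = SC_RBP_NAMES[rng.integers(16)]
            elif u < p_marker + p_cazyme and fams:
                w = np.array([community.cazyme_weights[sp][f] for f in fams])
                label = fams[rng.choice(len(fams), p=w / w.sum())]
            else:
                label = other_tags[rng.integers(len(other_tags))]
            genes.append(
                GeneRecord(
                    gene_id=f"{read_id}_g{j}",
                    parent_id=read_id,
                    ordinal=j,
                    length_bp=int(rng.integers(300, 1500)),
                    labels=frozenset({label}),
                )
            )
    return genes, truth


def make_hits(
    community: CommunitySpec,
    genes: Sequence[GeneRecord],
    truth: Mapping[str, int],
    noise: float,
    seed: int,
    p_genus_level: float = 0.2,
) -> list[AlignmentHit]:
    """Alignment-hit table for synthetic genes.

    Each gene gets 1–5 hits to its true species' lineage (the species
    itself, or its genus with probability ``p_genus_level``) with
    filter-passing quality. A ``noise`` fraction of genes additionally get
    one off-lineage hit to a random other species, drawn as a
    characteristically weak alignment (identity U(45,70), e-value
    log-U(1e-12, 1e-5), cover U(20,70)) of the kind the secondary filter
    exists to remove.
    """
    rng = np.random.default_rng(seed)
    tree = community.tree
    genus_of = {
        s: tree.ancestor_at_rank(s, "genus") for s in community.species_taxids
    }
    hits: list[AlignmentHit] = []
    for g in genes:
        sp = truth[g.parent_id]
        for k in range(int(rng.integers(1, 6))):
            taxid = genus_of[sp] if rng.random() < p_genus_level else sp
            hits.append(
                AlignmentHit(
                    query_gene_id=g.gene_id,
                    subject_id=f"ref_{taxid}_{k}",
                    percent_identity=float(rng.uniform(70, 100)),
                    evalue=float(10.0 ** rng.uniform(-30, -15)),
                    query_coverage=float(rng.uniform(55, 100)),
                    bitscore=float(rng.uniform(100, 500)),
                    subject_taxid=int(taxid),
                )
            )
        if rng.random() < noise:
            others = [t for t in community.species_taxids if t != sp]
            off = int(others[rng.integers(len(others))])
            hits.append(
                AlignmentHit(
                    query_gene_id=g.gene_id,
                    subject_id=f"ref_{off}_x",
                    percent_identity=float(rng.uniform(45, 70)),
                    evalue=float(10.0 ** rng.uniform(-12, -5)),
                    query_coverage=float(rng.uniform(20, 70)),
                    bitscore=float(rng.uniform(40, 120)),
                    subject_taxid=off,
                )
            )
    return hits


def make_depth_tracks(
    community: CommunitySpec,
    total_genome_equivalents: float,
    poisson_noise: bool,
    seed: int,
) -> tuple[dict[str, list[DepthInterval]], dict[str, int], dict[str, float]]:
    """Per-genome depth tracks with truth relative abundances.

    Mean depth of species i = abundance_i x total_genome_equivalents.
    With ``poisson_noise`` per-base depths are Poisson draws around the
    mean, compressed to run-length intervals; otherwise one constant
    interval spans the genome. Returns (track, manifest, truth abundance).
    """
    rng = np.random.default_rng(seed)
    track: dict[str, list[DepthInterval]] = {}
    manifest: dict[str, int] = {}
    truth: dict[str, float] = {}
    for i in range(community.n_species):
        gid = community.species_id(i)
        length = community.genome_lengths[i]
        mean = community.abundances[i] * total_genome_equivalents
        manifest[gid] = length
        truth[gid] = community.abundances[i]
        if not poisson_noise:
            track[gid] = [DepthInterval(gid, 0, length, float(mean))]
            continue
        per_base = rng.poisson(mean, size=length)
        # run-length encode
        change = np.flatnonzero(np.diff(per_base)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [length]))
        track[gid] = [
            DepthInterval(gid, int(s), int(e), float(per_base[s]))
            for s, e in zip(starts, ends)
        ]
    return track, manifest, truth


def make_transcripts(
    genes: Sequence[GeneRecord],
    expression: ExpressionSpec,
    library_size: int,
    seed: int,
) -> tuple[dict[str, int], dict[str, float]]:
    """Negative-binomial transcript counts plus analytic truth TPM.

    Expected count of gene g is proportional to rate_g x length_g and the
    expectations sum to ``library_size``. Truth TPM comes from the rates
    directly: tpm_g = 1e6 x rate_g / sum of rates.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = np.random.default_rng(seed)
    rates = np.array([expression.rates[g.gene_id] for g in genes], dtype=float)
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    weight = rates * lengths
    if weight.sum() == 0:
        raise ValueError("all expression rates are zero")
    mu = library_size * weight / weight.sum()
    size = expression.dispersion
    # numpy's negative_binomial(n, p): mean = n(1-p)/p -> p = size/(size+mu)
    counts = np.where(
        mu > 0, rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-300))), 0
    )
    truth_tpm = 1e6 * rates / rates.sum()
    return (
        {g.gene_id: int(c) for g, c in zip(genes, counts)},
        {g.gene_id: float(t) for g, t in zip(genes, truth_tpm)},
    )


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    n_mut = rng.binomial(len(seq), divergence)
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[rng.integers(3)]
    return out


def make_marker_pools(
    community: CommunitySpec,
    copies_per_species: int,
    seed: int,
    marker_length: int = 600,
    within_divergence: float = 0.002,
    between_divergence: float = 0.05,
) -> dict[str, dict[str, str]]:
    """Nucleotide sequence pools for the four species markers.

    One ancestral sequence per marker; each species diverges from it by
    ``between_divergence`` substitutions. ``within_divergence`` is the
    expected PAIRWISE divergence between copies of one species, so each
    copy mutates at half that rate from the species consensus. Pools are
    keyed marker -> gene_id -> sequence; truth species count is the
    community's species number.
    """
    rng = np.random.default_rng(seed)
    pools: dict[str, dict[str, str]] = {}
    for m in SPECIES_MARKERS:
        base = _BASES[rng.integers(4, size=marker_length)]
        pool: dict[str, str] = {}
        for i in range(community.n_species):
            sp_seq = _mutate(base, between_divergence, rng)
            for c in range(copies_per_species):
                copy = _mutate(sp_seq, within_divergence / 2, rng)
                pool[f"{community.species_id(i)}_{m}_{c}"] = "".join(copy)
        pools[m] = pool
    return pools


def make_marker_sequences_for_genes(
    community: CommunitySpec,
    genes: Sequence[GeneRecord],
    truth: Mapping[str, int],
    seed: int,
    marker_length: int = 600,
    within_divergence: float = 0.002,
    between_divergence: float = 0.05,
) -> dict[str, dict[str, str]]:
    """Sequences for the species-marker genes of an annotated gene table.

    Genes labelled L3/L4/L6/S8 receive a nucleotide sequence derived from
    their true species' marker sequence (between-species divergence 5%,
    within-species 0.2% by default), keyed marker -> gene_id -> sequence.
    Gene ids match the annotation table so downstream cluster taxonomy can
    use the pipeline's own classifications.
    """
    rng = np.random.default_rng(seed)
    taxid_to_index = {t: i for i, t in enumerate(community.species_taxids)}
    base = {
        m: _BASES[rng.integers(4, size=marker_length)] for m in SPECIES_MARKERS
    }
    sp_seq = {
        (m, i): _mutate(base[m], between_divergence, rng)
        for m in SPECIES_MARKERS
        for i in range(community.n_species)
    }
    pools: dict[str, dict[str, str]] = {m: {} for m in SPECIES_MARKERS}
    for g in genes:
        for m in SPECIES_MARKERS:
            if m in g.labels:
                i = taxid_to_index[truth[g.parent_id]]
                pools[m][g.gene_id] = "".join(
                    _mutate(sp_seq[(m, i)], within_divergence / 2, rng)
                )
    return pools


def make_loci(
    pul_architectures: Sequence[Sequence[str]],
    n_filler_contigs: int,
    seed: int,
    flank: int = 4,
    cazyme_catalog: Sequence[str] = ("GH16_3", "GH17", "PL7", "GH29", "CE2"),
) -> tuple[list[GeneRecord], dict[str, tuple[int, int]]]:
    """Contigs embedding planted PUL role sequences among filler genes.

    Each architecture is a role sequence over {"susC", "susD", "cazyme",
    "other"}; planted contigs surround it with ``flank`` filler genes on
    each side. Truth maps contig_id -> (first, last) ordinal of the
    planted span. Filler-only contigs carry no PUL.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    truth: dict[str, tuple[int, int]] = {}
    filler_tags = ("other", "peptidase", "sulfatase", "GT2", "CBM32")

    def filler_label() -> str:
        return filler_tags[rng.integers(len(filler_tags))]

    for i, arch in enumerate(pul_architectures):
        contig = f"pul_contig{i:04d}"
        roles = ["_flank"] * flank + list(arch) + ["_flank"] * flank
        truth[contig] = (flank, flank + len(arch) - 1)
        for j, role in enumerate(roles):
            if role in ("_flank", "other"):
                label = filler_label()
            elif role == "cazyme":
                label = cazyme_catalog[rng.integers(len(cazyme_catalog))]
            else:
                label = role  # susC / susD
            genes.append(
                GeneRecord(
                    gene_id=f"{contig}_g{j}",
                    parent_id=contig,
                    ordinal=j,
                    length_bp=int(rng.integers(600, 2400)),
                    labels=frozenset({label}),
                )
            )
    for i in range(n_filler_contigs):
        contig = f"bg_contig{i:04d}"
        for j in range(int(rng.integers(5, 15))):
            genes.append(
                GeneRecord(
                    gene_id=f"{contig}_g{j}",
                    parent_id=contig,
                    ordinal=j,
                    length_bp=int(rng.integers(600, 2400)),
                    labels=frozenset({filler_label()}),
                )
            )
    return genes, truth


def make_microarray(
    samples: Sequence[str],
    antibodies: Sequence[str],
    presence: Mapping[tuple[str, str], bool],
    replicate_cv: float,
    seed: int,
    n_replicates: int = 4,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Raw microarray spot signals with known epitope presence.

    Present (sample, antibody) pairs get mean signals placed well above
    the >=5 retention threshold on the normalized scale, absent pairs well
    below; one standard-control spot carries the global maximum. Spot
    noise is multiplicative lognormal with coefficient of variation
    ``replicate_cv``. Truth maps antibody -> should-be-retained.
    """
    if replicate_cv < 0:
        raise ValueError("replicate_cv must be >= 0")
    rng = np.random.default_rng(seed)
    control_raw = 10_000.0  # the standard control anchors the max
    rows = []
    truth = {ab: False for ab in antibodies}
    sigma = math.sqrt(math.log(1 + replicate_cv**2)) if replicate_cv > 0 else 0.0
    for sample in samples:
        for ab in antibodies:
            present = bool(presence.get((sample, ab), False))
            if present:
                truth[ab] = True
            for extraction in EXTRACTIONS_CYCLE:
                # per-extraction mean on the normalized (0-100) scale
                level = rng.uniform(8, 60) if present else rng.uniform(0.2, 3.0)
                mean_raw = level / 100.0 * control_raw
                for rep in range(1, n_replicates + 1):
                    noise = (
                        math.exp(rng.normal(-sigma**2 / 2, sigma))
                        if sigma
                        else 1.0
                    )
                    rows.append(
                        {
                            "sample": sample,
                            "extraction": extraction,
                            "antibody": ab,
                            "replicate": rep,
                            "signal": mean_raw * noise,
                            "is_control": 0,
                        }
                    )
        rows.append(
            {
                "sample": sample,
                "extraction": "H2O",
                "antibody": "STANDARD_CONTROL",
                "replicate": 1,
                "signal": control_raw if sample == samples[0] else control_raw * 0.8,
                "is_control": 1,
            }
        )
    return pd.DataFrame(rows), truth


# extraction assignment for generated replicates (each triple gets spots
# in all three extraction series across samples)
EXTRACTIONS_CYCLE = ("H2O", "EDTA", "NaOH")


def make_microarray_panel(
    samples: Sequence[str],
    antibodies: Sequence[str],
    p_present: float,
    replicate_cv: float,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Convenience wrapper drawing the presence matrix at random."""
    rng = np.random.default_rng(seed)
    presence = {
        (s, ab): bool(rng.random() < p_present)
        for s in samples
        for ab in antibodies
    }
    return make_microarray(samples, antibodies, presence, replicate_cv, seed + 1)


def make_study(
    outdir,
    seed: int,
    n_samples: int = 8,
    n_species: int = 20,
    n_reads: int = 400,
    library_size: int = 200_000,
    total_genome_equivalents: float = 1000.0,
) -> dict:
    """Write one coherent synthetic study to ``outdir``.

    Mirrors the study design at desk scale: ``n_samples`` samples over two
    depth layers (surface SRF and bottom of the mixed layer BML) sharing
    one community whose per-sample abundances are Dirichlet-perturbed.
    Emits, per sample: hit table, gene annotations, depth BEDGraph +
    manifest, transcript counts, marker FASTA pools; plus the shared
    taxdump and one microarray signal table. Truth tables go to
    ``outdir/truth``. Returns a manifest dict of the written paths.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    truth_dir = outdir / "truth"
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(exist_ok=True)

    community = make_community(n_species=n_species, seed=int(rng.integers(2**31)))
    iof.write_taxdump(
        community.tree, outdir / "nodes.dmp", outdir / "names.dmp"
    )

    stations = [f"S{i + 1}" for i in range(max(1, n_samples // 2))]
    layers = ["SRF", "BML"]
    samples = [f"{st}_{ly}" for st in stations for ly in layers][:n_samples]

    manifest: dict = {"samples": {}, "community_seed": community.seed}
    base_ab = np.asarray(community.abundances)
    for sample in samples:
        sdir = outdir / sample
        sdir.mkdir(exist_ok=True)
        s_seed = int(rng.integers(2**31))
        s_rng = np.random.default_rng(s_seed)
        # per-sample abundance jitter around the shared community profile
        ab = s_rng.dirichlet(base_ab * 50)
        sample_comm = CommunitySpec(
            tree=community.tree,
            species_taxids=community.species_taxids,
            abundances=tuple(float(a) for a in ab),
            genome_lengths=community.genome_lengths,
            cazyme_weights=community.cazyme_weights,
            seed=s_seed,
        )
        genes, read_truth = make_genes(
            sample_comm, n_reads, seed=int(s_rng.integers(2**31))
        )
        hits = make_hits(
            sample_comm, genes, read_truth, noise=0.1,
            seed=int(s_rng.integers(2**31)),
        )
        track, gmanifest, ab_truth = make_depth_tracks(
            sample_comm,
            total_genome_equivalents,
            poisson_noise=True,
            seed=int(s_rng.integers(2**31)),
        )
        rate_rng = np.random.default_rng(int(s_rng.integers(2**31)))
        rates = {
            g.gene_id: float(rate_rng.lognormal(0.0, 1.0)) for g in genes
        }
        counts, tpm_truth = make_transcripts(
            genes,
            ExpressionSpec(rates=rates),
            library_size,
            seed=int(s_rng.integers(2**31)),
        )
        pools = make_marker_sequences_for_genes(
            sample_comm, genes, read_truth, seed=int(s_rng.integers(2**31))
        )

        iof.write_gene_annotations(sdir / "genes.tsv", genes)
        iof.write_alignment_hits(sdir / "hits.tsv", hits)
        iof.write_depth_track(sdir / "depth.bedgraph", track)
        iof.write_genome_manifest(sdir / "genomes.tsv", gmanifest)
        iof.write_transcript_counts(sdir / "counts.tsv", counts)
        with open(sdir / "markers.fasta", "w") as fh:
            for m in sorted(pools):
                for gid in sorted(pools[m]):
                    fh.write(f">{gid} marker={m}\n{pools[m][gid]}\n")

        pd.DataFrame(
            {"read_id": list(read_truth), "taxid": list(read_truth.values())}
        ).to_csv(truth_dir / f"{sample}_reads.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"genome_id": list(ab_truth), "abundance": list(ab_truth.values())}
        ).to_csv(truth_dir / f"{sample}_abundance.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": list(tpm_truth), "tpm": list(tpm_truth.values())}
        ).to_csv(truth_dir / f"{sample}_tpm.tsv", sep="\t", index=False)
        manifest["samples"][sample] = str(sdir)

    # one locus set (MAG contigs) and one microarray table for the study
    archs = [["susC", "susD", "cazyme", "cazyme"],
             ["cazyme", "other", "cazyme", "other", "cazyme"],
             ["susD", "susC", "cazyme", "cazyme", "cazyme"]]
    loci, pul_truth = make_loci(archs, n_filler_contigs=5,
                                seed=int(rng.integers(2**31)))
    iof.write_gene_annotations(outdir / "mag_contigs.tsv", loci)
    pd.DataFrame(
        [
            {"contig_id": c, "start_ordinal": s, "end_ordinal": e}
            for c, (s, e) in pul_truth.items()
        ]
    ).to_csv(truth_dir / "puls.tsv", sep="\t", index=False)

    antibodies = [f"mAb{i:02d}" for i in range(12)]
    signals, retention_truth = make_microarray_panel(
        samples, antibodies, p_present=0.5, replicate_cv=0.1,
        seed=int(rng.integers(2**31)),
    )
    iof.write_microarray_signals(outdir / "microarray.tsv", signals)
    pd.DataFrame(
        {"antibody": list(retention_truth),
         "retained": [int(v) for v in retention_truth.values()]}
    ).to_csv(truth_dir / "microarray_retention.tsv", sep="\t", index=False)

    manifest["taxdump"] = [str(outdir / "nodes.dmp"), str(outdir / "names.dmp")]
    manifest["mag_contigs"] = str(outdir / "mag_contigs.tsv")
    manifest["microarray"] = str(outdir / "microarray.tsv")
    return manifest
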