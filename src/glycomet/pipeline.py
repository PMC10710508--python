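"""Full-study orchestration: classify -> markers -> abundance ->
transcription -> profiles -> pul -> microarray, in dependency order.

Each stage reads the study's input files (the layout written by
:func:`glycomet.synthetic.make_study`), feeds the previous stage's
outputs forward, and writes plain TSVs whose first line is a provenance
comment (tool version, config hash, seed — deliberately no timestamp, so
identical runs are byte-identical). A manifest JSON listing every output
with its SHA-256 checksum closes the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io_formats as iof
from .abundance import (
    competitive_depth_sanity,
    profiles_from_track,
    relative_abundance,
    tad,
)
from .markers import (
    SC_RBP_NAMES,
    MarkerGeneSet,
    assign_cluster_taxonomy,
    cluster_marker_genes,
    composition_profile,
    genome_equivalents,
    species_count,
)
from .microarray import process_microarray
from .profiles import (
    cazyme_family_counts,
    family_abundance_pmg,
    family_shares,
    family_taxon_breakdown,
)
from .pul import assign_roles, cazyme_class, detect_puls, render_locus
from .taxonomy import HitFilter, TaxonomyTree, classify_all
from .transcription import mag_relative_transcription, tpm, up_transcribed_families

log = logging.getLogger("glycomet")

__all__ = ["RunConfig", "run_all"]


class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    def __init__(
        self,
        study_dir,
        out_dir,
        seed: int = 0,
        min_identity: float = 65.0,
        max_evalue: float = 1e-10,
        min_query_cover: float = 50.0,
        ani_threshold: float = 99.0,
        tad_fraction: float = 0.8,
        pul_max_gap: int = 6,
        microarray_threshold: float = 5.0,
        rank: str = "genus",
    ):
        self.study_dir = Path(study_dir)
        self.out_dir = Path(out_dir)
        self.seed = int(seed)
        self.hit_filter = HitFilter(min_identity, max_evalue, min_query_cover)
        self.ani_threshold = float(ani_threshold)
        self.tad_fraction = float(tad_fraction)
        self.pul_max_gap = int(pul_max_gap)
        self.microarray_threshold = float(microarray_threshold)
        self.rank = rank
        if not self.study_dir.exists():
            raise FileNotFoundError(f"study directory not found: {self.study_dir}")

    def to_dict(self) -> dict:
        return {
            "study_dir": str(self.study_dir),
            "seed": self.seed,
            "min_identity": self.hit_filter.min_identity,
            "max_evalue": self.hit_filter.max_evalue,
            "min_query_cover": self.hit_filter.min_query_cover,
            "ani_threshold": self.ani_threshold,
            "tad_fraction": self.tad_fraction,
            "pul_max_gap": self.pul_max_gap,
            "microarray_threshold": self.microarray_threshold,
            "rank": self.rank,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return (
            f"# glycomet v{__version__} config={self.config_hash} "
            f"seed={self.seed}\n"
        )


def read_fasta_pools(path) -> dict[str, dict[str, str]]:
    """Read a marker FASTA (header: ``>gene_id marker=NAME``) into
    per-marker sequence pools."""
    pools: dict[str, dict[str, str]] = {}
    gid, marker, chunks = None, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if gid is not None:
                    pools.setdefault(marker, {})[gid] = "".join(chunks)
                fields = line[1:].split()
                gid = fields[0]
                marker = "unknown"
                for f in fields[1:]:
                    if f.startswith("marker="):
                        marker = f.split("=", 1)[1]
                chunks = []
            else:
                chunks.append(line)
    if gid is not None:
        pools.setdefault(marker, {})[gid] = "".join(chunks)
    return pools


def _write_df(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(config.header())
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _missing_inputs(config: RunConfig, samples: list[str]) -> list[str]:
    needed = [
        config.study_dir / "nodes.dmp",
        config.study_dir / "names.dmp",
        config.study_dir / "mag_contigs.tsv",
        config.study_dir / "microarray.tsv",
    ]
    for s in samples:
        sdir = config.study_dir / s
        needed += [
            sdir / "genes.tsv",
            sdir / "hits.tsv",
            sdir / "depth.bedgraph",
            sdir / "genomes.tsv",
            sdir / "counts.tsv",
            sdir / "markers.fasta",
        ]
    return [str(p) for p in needed if not p.exists()]


def run_all(config: RunConfig) -> dict:
    """Execute every stage over every sample of a study directory.

    Returns the output manifest (also written as ``manifest.json``); any
    stage failure aborts with the stage name attached, leaving partial
    outputs under a ``.partial`` suffix.
    """
    samples = sorted(
        p.name
        for p in config.study_dir.iterdir()
        if p.is_dir() and (p / "genes.tsv").exists()
    )
    missing = _missing_inputs(config, samples)
    if missing:
        raise FileNotFoundError(f"missing study inputs: {missing}")

    config.out_dir.mkdir(parents=True, exist_ok=True)
    tree = iof.read_taxdump(
        config.study_dir / "nodes.dmp", config.study_dir / "names.dmp"
    )
    outputs: list[Path] = []
    markerset = MarkerGeneSet(
        ani_thresholds={m: config.ani_threshold for m in ("L3", "L4", "L6", "S8")}
    )

    stage = "classify"
    try:
        for sample in samples:
            sdir = config.study_dir / sample
            odir = config.out_dir / sample
            odir.mkdir(exist_ok=True)

            stage = f"classify[{sample}]"
            log.info("stage=%s starting", stage)
            genes = iof.read_gene_annotations(sdir / "genes.tsv")
            hits = iof.read_alignment_hits(sdir / "hits.tsv")
            gene_cls, read_cls, propagated = classify_all(
                hits, genes, tree, config.hit_filter
            )
            gdf = pd.DataFrame(
                [
                    {
                        "gene_id": g,
                        "taxid": c.taxid if c.taxid is not None else "",
                        "n_hits_used": c.n_hits_used,
                        "lineage": tree.lineage(c.taxid) if c.taxid else "",
                    }
                    for g, c in sorted(gene_cls.items())
                ]
            )
            _write_df(gdf, odir / "gene_classification.tsv", config)
            rdf = pd.DataFrame(
                [
                    {
                        "read_id": r,
                        "taxid": c.taxid if c.taxid is not None else "",
                        "n_genes_used": c.n_genes_used,
                        "lineage": tree.lineage(c.taxid) if c.taxid else "",
                    }
                    for r, c in sorted(read_cls.items())
                ]
            )
            _write_df(rdf, odir / "read_classification.tsv", config)
            pdf = pd.DataFrame(
                [
                    {"gene_id": g, "taxid": t if t is not None else ""}
                    for g, t in sorted(propagated.items())
                ]
            )
            _write_df(pdf, odir / "gene_taxids.tsv", config)
            outputs += [
                odir / "gene_classification.tsv",
                odir / "read_classification.tsv",
                odir / "gene_taxids.tsv",
            ]

            stage = f"markers[{sample}]"
            log.info("stage=%s starting", stage)
            ge = genome_equivalents(genes, markerset)
            pools = read_fasta_pools(sdir / "markers.fasta")
            # a marker with no genes in this sample is an empty pool
            # (zero clusters), not missing data
            for m in markerset.species_subset:
                pools.setdefault(m, {})
            spc = species_count(pools, markerset)
            l6 = cluster_marker_genes(
                pools.get("L6", {}), markerset.ani_thresholds["L6"]
            )
            l6 = assign_cluster_taxonomy(l6, propagated, tree)
            comp = composition_profile(l6) if l6 else {}
            mdf = pd.DataFrame(
                [{"genome_equivalents": ge, "species_count": spc}]
            )
            _write_df(mdf, odir / "markers_summary.tsv", config)
            cdf = pd.DataFrame(
                sorted(
                    (
                        {
                            "taxid": t if t is not None else "",
                            "name": tree.name(t) if t is not None else "unclassified",
                            "share": s,
                        }
                        for t, s in comp.items()
                    ),
                    key=lambda r: -r["share"],
                )
            )
            _write_df(cdf, odir / "l6_composition.tsv", config)
            outputs += [odir / "markers_summary.tsv", odir / "l6_composition.tsv"]

            stage = f"abundance[{sample}]"
            log.info("stage=%s starting", stage)
            track = iof.read_depth_track(sdir / "depth.bedgraph")
            manifest_g = iof.read_genome_manifest(sdir / "genomes.tsv")
            profs = profiles_from_track(track, manifest_g)
            sanity = competitive_depth_sanity(profs)
            adf = pd.DataFrame(
                [
                    {
                        "genome_id": p.genome_id,
                        "tad": tad(p, config.tad_fraction),
                        "relative_abundance": relative_abundance(
                            tad(p, config.tad_fraction), ge
                        ),
                        "covered_fraction": sanity[p.genome_id]["covered_fraction"],
                        "low_coverage_flag": int(sanity[p.genome_id]["flagged"]),
                    }
                    for p in sorted(profs, key=lambda p: p.genome_id)
                ]
            )
            _write_df(adf, odir / "abundance.tsv", config)
            outputs.append(odir / "abundance.tsv")

            stage = f"transcription[{sample}]"
            log.info("stage=%s starting", stage)
            counts = iof.read_transcript_counts(sdir / "counts.tsv")
            lengths = {g.gene_id: g.length_bp for g in genes}
            tpms = tpm(counts, lengths)
            tdf = pd.DataFrame(
                [{"gene_id": g, "tpm": v} for g, v in sorted(tpms.items())]
            )
            _write_df(tdf, odir / "tpm.tsv", config)
            outputs.append(odir / "tpm.tsv")

            # MAG proxies: genes grouped by propagated species-level taxon
            sample_marker_tpms = _marker_mean_tpms(genes, tpms)
            mag_rows = []
            for taxid in sorted({t for t in propagated.values() if t is not None}):
                if tree.rank(taxid) != "species":
                    continue
                mag_genes = [g for g in genes if propagated[g.gene_id] == taxid]
                mag_marker_tpms = _marker_mean_tpms(mag_genes, tpms)
                if len(mag_marker_tpms) < 8:
                    mag_rows.append(
                        {
                            "mag_id": tree.name(taxid),
                            "taxid": taxid,
                            "n_markers": len(mag_marker_tpms),
                            "relative_transcription": "",
                            "flagged_few_markers": 1,
                        }
                    )
                    continue
                rt = mag_relative_transcription(
                    mag_marker_tpms, sample_marker_tpms
                )
                fam_tpms: dict[str, float] = {}
                for g in mag_genes:
                    for lab in g.labels:
                        if cazyme_class(lab):
                            fam_tpms[lab] = fam_tpms.get(lab, 0.0) + tpms.get(
                                g.gene_id, 0.0
                            )
                mag_mean = sum(mag_marker_tpms.values()) / len(mag_marker_tpms)
                up = up_transcribed_families(fam_tpms, mag_mean)
                mag_rows.append(
                    {
                        "mag_id": tree.name(taxid),
                        "taxid": taxid,
                        "n_markers": len(mag_marker_tpms),
                        "relative_transcription": rt,
                        "flagged_few_markers": 0,
                        "up_transcribed_families": ";".join(sorted(up)),
                    }
                )
            _write_df(
                pd.DataFrame(mag_rows), odir / "mag_transcription.tsv", config
            )
            outputs.append(odir / "mag_transcription.tsv")

            stage = f"profiles[{sample}]"
            log.info("stage=%s starting", stage)
            fam_counts = cazyme_family_counts(genes)
            if fam_counts:
                pmg = family_abundance_pmg(fam_counts, ge)
                ab_shares = family_shares(fam_counts)
                fam_tpm_totals = {}
                fam_gene_ids: dict[str, list[str]] = {}
                for g in genes:
                    for lab in g.labels:
                        if cazyme_class(lab):
                            fam_tpm_totals[lab] = fam_tpm_totals.get(
                                lab, 0.0
                            ) + tpms.get(g.gene_id, 0.0)
                            fam_gene_ids.setdefault(lab, []).append(g.gene_id)
                tr_shares = (
                    family_shares(fam_tpm_totals)
                    if sum(fam_tpm_totals.values()) > 0
                    else {f: 0.0 for f in fam_counts}
                )
                fdf = pd.DataFrame(
                    [
                        {
                            "family": f,
                            "abundance_pmg": pmg[f],
                            "abundance_share": ab_shares[f],
                            "transcription_share": tr_shares.get(f, 0.0),
                        }
                        for f in sorted(fam_counts)
                    ]
                )
                _write_df(fdf, odir / "family_profile.tsv", config)
                outputs.append(odir / "family_profile.tsv")

                taxon_rows = []
                for fam in sorted(fam_gene_ids):
                    gids = fam_gene_ids[fam]
                    breakdown = family_taxon_breakdown(
                        {g: propagated.get(g) for g in gids},
                        {g: tpms.get(g, 0.0) for g in gids},
                        config.rank,
                        tree,
                    ) if any(tpms.get(g, 0.0) > 0 for g in gids) else {}
                    for taxon, share in sorted(
                        breakdown.items(), key=lambda kv: -kv[1]
                    ):
                        taxon_rows.append(
                            {"family": fam, "taxon": taxon, "share": share}
                        )
                _write_df(
                    pd.DataFrame(taxon_rows), odir / "family_taxa.tsv", config
                )
                outputs.append(odir / "family_taxa.tsv")

        stage = "pul"
        log.info("stage=%s starting", stage)
        contig_genes = iof.read_gene_annotations(
            config.study_dir / "mag_contigs.tsv"
        )
        by_contig: dict[str, list] = {}
        for g in contig_genes:
            by_contig.setdefault(g.parent_id, []).append(g)
        pul_rows, diagrams = [], []
        for contig in sorted(by_contig):
            locus = assign_roles(by_contig[contig])
            calls = detect_puls(locus, config.pul_max_gap)
            for i, call in enumerate(calls):
                pul_rows.append(
                    {
                        "contig_id": contig,
                        "pul_index": i,
                        "trigger_clause": call.trigger_clause,
                        "member_genes": ";".join(call.member_gene_ids),
                        "cazyme_families": ";".join(call.cazyme_families),
                    }
                )
            if calls:
                diagrams.append(render_locus(locus, calls))
        _write_df(pd.DataFrame(pul_rows), config.out_dir / "puls.tsv", config)
        with open(config.out_dir / "pul_diagrams.txt", "w") as fh:
            fh.write(config.header())
            fh.write("\n\n".join(diagrams) + "\n")
        outputs += [config.out_dir / "puls.tsv", config.out_dir / "pul_diagrams.txt"]

        stage = "microarray"
        log.info("stage=%s starting", stage)
        signals = iof.read_microarray_signals(config.study_dir / "microarray.tsv")
        epitopes = process_microarray(signals, config.microarray_threshold)
        _write_df(epitopes, config.out_dir / "epitopes.tsv", config)
        wide = epitopes.pivot(
            index="antibody", columns="sample", values="summed_mean_signal"
        ).fillna(0.0).reset_index()
        _write_df(wide, config.out_dir / "epitopes_wide.tsv", config)
        outputs += [
            config.out_dir / "epitopes.tsv",
            config.out_dir / "epitopes_wide.tsv",
        ]
    except Exception as exc:
        for p in outputs:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "tool": "glycomet",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "outputs": {
            str(p.relative_to(config.out_dir)): _sha256(p) for p in outputs
        },
    }
    with open(config.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("stage=done outputs=%d", len(outputs))
    return manifest


def _marker_mean_tpms(genes, tpms) -> dict[str, float]:
    """Per-marker mean TPM over the genes carrying each SC-RBP label."""
    per_marker: dict[str, list[float]] = {}
    for g in genes:
        for m in SC_RBP_NAMES:
            if m in g.labels:
                per_marker.setdefault(m, []).append(tpms.get(g.gene_id, 0.0))
    return {m: sum(v) / len(v) for m, v in per_marker.items()}
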