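# Methods

`glycomet` re-implements, as a tested library, the quantification chain
used in combined long-read metagenome / metatranscriptome / glycan
microarray surveys of marine microbial communities. This note documents
the models and procedures, the parameters that matter, the synthetic-data
conditions under which everything is validated, and the design choices
made where the procedure left room.

## Two-stage LCA taxonomic classification

Long (HiFi-class) reads carry several predicted protein-coding genes.
Each gene accumulates protein alignment hits against a taxonomically
labelled reference; classification proceeds in two lowest-common-ancestor
(LCA) stages:

1. **Hit filter.** A hit survives iff identity > 65%, e-value < 1e-10 and
   query cover > 50%. All three comparisons are strict, exactly as the
   thresholds are written; boundary values are rejected. The upstream
   aligner's own pre-filter (e.g. DIAMOND `--id 50 --top 5`) is an
   external concern; this module consumes whatever hit table it is given.
2. **Gene LCA.** The gene's taxon is the LCA of the subject taxa of its
   surviving hits (unweighted, as in TaxonKit's `lca`). A gene with no
   surviving hit is *unclassified*. A bitscore-weighted vote exists as an
   explicit flag but never changes default behaviour.
3. **Read LCA.** The read's taxon is the LCA over its *classified* genes
   only — unclassified genes abstain rather than dragging the read to the
   root. The read taxon then propagates back onto all genes of the read
   (overriding gene-level calls); genes of unclassified reads keep their
   own calls. Both choices maximize the number of classified genes, which
   is the stated purpose of the read-level stage.

The LCA itself is the deepest node ancestral-or-self to every input
taxon; it is idempotent, order-invariant, and monotone (adding taxa never
deepens the answer). Tests check it against a brute-force root-path
intersection oracle on random trees.

## Genome equivalents and species counts from SC-RBP markers

Sixteen universal single-copy ribosomal proteins (L2, L3, L4, L5, L6,
L14, L15, L16, L18, L22, L24, S3, S8, S10, S17, S19) act as genome
proxies: every genome carries each exactly once, so the **mean count of
the 16 markers in a sample estimates the number of genomes sequenced**
("genome equivalents"), the denominator for all per-genome (PMG)
normalization. Counting is the primary definition; a per-gene weight
column supports the depth-weighted reading instead, through the same code
path. Absent markers count zero in the mean; a sample with no marker at
all is an error, since the downstream division is undefined.

**Species counts** come from greedy centroid clustering of the four
species-delineating markers L3, L4, L6 and S8 at per-marker nucleotide
identity thresholds (default 99.0% each; the thresholds are mandatory
configuration, not constants). Sequences are processed longest-first
(ties by gene id); a sequence joins the first centroid at or above the
threshold, else founds a cluster. Pairwise identity is computed from a
global alignment with free terminal gaps (match +1, mismatch −1, gap −2,
Biopython `PairwiseAligner`), with identity = matches / **all** alignment
columns. Counting every column (including terminal-gap columns) matters:
judging only the overlapped region lets a spurious one-base overlap
between unrelated sequences score 100% identity and collapse clusters.
The species estimate is the mean cluster count over the four markers.
Clustering is pooled across samples, so composition profiles share
clusters between samples.

Community composition uses the L6 clusters: each cluster's weight is the
summed weight of its member genes (1 per gene for metagenomes, TPM for
metatranscriptomes), aggregated by the cluster's majority-vote taxon
(strict plurality; ties resolve to the LCA of the tied taxa) and
normalized to proportions.

## TAD: truncated-average-depth genome abundance

The abundance of a genome (MAG) in a sample is its **80% central
truncated average depth**: conceptually sort the genome-length vector of
per-base depths (uncovered bases = 0), discard `floor(L × 0.1)` positions
from *each* tail, and average the rest. Truncation suppresses
conserved-region pile-ups and mobile-element spikes. The implementation
operates on run-length BEDGraph intervals without per-base expansion and
is tested for exact agreement with the per-base oracle on fragmented
random profiles. Because zeros participate, the genome length must be
known — hence the mandatory genome manifest whenever the depth track
omits zero runs. **Relative abundance** is TAD divided by the sample's
genome equivalents. An advisory flag marks genomes whose covered fraction
falls below 10% (configurable), whose TAD is then unreliable; no hard
reporting threshold is imposed.

## TPM and relative transcription

Transcripts per million with an explicit normalization universe:
`rate_g = count_g / length_g`, `tpm_g = 1e6 · rate_g / Σ_universe rate_u`.
Gene length is the annotated nucleotide length of the predicted gene.
MAG genes are converted with the **community** denominator, making MAG
and community values commensurable (MAG totals are then bounded by 1e6
rather than summing to it).

**MAG relative transcription** is `mean(MAG SC-RBP TPM) / mean(sample
SC-RBP TPM)` — the proportional transcription of one genome against the
community average. For MAGs missing markers the mean runs over the
markers present, with a floor of 8 of 16 required (mirroring the usual
concatenated-marker tree inclusion rule); below the floor the record is
flagged and no value is emitted. Whether to use all 16 or the present
subset was an open choice; the present-markers mean avoids biasing
incomplete MAGs downward for assembly reasons rather than biological
ones.

**Family transcription shares** divide each MAG's mapped transcripts for
a CAZyme family by the community total for that family; the unassigned
remainder is reported as "other community members". **Up-transcribed
families** are those whose summed TPM strictly exceeds the MAG's mean
SC-RBP TPM — transcription above the ribosomal-protein baseline.

## PUL detection

A polysaccharide utilization locus is called on the ordered gene list of
a contig by either clause:

1. an adjacent susC/susD pair (consecutive ordinals, either order) with
   ≥ 2 degradative CAZymes within `max_gap` (default 6) intervening genes
   of the pair boundary, or
2. ≥ 3 degradative CAZymes chained at ≤ `max_gap` intervening genes
   between consecutive members.

Degradative classes default to GH, PL and CE. CBMs bind rather than
cleave and are excluded by default; CE inclusion is configurable since
esterases are accessory. A gene carrying both susC and a CAZyme label
acts as susC for clause 1 and as a CAZyme only for clause 2 chains.
Strand is ignored; the rule is symmetric under gene-order reversal.
Overlapping clause hits merge into one call spanning their union, so
each gene belongs to at most one PUL. The clause-1 proximity window is
applied for determinism (how far the ≥ 2 CAZymes may sit from the pair is
otherwise under-determined). The rule is verified by exhaustive
enumeration of all 4^8 role sequences of length 8 against an
independently written checker, and by planted-architecture recovery.
Calls are rendered as plain-text locus diagrams rather than manual
figures.

## Glycan microarray chain

Quadruplicate-printed polysaccharide extracts (sequential H2O, EDTA,
NaOH extractions) probed with monoclonal antibodies are processed as:

1. **normalize**: the highest spot signal in the data set (a standard
   control) becomes exactly 100; everything scales linearly;
2. **replicate means** per (sample, extraction, antibody), controls
   excluded from downstream tables;
3. **retention filter**: an antibody is kept iff some sample shows a mean
   signal ≥ 5 (non-strict, as printed). The prose order of filtering vs
   averaging is ambiguous at the spot level; the default filters on
   means, with `filter_on="spot"` for the per-spot reading (which can
   only retain more);
4. **extraction sums** per (sample, antibody) over the three extractions
   (missing extraction = 0) give the epitope abundance table.

Antibody avidities differ, so no cross-antibody statistic is ever
emitted; values are comparable only within one antibody across samples.
The chain is homogeneous of degree 1 in raw signals before normalization
and degree 0 after it.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with known truth, all pure
functions of (parameters, seed):

- **Taxonomy**: random rooted trees with ranks domain→species, level
  widths halving upward.
- **Community**: Dirichlet(2.0) relative abundances over 20 species by
  default (moderately uneven, no near-zero members), genome length 1e5,
  1000 genome equivalents per sample (the order observed in open-ocean
  metagenomes); every species carries the 16 markers once.
- **Hits**: per gene 1–5 hits into the true species' lineage (species
  80% / genus 20%) at clearly filter-passing quality; a configurable
  fraction of genes receives one off-lineage hit drawn as a
  characteristically *weak* alignment (identity U(45,70), e-value
  log-U(1e-12,1e-5), cover U(20,70)) — the realistic spurious-homology
  scenario the secondary filter exists to remove.
- **Depth**: per-base Poisson around abundance × genome-equivalents,
  run-length encoded; or exact constant tracks.
- **Transcripts**: negative-binomial counts with expectation ∝ rate ×
  length, size 100 (mild overdispersion, ~10% extra CV — the level
  consistent with deeply sequenced metatranscriptome technical noise);
  truth TPM is computed analytically from the rates.
- **Marker sequences**: one ancestor per marker, 600 bp; species diverge
  5%, within-species copies at 0.2% *pairwise* divergence (each copy
  mutates at half that from the species consensus).
- **Loci**: planted role architectures flanked by filler genes.
- **Microarray**: present epitopes at 8–60 on the normalized scale,
  absent at 0.2–3, multiplicative lognormal spot noise at the requested
  CV, one standard-control spot holding the global maximum.

`make_study` composes all of this into an 8-sample, two-depth-layer study
at desk scale (400 reads × 5 genes per sample by default) for the
integration path.

What the generators deliberately do **not** model: sequence-level read
errors and chimeras, genome-content correlation between relatives,
database incompleteness (every hit has a resolvable taxon), rRNA
carry-over in transcript counts, uneven genome lengths, spatial structure
on the array, and antibody cross-reactivity. Passing recovery tests
therefore demonstrates correctness of the *quantification arithmetic and
rules* under controlled noise, not robustness to every failure mode of
real survey data.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout (BEDGraph convention).
- TAD tail size is `floor(L(1−f)/2)` per tail, keeping tiny genomes
  defined; `f = 1` is the plain mean; overlapping depth intervals are
  rejected at parse time.
- TPM with an all-zero universe yields all-zero values with a warning
  (not an error: empty samples occur); zero gene lengths are errors.
- Greedy clustering tie-breaks: longest sequence first, then lexicographic
  id; first-qualifying centroid wins.
- Majority vote ties resolve to the LCA of the tied taxa rather than an
  arbitrary pick.
- All readers reject malformed rows with 1-based line numbers; no silent
  coercion.
- Pipeline outputs carry a provenance header (version, config hash, seed)
  with no timestamp, so identical configurations re-run byte-identically;
  run manifests record SHA-256 checksums of every output.

## Problem sizes used in validation

The shipped validation suite runs at: 1,000 random depth profiles
(length ≤ 10,000) for the TAD oracle; 500 trees × 10 taxon sets for the
LCA oracle; 1,000 reads × 5 genes for classification recovery; 20 species
× 1e5 bp for abundance recovery; 1,000 genes at library 1e6 for TPM
recovery; 100 replicates for the MAG-ratio and clustering calibrations;
all 65,536 length-8 role sequences plus 200 planted contigs for the PUL
rule; 50 replicates for microarray retention; and the full 8-sample
synthetic study for the end-to-end determinism check. These sizes were
chosen so the whole suite runs comfortably on a laptop while keeping the
statistical targets (Pearson r, recovery rates, bias bounds) well
resolved.

## Known limitations

- The 16-marker list and the 99% clustering thresholds are conventions;
  real analyses may use curated per-marker thresholds.
- Unweighted LCA ignores hit quality beyond the pass/fail filter.
- PUL substrate prediction is out of scope; calls are architectural only.
- The microarray filter order flag changes retention for antibodies
  hovering at the threshold; both orders are exposed and tested, but only
  one can be the default.
- Merged/deleted taxid remapping is not handled; taxids must be current
  in the supplied tree.
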