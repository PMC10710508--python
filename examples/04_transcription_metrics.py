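"""TPM conversion and the MAG SC-RBP relative-transcription ratio.

Simulates negative-binomial transcript counts for a community whose MAG
expresses its ribosomal proteins at 40% of the community average, then
recovers that ratio from TPM values.
"""

from glycomet.io_formats import GeneRecord
from glycomet.synthetic import ExpressionSpec, make_transcripts
from glycomet.transcription import mag_relative_transcription, tpm

MARKERS = [f"L{i}" for i in range(16)]
TRUE_RATIO = 0.4

genes = [
    GeneRecord(f"sample_{m}", "community", i, 900, frozenset({m}))
    for i, m in enumerate(MARKERS)
] + [
    GeneRecord(f"mag_{m}", "mag", i, 900, frozenset({m}))
    for i, m in enumerate(MARKERS)
]
rates = {f"sample_{m}": 1.0 for m in MARKERS}
rates.update({f"mag_{m}": TRUE_RATIO for m in MARKERS})

counts, _ = make_transcripts(
    genes, ExpressionSpec(rates=rates), library_size=8000, seed=9
)
tpms = tpm(counts, {g.gene_id: g.length_bp for g in genes})

print(f"sum of TPM over the universe: {sum(tpms.values()):,.0f}")
ratio = mag_relative_transcription(
    {m: tpms[f"mag_{m}"] for m in MARKERS},
    {m: tpms[f"sample_{m}"] for m in MARKERS},
)
print(f"recovered MAG relative transcription: {ratio:.3f} "
      f"(generated at {TRUE_RATIO})")
print("A value of 1.0 means the MAG transcribes its ribosomal proteins at")
print("exactly the community-average level; below 1.0, less actively.")
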