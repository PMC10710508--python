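"""Rule-based polysaccharide utilization locus (PUL) detection.

Plants two PUL architectures — a susC/susD pair with CAZymes, and a
CAZyme-only chain — among filler genes and shows the calls with text
locus diagrams.
"""

from glycomet.pul import assign_roles, detect_puls, render_locus
from glycomet.synthetic import make_loci

architectures = [
    ["susC", "susD", "cazyme", "cazyme"],
    ["cazyme", "other", "other", "cazyme", "other", "cazyme"],
]
genes, truth = make_loci(architectures, n_filler_contigs=1, seed=10)

by_contig = {}
for g in genes:
    by_contig.setdefault(g.parent_id, []).append(g)

for contig in sorted(by_contig):
    locus = assign_roles(by_contig[contig])
    calls = detect_puls(locus, max_gap=6)
    print(render_locus(locus, calls))
    for call in calls:
        print(f"  -> {call.trigger_clause}: {len(call.member_gene_ids)} genes, "
              f"families {', '.join(call.cazyme_families)}")
    if not calls:
        print("  -> no PUL (filler only)")
    print()
print("Clause 1 needs an adjacent susC/susD pair with >=2 degradative")
print("CAZymes nearby; clause 2 needs >=3 degradative CAZymes at most six")
print("genes apart. '^' marks PUL member genes.")
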