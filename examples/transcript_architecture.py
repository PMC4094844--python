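"""Transcript architecture of the Synechocystis ado/aar locus.

Reconstructs the two experimentally anchored transcripts from their
circular-RACE junctions, assigns the three TSS to genes, decomposes the aar
mRNA into UTR/ORF/trailer and applies the minimal-dicistron rule.
"""

from alkatlas import locus
from alkatlas.genome_model import ProductClass
from alkatlas.txunit import (LengthEvidence, TranscriptModel, assign_tss,
                             classify_transcript, min_dicistron_length,
                             reconstruct_circular_junction, utr_lengths)

genes = {f.product_class: f for f in locus.locus_features()}
ado, aar = genes[ProductClass.ADO], genes[ProductClass.AAR]

aar_mrna = reconstruct_circular_junction(locus.AAR_JUNCTION, "-")
cotx = reconstruct_circular_junction(locus.COTRANSCRIPT_JUNCTION, "-")
print(f"aar mRNA: {aar_mrna.five_prime} -> {aar_mrna.three_prime} "
      f"({aar_mrna.length_nt} nt)")
print(f"SyR9-ado cotranscript: {cotx.five_prime} -> {cotx.three_prime} "
      f"({cotx.length_nt} nt)")

u5, u3 = utr_lengths(aar_mrna, aar)
print(f"aar decomposition: 5'UTR {u5} + ORF {aar.length_nt} + trailer {u3} "
      f"= {u5 + aar.length_nt + u3} nt")

bound = min_dicistron_length(ado, aar)
cls = classify_transcript(TranscriptModel(locus.TSS2, locus.ADO_MRNA_3PRIME, "-"),
                          list(genes.values()),
                          evidence=LengthEvidence(900, 1000))
print(f"minimal dicistron bound: {bound} nt "
      f"(ORF sum {ado.length_nt + aar.length_nt} nt)")
print(f"900-1000 nt northern band vs that bound -> {cls.value}")

cls_co = classify_transcript(cotx, list(genes.values()),
                             srna_loci=[locus.syr9_locus()])
print(f"985-nt junction transcript with the SyR9 locus known -> {cls_co.value}")

assigned, orphans = assign_tss(locus.locus_tss(), list(genes.values()))
for gene_id, lst in assigned.items():
    for a in lst:
        print(f"{a.tss.label} -> {gene_id}: leader {a.leader_nt} nt ({a.role})")

# A transcript far shorter than the dicistron bound cannot carry both ORFs:
# each gene keeps its own promoter(s), with ado driven from both a proximal
# and a distal TSS.
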