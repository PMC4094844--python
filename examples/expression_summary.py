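"""Fold-change extremes, sign concordance and reporter activities.

Uses the packaged novobiocin-stress log2 fold-change table for ado/aar and a
synthetic luciferase measurement set mirroring the promoter-fusion design.
"""

from alkatlas.expression_meta import (ReporterMeasurement,
                                      load_novobiocin_table,
                                      relative_promoter_activity,
                                      sign_concordance, top_change)

table = load_novobiocin_table()
for gene in ("ado", "aar"):
    cond, value = top_change(table, gene, "min")
    print(f"{gene}: strongest repression {value} (log2 FC) under {cond}")

conc, discordant = sign_concordance(table, "ado", "aar")
print(f"sign concordance: {conc:.0%}; discordant: {discordant}")
# Despite the shared locus, the two genes do not always move together.

measurements = [
    ReporterMeasurement("petE", (3000.0, 3200.0, 2800.0)),   # reference
    ReporterMeasurement("P1", (1100.0, 1080.0, 1120.0)),
    ReporterMeasurement("P2", (110.0, 95.0, 105.0)),
    ReporterMeasurement("P3", (900.0, 950.0, 850.0)),
    ReporterMeasurement("ctrl", (100.0, 105.0, 95.0),
                        is_negative_control=True),
]
acts = relative_promoter_activity(measurements, "petE", "ctrl")
for cid in ("P1", "P2", "P3"):
    flag = " (close to background)" if acts[cid].background_flag else ""
    print(f"{cid}: {acts[cid].activity:.2f} of reference{flag}")
# P1/P3 land near one third of the strong reference promoter; P2 is weak.
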