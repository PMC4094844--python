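"""Promoter -10 box scanning and intrinsic-terminator detection.

Plants a TATAAT hexamer upstream of a TSS and a stem-loop + U-tract in a 3'
region, then recovers both with the sequence-level callers.
"""

import numpy as np

from alkatlas.genome_model import Genome
from alkatlas.regulatory_elements import find_terminator_hairpin, scan_minus10
from alkatlas.synthetic_data import (PlantedPromoter, generate_terminator_region,
                                     generate_tss_profile)

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), size=400))
genome, tss, truth = generate_tss_profile(
    Genome("demo", {"c": seq}, []),
    [PlantedPromoter("c", 200, "-", "TSS1")], seed=1)

call = scan_minus10(genome.contigs["c"], tss[0])
print(f"-10 element: {call.hexamer_seq} at offset {call.hexamer_offset} "
      f"(score {call.score:.2f} bits)")
# offset -7 means the hexamer's 3' edge sits 7 nt upstream of the +1.

region, t_truth = generate_terminator_region(stem_len=8, loop_len=4,
                                             u_tract_len=6, seed=2)
term = find_terminator_hairpin(region)
print(f"terminator: stem {term.stem_len} bp, loop {term.loop_len} nt, "
      f"U-tract {term.u_tract_len} nt, pairing score {term.pairing_score}")
print(f"planted at {t_truth['stem5_span'][0]}, found at {term.start}")
# The U-tract requirement is what separates an intrinsic terminator from an
# arbitrary hairpin.
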