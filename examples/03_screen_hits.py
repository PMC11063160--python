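"""Genome-wide screen hit calling on a simulated phenotype table.

Simulates per-line daily-sleep, locomotor and social phenotypes for 300
RNAi lines with a few planted effects, calls hits with the three population
rules, and reports the seven-region overlap.
"""

from vtlkit.screen import (
    call_locomotor_hits,
    call_sleep_hits,
    call_social_hits,
    hits_to_genes,
    overlap_sets,
)
from vtlkit.synthetic import simulate_screen

# Sleep (min/day): hits fall 2 population SDs below the mean.
sleep = simulate_screen(300, base_mean=600.0, base_sd=60.0,
                        planted_hits=[(5, -4.0), (6, -5.0)], seed=1)
# Locomotor (px/day): hits are at least 1.5x the population mean.
loco = simulate_screen(300, base_mean=40000.0, base_sd=4000.0,
                       planted_hits=[(5, 6.0), (7, 8.0)], seed=2)
# Social (min/day): hits are at most half the population mean.
social = simulate_screen(300, base_mean=40.0, base_sd=4.0,
                         planted_hits=[(5, -6.0), (8, -7.0)], seed=3)

sleep_hits = hits_to_genes(sleep, call_sleep_hits(sleep))
loco_hits = hits_to_genes(loco, call_locomotor_hits(loco))
social_hits = hits_to_genes(social, call_social_hits(social))
print(f"sleep hits     : {len(sleep_hits)} -> {sorted(sleep_hits)}")
print(f"locomotor hits : {len(loco_hits)} -> {sorted(loco_hits)}")
print(f"social hits    : {len(social_hits)} -> {sorted(social_hits)}")

print("\nVenn regions:", overlap_sets(sleep_hits, loco_hits, social_hits))
# gene00005 was planted in all three tables, so it appears in `all_three`;
# extra sleep calls are genuine tail lines of the simulated null population.
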