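"""Classify single variants: pair classes, window patterns, region flags.

Builds a wobble and a double-mismatch variant by hand and shows how the
classifier names them.  G-U means G on the 5p strand (the strand that
carries the position coordinate); seedMW flags any non-Watson-Crick pair at
upper-stem positions 4-8, midMW at 7-9 / 10-12.
"""

from pristem import classify_variant
from pristem.designs import single_window_design

design = single_window_design(4)  # one randomized window at positions 4-6

seq = list(design.full_sequence)
seq[design.index5p(4)] = "G"   # wobble G-U at position 4
seq[design.index3p(4)] = "U"
rec = classify_variant("".join(seq), design)
print("wobble variant:", rec.pair_classes[4], rec.subgroup, rec.window_pattern)
print("  seedMW:", rec.seedMW, " midMW_7_9:", rec.midMW_7_9)

seq[design.index5p(5)] = "C"   # add mismatches at positions 5 and 6
seq[design.index3p(5)] = "C"
seq[design.index5p(6)] = "A"
seq[design.index3p(6)] = "A"
rec = classify_variant("".join(seq), design)
print("wobble+2xMM variant:", {p: rec.pair_classes[p] for p in (4, 5, 6)})
print("  subgroup:", rec.subgroup, "(mismatched wins)  pattern:", rec.window_pattern)
# patterns code mismatch count/adjacency: Mmm one MM, MMm adjacent pair,
# MmM separated pair, MMM triple; 'mixed' when wobbles and MMs co-occur
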