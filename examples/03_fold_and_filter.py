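"""Fold hairpins and filter a library on structural similarity.

Variants whose predicted structure differs from the backbone anywhere
outside their randomized window (+/- its register partners, +/- 2 nt) are
dropped before structure-sensitive aggregation, since a randomized triplet
can refold distant parts of the hairpin.
"""

from pristem import enumerate_variants, filter_by_structure, fold_hairpin
from pristem.designs import single_window_design

ss = fold_hairpin("GGGAAACCC", backend="nussinov")
print("toy hairpin:", ss.sequence, "->", ss.dotbracket, f"({ss.backend})")

design = single_window_design(4)
backbone = fold_hairpin(design.full_sequence)  # ViennaRNA when available
print("\nbackbone fold:", backbone.backend)
print(backbone.sequence)
print(backbone.dotbracket)

library = enumerate_variants(design)
kept, dropped = filter_by_structure(library, backbone)
print(f"\nstructure filter: kept {len(kept)} / {len(library)} variants "
      f"({len(dropped)} refold outside the masked window region)")
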