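"""Profile unmatched nucleotides along pri-miRNA upper stems.

For each pri-miRNA (pre-miRNA with 30-nt flanks, annotated with the first
nucleotide of the mature 5p miRNA), positions are counted 1-based from that
cleavage site and a position is 'unmatched' when it is unpaired in the
predicted structure.  Real pri-miRNAs are enriched for unmatched
nucleotides at positions 10-12, the region whose mismatches/wobbles block
unproductive cleavage.  This example uses synthetic hairpins; to run the
analysis on the MirGeneDB human set, fetch it with
scripts/fetch_mirgenedb.py and use `pristem profile`.
"""

from pristem import PriMirnaEntry, unmatched_position_profile
from pristem.designs import reverse_complement

stem = "GCAUGGCAUCGAUCGAUGCAUGC"


def hairpin(seq5p: str) -> str:
    return seq5p + "GAAA" + reverse_complement(stem)


entries = [
    PriMirnaEntry("perfect", hairpin(stem), mature5p_start=0),
    # one extra nucleotide at stem position 11 bulges out of the duplex
    PriMirnaEntry("bulge11", hairpin(stem[:10] + "A" + stem[10:]), mature5p_start=0),
]
profile = unmatched_position_profile(entries, max_position=14)
print(f"backend: {profile.backend}")
print(profile.to_frame().to_string(index=False))
print(f"\nentries with >=1 unmatched nt at positions 10-12: "
      f"{profile.count_ge1_10_12}/{profile.region_n}")
print(f"entries with 2-3 unmatched nt at positions 10-12: "
      f"{profile.count_2or3_10_12}/{profile.region_n}")
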