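#!/usr/bin/env python
"""Fetch the MirGeneDB human pri-miRNA set for the cross-species profile.

Run this on a machine with network access:

    python scripts/fetch_mirgenedb.py --out data/external/mirgenedb

It downloads the human precursor sequences with 30-nt flanks and the mature
sequences from mirgenedb.org, locates the mature-5p start inside each
pri-miRNA, and writes the two files the profile analysis expects:

    hsa_pri30.fasta   pri-miRNA sequences (pre-miRNA +/- 30 nt)
    hsa_annot.tsv     id, mature5p_start (0-based), species

Entries whose 5p mature cannot be located unambiguously in the pri sequence
are skipped and reported.  MirGeneDB download URLs occasionally change
between releases; adjust --pri-url/--mat-url if needed.
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

PRI_URL = "https://mirgenedb.org/fasta/hsa?pri=1"
MAT_URL = "https://mirgenedb.org/fasta/hsa?mat=1"


def read_fasta(text: str) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks).upper().replace("T", "U")
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks).upper().replace("T", "U")
    return records


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/external/mirgenedb"))
    parser.add_argument("--pri-url", default=PRI_URL)
    parser.add_argument("--mat-url", default=MAT_URL)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pri = read_fasta(urllib.request.urlopen(args.pri_url).read().decode())
    mat = read_fasta(urllib.request.urlopen(args.mat_url).read().decode())
    matures_5p = {k: v for k, v in mat.items() if k.endswith("5p")}

    kept, skipped = [], []
    for pri_id, seq in pri.items():
        gene = pri_id.replace("_pri", "")
        candidates = [
            s for k, s in matures_5p.items() if k.startswith(gene)
        ]
        starts = {seq.find(c) for c in candidates if seq.find(c) >= 0}
        if len(starts) == 1:
            kept.append((pri_id, seq, starts.pop()))
        else:
            skipped.append(pri_id)

    with open(args.out / "hsa_pri30.fasta", "w") as fh:
        for pri_id, seq, _start in kept:
            fh.write(f">{pri_id}\n{seq}\n")
    with open(args.out / "hsa_annot.tsv", "w") as fh:
        fh.write("id\tmature5p_start\tspecies\n")
        for pri_id, _seq, start in kept:
            fh.write(f"{pri_id}\t{start}\thsa\n")
    print(f"wrote {len(kept)} entries to {args.out}; skipped {len(skipped)}")
    if skipped:
        print("skipped (no unambiguous 5p mature):", ", ".join(skipped[:10]), "...")


if __name__ == "__main__":
    main()
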