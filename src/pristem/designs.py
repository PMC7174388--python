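"""Built-in reference hairpin designs.

The bundled one-junction backbone mirrors the published screening
substrate's geometry: a 6-nt single-stranded basal segment, a 13-bp lower
stem (the canonical DROSHA cut falls 13 nt from the basal junction), a
17-bp perfectly Watson-Crick upper stem and a stable apical tetraloop.  The
backbone sequence itself is synthetic -- the screen's actual oligo
sequences are not reproduced here -- but every coordinate-dependent result
(cut-site calling, window tiling, pair classification) is independent of
the backbone letters.
"""

from __future__ import annotations

from .variant_library import HairpinDesign

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

BASAL5 = "UUAGCA"
LOWER5P = "GCAGUCAGGCAUC"  # 13 bp lower stem
UPPER5P = "GAUCGUACGCAUGGCAU"  # 17 bp upper stem
LOOP = "GAAA"
BASAL3 = "AAUCGU"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def one_junction_design(
    name: str = "arti",
    windows: tuple[tuple[str, int], ...] | None = None,
) -> HairpinDesign:
    """One-junction hairpin with an apical loop closing the 30-bp stem.

    ``windows`` defaults to the 11 sliding 3-nt windows G1..G11 tiling
    upper-stem positions 1-13.
    """
    if windows is None:
        windows = tuple((f"G{i}", i) for i in range(1, 12))
    seq5p = BASAL5 + LOWER5P + UPPER5P
    seq3p = reverse_complement(UPPER5P) + reverse_complement(LOWER5P) + BASAL3
    return HairpinDesign.duplex(
        name=name,
        seq5p=seq5p,
        loop=LOOP,
        seq3p=seq3p,
        basal_junction=len(BASAL5),
        stem_pairs=len(LOWER5P) + len(UPPER5P),
        windows=windows,
    )


def single_window_design(start: int, name: str | None = None) -> HairpinDesign:
    """Same backbone with a single randomized window at positions
    ``start..start+2`` (4096 variants)."""
    label = f"G{start}"
    return one_junction_design(
        name=name or f"arti_{label}", windows=((label, start),)
    )


def design_to_yaml(design: HairpinDesign, path) -> None:
    """Serialize a duplex design to the key-value schema."""
    import yaml

    payload = {
        "name": design.name,
        "seq5p": design.seq5p,
        "loop": design.loop,
        "seq3p": design.seq3p,
        "basal_junction": design.basal_junction,
        "pairing_register": [list(p) for p in design.pairing_register],
        "windows": [{"label": w.label, "start": w.start} for w in design.windows],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
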