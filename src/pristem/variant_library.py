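"""Randomized hairpin variant libraries and base-pair classification.

A pri-miRNA hairpin substrate is described by a :class:`HairpinDesign`: the
5p strand (5'->3', including the single-stranded basal segment), an apical
loop, the 3p strand (5'->3'), a pairing register between the two strands and
a set of randomized 3-bp windows in the upper stem.  DROSHA's canonical
cleavage site (CL0) sits 13 nt from the basal junction; upper-stem positions
are numbered 1-based starting at the first nucleotide 3' of that cut on the
5p strand.

Each randomized window substitutes all 4^6 ordered combinations of three 5p
nucleotides and their three register partners on the 3p strand.  Libraries
built from several windows share sequences (any variant whose mutated
positions fit inside two windows is generated by both), so full sequences
are deduplicated across windows and every unique variant records all the
window groups that contain it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

NUCLEOTIDES = "ACGU"
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

#: Distance (nt) from the basal junction to the canonical CL0 cut.
CL0_DISTANCE = 13

#: Window width (nt) of a randomized group.
WINDOW_WIDTH = 3


class DesignError(ValueError):
    """Raised for inconsistent hairpin designs or malformed variants."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; reject anything outside ACGU."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(NUCLEOTIDES)
    if bad:
        raise DesignError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return s


def classify_pair(n5: str, n3: str) -> str:
    """Classify an ordered base pair (5p nucleotide, 3p nucleotide).

    Returns one of ``WC``, ``GU`` (G on the 5p strand), ``UG`` (G on the 3p
    strand) or ``MM``.  Of the 16 ordered pairs, 4 are WC, 1 GU, 1 UG and
    10 MM.
    """
    if (n5, n3) in WC_PAIRS:
        return "WC"
    if n5 == "G" and n3 == "U":
        return "GU"
    if n5 == "U" and n3 == "G":
        return "UG"
    return "MM"


@dataclass(frozen=True)
class Window:
    """A randomized group covering three consecutive upper-stem positions."""

    label: str
    start: int  # 1-based upper-stem position of the first randomized pair

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.start + WINDOW_WIDTH))


@dataclass(frozen=True)
class HairpinDesign:
    """Hairpin backbone with coordinates, pairing register and windows.

    ``basal_junction`` is a between-nucleotide (0-based, half-open) boundary
    on ``seq5p`` where the lower stem begins; ``cl0_cut`` is always 13 nt
    further 3'.  ``pairing_register`` maps 0-based ``seq5p`` indices to
    0-based ``seq3p`` indices, one-to-one.
    """

    name: str
    seq5p: str
    seq3p: str
    loop: str
    basal_junction: int
    pairing_register: tuple[tuple[int, int], ...]
    windows: tuple[Window, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq5p", normalize_rna(self.seq5p))
        object.__setattr__(self, "seq3p", normalize_rna(self.seq3p) if self.seq3p else "")
        object.__setattr__(self, "loop", normalize_rna(self.loop) if self.loop else "")
        self._validate()

    # -- coordinates ---------------------------------------------------
    @property
    def cl0_cut(self) -> int:
        """Between-nucleotide index on seq5p of the canonical cut."""
        return self.basal_junction + CL0_DISTANCE

    @property
    def full_sequence(self) -> str:
        return self.seq5p + self.loop + self.seq3p

    @property
    def register_map(self) -> dict[int, int]:
        return dict(self.pairing_register)

    def index5p(self, position: int) -> int:
        """Full-sequence index of the 5p nucleotide at upper-stem ``position``."""
        return self.cl0_cut + position - 1

    def index3p(self, position: int) -> int:
        """Full-sequence index of the register partner of ``position``."""
        i5p = self.index5p(position)
        try:
            i3p = self.register_map[i5p]
        except KeyError:
            raise DesignError(
                f"upper-stem position {position} has no register partner"
            ) from None
        return len(self.seq5p) + len(self.loop) + i3p

    def upper_stem_positions(self) -> list[int]:
        """All 1-based upper-stem positions covered by the register."""
        return sorted(
            i5p - self.cl0_cut + 1 for i5p, _ in self.pairing_register if i5p >= self.cl0_cut
        )

    def window_indices(self, window: Window) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """(5p indices, 3p indices) in full-sequence coordinates."""
        p5 = tuple(self.index5p(p) for p in window.positions)
        p3 = tuple(self.index3p(p) for p in window.positions)
        return p5, p3

    def cut_index(self, x: int) -> int:
        """Between-nucleotide full-sequence index of the CLx cut (x=0 is CL0)."""
        return self.cl0_cut + x

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        if not 0 <= self.basal_junction < len(self.seq5p):
            raise DesignError("basal_junction outside seq5p")
        reg = self.register_map
        if len(reg) != len(self.pairing_register):
            raise DesignError("pairing_register has duplicate 5p indices")
        if len(set(reg.values())) != len(reg):
            raise DesignError("pairing_register is not one-to-one")
        for i5p, i3p in self.pairing_register:
            if not 0 <= i5p < len(self.seq5p):
                raise DesignError(f"register 5p index {i5p} outside seq5p")
            if not 0 <= i3p < len(self.seq3p):
                raise DesignError(f"register 3p index {i3p} outside seq3p")
        upper = set(self.upper_stem_positions())
        for w in self.windows:
            if w.start < 1:
                raise DesignError(f"window {w.label} starts below position 1")
            missing = [p for p in w.positions if p not in upper]
            if missing:
                raise DesignError(
                    f"window {w.label} covers unpaired/out-of-stem positions {missing}"
                )

    # -- construction helpers ------------------------------------------
    @classmethod
    def duplex(
        cls,
        name: str,
        seq5p: str,
        loop: str,
        seq3p: str,
        basal_junction: int,
        stem_pairs: int,
        windows: Iterable[tuple[str, int]] = (),
    ) -> "HairpinDesign":
        """Build a design whose stem is a contiguous duplex of ``stem_pairs``.

        5p stem nucleotide k (0-based from the basal junction) pairs with
        seq3p index ``stem_pairs - 1 - k`` (the 3p strand descends from the
        apical end).
        """
        register = tuple(
            (basal_junction + k, stem_pairs - 1 - k) for k in range(stem_pairs)
        )
        wins = tuple(Window(label, start) for label, start in windows)
        return cls(name, seq5p, seq3p, loop, basal_junction, register, wins)

    @classmethod
    def from_yaml(cls, path) -> "HairpinDesign":
        """Load a design from the documented key-value (YAML) schema.

        Required keys: ``name``, ``seq5p``, ``seq3p``, ``basal_junction`` and
        either ``stem_pairs`` (contiguous duplex register) or
        ``pairing_register`` (explicit ``[i5p, i3p]`` pairs).  Optional:
        ``loop`` and ``windows`` (list of ``{label, start}`` or the string
        ``tile``, which tiles upper-stem positions 1..13 with the 11 sliding
        3-nt windows named G1..G11).
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        windows = raw.get("windows", [])
        if windows == "tile":
            windows = [{"label": f"G{i}", "start": i} for i in range(1, 12)]
        win_list = [(w["label"], int(w["start"])) for w in windows]
        if "stem_pairs" in raw:
            return cls.duplex(
                raw["name"], raw["seq5p"], raw.get("loop", ""), raw["seq3p"],
                int(raw["basal_junction"]), int(raw["stem_pairs"]), win_list,
            )
        register = tuple((int(a), int(b)) for a, b in raw["pairing_register"])
        wins = tuple(Window(lbl, s) for lbl, s in win_list)
        return cls(
            raw["name"], raw["seq5p"], raw["seq3p"], raw.get("loop", ""),
            int(raw["basal_junction"]), register, wins,
        )


@dataclass
class VariantRecord:
    """Annotation of a single library member."""

    variant_id: str
    full_sequence: str
    groups: tuple[str, ...]
    pair_classes: dict[int, str | None]  # upper-stem position -> class
    window_pattern: dict[str, str]  # window label -> code
    subgroup: str  # matched | wobble | mismatched
    seedMW: bool
    midMW_7_9: bool
    midMW_10_12: bool


@dataclass
class VariantLibrary:
    """Deduplicated variant library for one design."""

    design: HairpinDesign
    id_to_seq: dict[str, str]
    groups: dict[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.id_to_seq)

    @property
    def seq_to_id(self) -> dict[str, str]:
        return {s: i for i, s in self.id_to_seq.items()}

    @property
    def backbone_id(self) -> str:
        return self.seq_to_id[self.design.full_sequence]

    def sequences(self) -> Iterable[tuple[str, str]]:
        return self.id_to_seq.items()

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for vid, seq in self.id_to_seq.items():
                fh.write(f">{vid} groups={','.join(self.groups[vid])}\n{seq}\n")

    def annotate(self):
        """Classify every variant; returns a pandas DataFrame (one row each)."""
        import pandas as pd

        rows = []
        for vid, seq in self.id_to_seq.items():
            rec = classify_variant(seq, self.design, groups=self.groups[vid], variant_id=vid)
            row = {
                "variant_id": vid,
                "groups": ",".join(rec.groups),
                "subgroup": rec.subgroup,
                "seedMW": rec.seedMW,
                "midMW_7_9": rec.midMW_7_9,
                "midMW_10_12": rec.midMW_10_12,
            }
            for pos, cls in rec.pair_classes.items():
                row[f"class_p{pos}"] = cls
            for label, code in rec.window_pattern.items():
                row[f"pattern_{label}"] = code
            rows.append(row)
        return pd.DataFrame(rows).set_index("variant_id")


def pattern_code(classes: Sequence[str]) -> str:
    """Window pattern code from the three pair classes of a window.

    Codes follow mismatch/wobble count and adjacency: ``Mmm`` one mismatch
    anywhere, ``MMm`` two adjacent, ``MmM`` two separated by a match, ``MMM``
    three; ``Wmm``/``WWm``/``WmW``/``WWW`` likewise for wobbles; ``mmm``
    all Watson-Crick; ``mixed`` when mismatches and wobbles co-occur.
    Positions without a register partner (class ``None``) are excluded.
    """
    usable = [c for c in classes if c is not None]
    mm = [i for i, c in enumerate(usable) if c == "MM"]
    wob = [i for i, c in enumerate(usable) if c in ("GU", "UG")]
    if mm and wob:
        return "mixed"
    letter, idx = ("M", mm) if mm else ("W", wob)
    if not idx:
        return "mmm"
    n = len(idx)
    if n == 1:
        return f"{letter}mm"
    if n == 3:
        return letter * 3
    adjacent = idx[1] - idx[0] == 1
    return f"{letter}{letter}m" if adjacent else f"{letter}m{letter}"


def enumerate_variants(design: HairpinDesign) -> VariantLibrary:
    """Generate all window substitutions and deduplicate full sequences.

    For each window, all 4^6 ordered (5p-triplet, 3p-triplet) substitutions
    of the backbone are generated.  Sequences generated by several windows
    are stored once with every containing group recorded.  For L >= 3 tiled
    positions the unique count obeys
    ``1 + 15 L + 225 (2 L - 3) + 3375 (L - 2)``.
    """
    if not design.windows:
        raise DesignError("design has no randomized windows")
    backbone = design.full_sequence
    seq_groups: dict[str, set[str]] = {}
    for window in design.windows:
        p5, p3 = design.window_indices(window)
        indices = p5 + p3
        for i in indices:
            if backbone[i] not in NUCLEOTIDES:
                raise DesignError(f"degenerate backbone base at index {i}")
        template = list(backbone)
        for combo in itertools.product(NUCLEOTIDES, repeat=2 * WINDOW_WIDTH):
            for i, nt in zip(indices, combo):
                template[i] = nt
            seq = "".join(template)
            seq_groups.setdefault(seq, set()).add(window.label)
    ordered = sorted(seq_groups)
    width = max(5, len(str(len(ordered))))
    id_to_seq = {f"{design.name}_v{i:0{width}d}": s for i, s in enumerate(ordered)}
    label_order = {w.label: j for j, w in enumerate(design.windows)}
    groups = {
        vid: tuple(sorted(seq_groups[seq], key=label_order.__getitem__))
        for vid, seq in id_to_seq.items()
    }
    return VariantLibrary(design, id_to_seq, groups)


def expected_unique_count(n_positions: int) -> int:
    """Closed-form unique-variant count for sliding 3-windows tiling
    ``n_positions`` upper-stem positions (n_positions >= 3).

    Counts sequences by their set of mutated pair positions: the backbone
    (1), one mutated pair (15 ordered non-backbone pairs at each of L
    positions), two within distance <= 2 (2L-3 position pairs x 15^2) and
    three consecutive (L-2 triples x 15^3).
    """
    L = n_positions
    if L < WINDOW_WIDTH:
        raise ValueError("closed form requires at least 3 tiled positions")
    return 1 + 15 * L + 225 * (2 * L - 3) + 3375 * (L - 2)


def classify_variant(
    variant: str,
    design: HairpinDesign,
    groups: Sequence[str] | None = None,
    variant_id: str = "",
) -> VariantRecord:
    """Classify one variant's base-pair structure against its design.

    Assigns a :func:`classify_pair` class to every upper-stem position in
    the pairing register, a pattern code per containing window, the
    matched/wobble/mismatched subgroup (precedence mismatched > wobble) and
    the seedMW (any non-WC at positions 4-8) and midMW (7-9, 10-12) region
    flags.
    """
    variant = normalize_rna(variant)
    backbone = design.full_sequence
    if len(variant) != len(backbone):
        raise DesignError(
            f"variant length {len(variant)} != backbone length {len(backbone)}"
        )
    allowed: set[int] = set()
    window_by_label = {w.label: w for w in design.windows}
    for w in design.windows:
        p5, p3 = design.window_indices(w)
        allowed.update(p5)
        allowed.update(p3)
    diffs = {i for i, (a, b) in enumerate(zip(variant, backbone)) if a != b}
    stray = diffs - allowed
    if stray:
        raise DesignError(f"variant differs from backbone outside randomized positions: {sorted(stray)}")

    if groups is None:
        groups = tuple(
            w.label
            for w in design.windows
            if diffs <= set(design.window_indices(w)[0]) | set(design.window_indices(w)[1])
        )
    groups = tuple(groups)

    pair_classes: dict[int, str | None] = {}
    reg = design.register_map
    offset3p = len(design.seq5p) + len(design.loop)
    for pos in design.upper_stem_positions():
        i5p = design.index5p(pos)
        i3p = reg.get(i5p)
        if i3p is None:
            pair_classes[pos] = None
            continue
        pair_classes[pos] = classify_pair(variant[i5p], variant[offset3p + i3p])

    window_pattern = {
        label: pattern_code([pair_classes.get(p) for p in window_by_label[label].positions])
        for label in groups
        if label in window_by_label
    }

    classes = [c for c in pair_classes.values() if c is not None]
    if "MM" in classes:
        subgroup = "mismatched"
    elif "GU" in classes or "UG" in classes:
        subgroup = "wobble"
    else:
        subgroup = "matched"

    def region_flag(lo: int, hi: int) -> bool:
        return any(
            pair_classes.get(p) not in (None, "WC") for p in range(lo, hi + 1)
        )

    return VariantRecord(
        variant_id=variant_id,
        full_sequence=variant,
        groups=groups,
        pair_classes=pair_classes,
        window_pattern=window_pattern,
        subgroup=subgroup,
        seedMW=region_flag(4, 8),
        midMW_7_9=region_flag(7, 9),
        midMW_10_12=region_flag(10, 12),
    )
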