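"""Secondary structure: folding backends, structure filtering, stem profiles.

Folding is pluggable.  The preferred backend is the ViennaRNA MFE folder
(``import RNA``, default settings); a built-in Nussinov-style base-pair
maximization (minimum hairpin loop 3, G-U allowed, deterministic traceback)
serves as a dependency-free approximation.  Every result records which
backend produced it, since predicted structures drift between folder
versions.

The cross-species analysis asks, for a set of pri-miRNAs annotated with the
first nucleotide of their mature 5p miRNA (the DROSHA cleavage site), how
often each upper-stem position carries an unmatched (unpaired) nucleotide on
the 5p strand.  Unmatched nucleotides cluster at positions 10-12, the
region where mismatches and wobbles block unproductive cleavage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .variant_library import HairpinDesign, VariantLibrary, normalize_rna

logger = logging.getLogger(__name__)

#: Pairs the built-in folder may form (Watson-Crick + wobble).
_CAN_PAIR = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}

#: Minimum number of unpaired nucleotides enclosed by a hairpin loop.
MIN_LOOP = 3


class FoldingError(RuntimeError):
    """Raised when the configured folding backend fails."""


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str
    dotbracket: str
    backend: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise FoldingError("structure/sequence length mismatch")
        self.pair_table  # validates bracket balance

    @property
    def pair_table(self) -> tuple[int | None, ...]:
        """Partner index per position (None when unpaired)."""
        table: list[int | None] = [None] * len(self.dotbracket)
        stack: list[int] = []
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise FoldingError("unbalanced dot-bracket string")
                j = stack.pop()
                table[i], table[j] = j, i
            elif ch != ".":
                raise FoldingError(f"unexpected structure character {ch!r}")
        if stack:
            raise FoldingError("unbalanced dot-bracket string")
        return tuple(table)

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def unpaired(self, index: int) -> bool:
        return self.dotbracket[index] == "."


def _vienna_fold(sequence: str) -> tuple[str, str]:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - vienna present in CI env
        raise FoldingError("ViennaRNA backend requested but 'RNA' is not importable") from exc
    db, _mfe = RNA.fold(sequence)
    version = getattr(RNA, "__version__", "unknown")
    return db, f"ViennaRNA {version} (MFE, default settings)"


def nussinov_fold(sequence: str) -> str:
    """Base-pair maximization with minimum loop 3 and wobble pairs.

    Dynamic program ``N[i][j] = max(N[i][j-1], max_k N[i][k-1] + 1 +
    N[k+1][j-1])`` over ``k`` with ``(s[k], s[j])`` pairable and
    ``j - k > MIN_LOOP``.  Traceback prefers the lowest pairing index that
    attains the maximum, which makes the returned structure deterministic
    among co-optimal ones.
    """
    s = sequence
    n = len(s)
    N = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]
            for k in range(i, j - MIN_LOOP):
                if (s[k], s[j]) in _CAN_PAIR:
                    cand = 1 + N[k + 1][j - 1] + (N[i][k - 1] if k > i else 0)
                    if cand > best:
                        best = cand
            N[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        target = N[i][j]
        paired = False
        for k in range(i, j - MIN_LOOP):
            if (s[k], s[j]) in _CAN_PAIR:
                cand = 1 + N[k + 1][j - 1] + (N[i][k - 1] if k > i else 0)
                if cand == target:
                    structure[k], structure[j] = "(", ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return "".join(structure)


def fold_hairpin(sequence: str, backend: str = "auto") -> SecondaryStructure:
    """Predict the secondary structure of an RNA sequence.

    ``backend`` is one of ``auto`` (ViennaRNA if importable, else the
    built-in folder), ``vienna`` or ``nussinov``.
    """
    seq = normalize_rna(sequence)
    if not seq:
        raise FoldingError("empty sequence")
    if backend == "auto":
        try:
            import RNA  # noqa: F401
            backend = "vienna"
        except ImportError:
            backend = "nussinov"
    if backend == "vienna":
        db, name = _vienna_fold(seq)
        return SecondaryStructure(seq, db, name)
    if backend == "nussinov":
        return SecondaryStructure(seq, nussinov_fold(seq), "built-in Nussinov (max pairs, min loop 3)")
    raise FoldingError(f"unknown folding backend {backend!r}")


# ---------------------------------------------------------------------------
# structure-similarity filtering of variant libraries


def masked_indices(design: HairpinDesign, groups: Sequence[str], margin: int = 2) -> set[int]:
    """Full-sequence indices excluded from structure comparison for a variant.

    The union, over the variant's windows, of the randomized positions and
    their register partners, each expanded by ``margin`` nt up- and
    downstream.
    """
    by_label = {w.label: w for w in design.windows}
    n = len(design.full_sequence)
    mask: set[int] = set()
    for label in groups:
        p5, p3 = design.window_indices(by_label[label])
        for block in (p5, p3):
            lo, hi = min(block) - margin, max(block) + margin
            mask.update(range(max(0, lo), min(n, hi + 1)))
    return mask


def filter_by_structure(
    library: VariantLibrary,
    backbone_structure: SecondaryStructure | None = None,
    margin: int = 2,
    backend: str = "auto",
    fold: Callable[[str], SecondaryStructure] | None = None,
) -> tuple[list[str], list[str]]:
    """Partition a library into (kept, dropped) variant ids.

    A variant is kept iff its predicted dot-bracket equals the backbone's at
    every position outside its masked region (randomized windows, their
    register partners, +/- ``margin`` nt).  Backbone and variants are folded
    with the same backend.
    """
    folder = fold if fold is not None else (lambda s: fold_hairpin(s, backend=backend))
    if backbone_structure is None:
        backbone_structure = folder(library.design.full_sequence)
    bb = backbone_structure.dotbracket
    if len(bb) != len(library.design.full_sequence):
        raise FoldingError("backbone structure length mismatch")
    kept: list[str] = []
    dropped: list[str] = []
    mask_cache: dict[tuple[str, ...], set[int]] = {}
    for vid, seq in library.sequences():
        groups = library.groups[vid]
        mask = mask_cache.get(groups)
        if mask is None:
            mask = masked_indices(library.design, groups, margin)
            mask_cache[groups] = mask
        db = folder(seq).dotbracket
        if all(db[i] == bb[i] for i in range(len(bb)) if i not in mask):
            kept.append(vid)
        else:
            dropped.append(vid)
    return kept, dropped


# ---------------------------------------------------------------------------
# cross-species unmatched-nucleotide profile


@dataclass(frozen=True)
class PriMirnaEntry:
    """A pri-miRNA: pre-miRNA with 30-nt flanks and the mature-5p start."""

    id: str
    sequence: str
    mature5p_start: int  # 0-based index of the first mature-5p nucleotide
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not 0 <= self.mature5p_start < len(self.sequence):
            raise ValueError(f"{self.id}: mature5p_start outside sequence")


@dataclass
class UnmatchedProfile:
    """Per-position unmatched-nucleotide frequencies over a pri-miRNA set."""

    frequencies: dict[int, float]
    denominators: dict[int, int]
    n_entries: int
    n_skipped: int
    count_ge1_10_12: int
    count_2or3_10_12: int
    region_n: int
    backend: str

    @property
    def fraction_ge1_10_12(self) -> float:
        return self.count_ge1_10_12 / self.region_n if self.region_n else float("nan")

    @property
    def fraction_2or3_10_12(self) -> float:
        return self.count_2or3_10_12 / self.region_n if self.region_n else float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": sorted(self.frequencies),
                "unmatched_frequency": [self.frequencies[p] for p in sorted(self.frequencies)],
                "n": [self.denominators[p] for p in sorted(self.frequencies)],
            }
        )


def unmatched_position_profile(
    entries: Iterable[PriMirnaEntry],
    max_position: int = 22,
    backend: str = "auto",
    fold: Callable[[str], SecondaryStructure] | None = None,
) -> UnmatchedProfile:
    """Profile unmatched 5p-strand nucleotides along the upper stem.

    Position ``i`` (1-based from the mature-5p start, i.e. from the DROSHA
    cleavage site) is unmatched iff that nucleotide is unpaired in the
    predicted structure.  Positions past the end of a given entry only count
    toward positions the entry actually has.  Region counts report entries
    with >= 1 and with 2-3 unmatched nucleotides at positions 10-12; an
    entry enters the region denominator only if position 12 exists.
    """
    folder = fold if fold is not None else (lambda s: fold_hairpin(s, backend=backend))
    unmatched = {p: 0 for p in range(1, max_position + 1)}
    denom = {p: 0 for p in range(1, max_position + 1)}
    n_used = n_skipped = region_n = ge1 = two3 = 0
    backend_name = ""
    for entry in entries:
        try:
            ss = folder(entry.sequence)
        except FoldingError as exc:
            logger.warning("skipping %s: %s", entry.id, exc)
            n_skipped += 1
            continue
        backend_name = ss.backend
        if entry.mature5p_start >= len(entry.sequence):
            logger.warning("skipping %s: mature5p_start beyond folded stem", entry.id)
            n_skipped += 1
            continue
        n_used += 1
        flags = {}
        for p in range(1, max_position + 1):
            idx = entry.mature5p_start + p - 1
            if idx >= len(entry.sequence):
                break
            denom[p] += 1
            flags[p] = ss.unpaired(idx)
            if flags[p]:
                unmatched[p] += 1
        if 12 in flags:
            region_n += 1
            k = sum(flags[p] for p in (10, 11, 12))
            if k >= 1:
                ge1 += 1
            if k in (2, 3):
                two3 += 1
    freqs = {p: (unmatched[p] / denom[p] if denom[p] else float("nan")) for p in denom}
    return UnmatchedProfile(
        frequencies=freqs,
        denominators=denom,
        n_entries=n_used,
        n_skipped=n_skipped,
        count_ge1_10_12=ge1,
        count_2or3_10_12=two3,
        region_n=region_n,
        backend=backend_name,
    )


def load_primirna_entries(fasta_path, annot_path) -> list[PriMirnaEntry]:
    """Load pri-miRNAs from FASTA plus a TSV sidecar.

    The sidecar has a header line and columns ``id``, ``mature5p_start``
    (0-based) and optional ``species``.
    """
    from Bio import SeqIO

    import pandas as pd

    annot = pd.read_csv(annot_path, sep="\t").set_index("id")
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in annot.index:
            logger.warning("no annotation for %s; skipped", rec.id)
            continue
        row = annot.loc[rec.id]
        entries.append(
            PriMirnaEntry(
                id=rec.id,
                sequence=str(rec.seq),
                mature5p_start=int(row["mature5p_start"]),
                species=str(row.get("species", "")),
            )
        )
    return entries


def write_dotbracket(records: Iterable[tuple[str, SecondaryStructure]], path) -> None:
    """Write Vienna-format dot-bracket records (>id / sequence / structure)."""
    with open(path, "w") as fh:
        for name, ss in records:
            fh.write(f">{name}\n{ss.sequence}\n{ss.dotbracket}\n")
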