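"""Reads -> per-variant, per-cleavage-site count tables.

Sample classes follow the endpoint processing assay: ``S`` (original
substrate pool), ``US`` (uncleaved substrate recovered after the reaction)
and ``P`` (cleaved products).  Each sequenced molecule carries a 6-nt random
barcode (UMI) at its 5' end; reads identical over UMI+insert are PCR
duplicates and are collapsed before counting.

Assignment is by exact lookup against the designed reference library, the
in-silico equivalent of keeping only perfectly mapped reads: substrate reads
must equal a library sequence over the full length, product reads must equal
the suffix of a library sequence starting at a cut CLx with x in [-6, +1]
(the product's first nucleotide sits at upper-stem position x+1).  A product
read that no longer contains a randomized 5p position can be shared by
several variants; such reads are tallied as ambiguous, not assigned.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .variant_library import HairpinDesign, VariantLibrary

logger = logging.getLogger(__name__)

SAMPLE_CLASSES = ("S", "US", "P")
#: Observed cut-site range (offsets from CL0).
CUT_RANGE = tuple(range(-6, 2))
#: Raw-count cutoffs per sample class; US inherits the substrate cutoff.
DEFAULT_CUTOFFS = {"S": 30, "US": 30, "P": 15}
DEFAULT_UMI_LENGTH = 6

_AMBIGUOUS = object()


class ReadProcessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# I/O


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path) -> Iterator[str]:
    """Yield read sequences from FASTQ or FASTA (optionally gzipped).

    Raises :class:`ReadProcessingError` naming the file and record index on
    a corrupt FASTQ record.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = str(path)
    is_fasta = path.rstrip(".gz").endswith((".fa", ".fasta", ".fna"))
    with _open_text(path) as fh:
        if is_fasta:
            for _title, seq in SimpleFastaParser(fh):
                yield seq.upper().replace("T", "U")
        else:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                try:
                    rec = next(it, None)
                except ValueError as exc:
                    raise ReadProcessingError(f"{path}: corrupt FASTQ record {i}: {exc}") from exc
                if rec is None:
                    break
                yield rec[1].upper().replace("T", "U")
                i += 1


# ---------------------------------------------------------------------------
# preprocessing: UMI collapse + adapter trimming


@dataclass
class PreprocessStats:
    total: int = 0
    duplicates_removed: int = 0
    too_short: int = 0
    unique: int = 0


def preprocess_reads(
    reads: Iterable[str],
    umi_length: int = DEFAULT_UMI_LENGTH,
    adapter5: str = "",
    adapter3: str = "",
) -> tuple[list[str], PreprocessStats]:
    """Collapse PCR duplicates and strip the UMI and any exact adapters.

    Duplicates are reads identical over the 5'-terminal UMI plus insert;
    one survivor is kept per unique molecule.  The UMI is then discarded and
    adapters, when configured, are removed by exact prefix/suffix match.
    Reads no longer than the UMI are dropped and counted.
    """
    counts = Counter(reads)
    stats = PreprocessStats(total=sum(counts.values()))
    stats.duplicates_removed = stats.total - len(counts)
    inserts: list[str] = []
    for read in counts:
        if len(read) <= umi_length:
            stats.too_short += 1
            continue
        insert = read[umi_length:] if umi_length else read
        if adapter5 and insert.startswith(adapter5):
            insert = insert[len(adapter5):]
        if adapter3 and insert.endswith(adapter3):
            insert = insert[: len(insert) - len(adapter3)]
        if not insert:
            stats.too_short += 1
            continue
        inserts.append(insert)
    stats.unique = len(inserts)
    return inserts, stats


# ---------------------------------------------------------------------------
# exact-match reference assignment and cleavage-site calling


class ReferenceIndex:
    """Exact-lookup index of library sequences and their CLx suffixes."""

    def __init__(
        self,
        library: VariantLibrary,
        cut_range: Sequence[int] = CUT_RANGE,
    ) -> None:
        self.library = library
        self.design: HairpinDesign = library.design
        self.cut_range = tuple(cut_range)
        self.full_length = len(self.design.full_sequence)
        self.full_map: dict[str, str] = {}
        for vid, seq in library.sequences():
            if len(seq) != self.full_length:
                raise ReadProcessingError(f"{vid}: unexpected sequence length")
            self.full_map[seq] = vid
        suffix_lists: dict[str, list[tuple[str, int]]] = {}
        for vid, seq in library.sequences():
            for x in self.cut_range:
                cut = self.design.cut_index(x)
                suffix_lists.setdefault(seq[cut:], []).append((vid, x))
        self.suffix_map: dict[str, object] = {
            s: (hits[0] if len(hits) == 1 else _AMBIGUOUS)
            for s, hits in suffix_lists.items()
        }
        self._suffix_x_by_length = {
            self.full_length - self.design.cut_index(x): x for x in self.cut_range
        }

    def call_substrate(self, read: str) -> str | None:
        return self.full_map.get(read)

    def call_product(self, read: str):
        """Return (variant_id, x), ``'ambiguous'``, ``'out_of_range'`` or None."""
        if len(read) not in self._suffix_x_by_length:
            return "out_of_range"
        hit = self.suffix_map.get(read)
        if hit is None:
            return None
        if hit is _AMBIGUOUS:
            return "ambiguous"
        return hit


@dataclass
class AssignmentTallies:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    out_of_range: int = 0
    ambiguous: int = 0

    def conserved(self) -> bool:
        return self.total == self.assigned + self.unassigned + self.out_of_range + self.ambiguous


def assign_and_call(read: str, index: ReferenceIndex, sample_class: str):
    """Assign one read: (variant_id, x) for products, (variant_id, None) for
    substrates, or a tally label (``unassigned``/``out_of_range``/``ambiguous``)."""
    if sample_class not in SAMPLE_CLASSES:
        raise ReadProcessingError(f"unknown sample class {sample_class!r}")
    if sample_class in ("S", "US"):
        vid = index.call_substrate(read)
        return (vid, None) if vid is not None else "unassigned"
    hit = index.call_product(read)
    if hit is None:
        return "unassigned"
    if isinstance(hit, str):
        return hit
    return hit


def assign_reads(
    reads: Iterable[str], index: ReferenceIndex, sample_class: str
) -> tuple[Counter, AssignmentTallies]:
    """Assign a batch of reads; returns counts keyed (variant_id, site)."""
    counts: Counter = Counter()
    tallies = AssignmentTallies()
    if sample_class in ("S", "US"):
        full_map = index.full_map
        for read in reads:
            tallies.total += 1
            vid = full_map.get(read)
            if vid is None:
                tallies.unassigned += 1
            else:
                tallies.assigned += 1
                counts[(vid, None)] += 1
    else:
        call = index.call_product
        for read in reads:
            tallies.total += 1
            hit = call(read)
            if hit is None:
                tallies.unassigned += 1
            elif hit == "out_of_range":
                tallies.out_of_range += 1
            elif hit == "ambiguous":
                tallies.ambiguous += 1
            else:
                tallies.assigned += 1
                counts[hit] += 1
    return counts, tallies


# ---------------------------------------------------------------------------
# count tables


@dataclass
class CleavageCountTable:
    """Long-format raw and CPM counts per (variant, replicate, sample, site).

    ``site`` is the CLx offset for product rows and NA for substrate rows.
    CPM is computed per sample (replicate x class) over all assigned reads
    in that sample, before cutoff masking; masked (variant, replicate,
    sample) combinations fall below the raw-count cutoff and are treated as
    absent by downstream scoring.
    """

    counts: pd.DataFrame
    masked: set[tuple[str, object, str]] = field(default_factory=set)
    library_sizes: dict[tuple[str, object], int] = field(default_factory=dict)
    cutoffs: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def is_masked(self, variant_id: str, replicate, sample: str) -> bool:
        return (variant_id, replicate, sample) in self.masked

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, cutoffs: Mapping[str, int] | None = None) -> "CleavageCountTable":
        df = pd.read_csv(path, sep="\t")
        return build_count_table_from_frame(df, cutoffs or DEFAULT_CUTOFFS)


def build_count_table(
    assignments: Mapping[tuple[str, object], Counter],
    cutoffs: Mapping[str, int] | None = None,
) -> CleavageCountTable:
    """Aggregate assigned-read counters into a :class:`CleavageCountTable`.

    ``assignments`` maps (sample_class, replicate) to a Counter keyed
    (variant_id, site).  Raising a cutoff can only mask more variants, never
    fewer.
    """
    rows = []
    for (sample, replicate), counter in assignments.items():
        if sample not in SAMPLE_CLASSES:
            raise ReadProcessingError(f"unknown sample class {sample!r}")
        if not counter:
            logger.warning("empty sample %s replicate %r", sample, replicate)
        for (vid, site), raw in counter.items():
            rows.append(
                {
                    "variant_id": vid,
                    "replicate": replicate,
                    "sample": sample,
                    "site": site,
                    "raw": int(raw),
                }
            )
    df = pd.DataFrame(rows, columns=["variant_id", "replicate", "sample", "site", "raw"])
    return build_count_table_from_frame(df, cutoffs or DEFAULT_CUTOFFS)


def build_count_table_from_frame(
    df: pd.DataFrame, cutoffs: Mapping[str, int]
) -> CleavageCountTable:
    if (df["raw"] < 0).any():
        raise ReadProcessingError("negative raw counts")
    df = df.copy()
    sizes: dict[tuple[str, object], int] = {}
    cpm = pd.Series(0.0, index=df.index)
    for (sample, replicate), sub in df.groupby(["sample", "replicate"], sort=False):
        total = int(sub["raw"].sum())
        sizes[(sample, replicate)] = total
        if total > 0:
            cpm.loc[sub.index] = sub["raw"] * 1e6 / total
    df["cpm"] = cpm
    masked: set[tuple[str, object, str]] = set()
    per_variant = df.groupby(["variant_id", "replicate", "sample"], sort=False)["raw"].sum()
    for (vid, replicate, sample), raw_total in per_variant.items():
        if raw_total < cutoffs.get(sample, 0):
            masked.add((vid, replicate, sample))
    return CleavageCountTable(counts=df, masked=masked, library_sizes=sizes, cutoffs=dict(cutoffs))


# ---------------------------------------------------------------------------
# isomiR 5'-end tabulation


def tabulate_5p_isoforms(
    read_starts: Iterable[int],
    cl0_start: int,
    normalizer: float,
) -> pd.DataFrame:
    """Bin locus reads by 5'-end offset from the canonical CL0 product start.

    Returns one row per observed offset with the read count and its relative
    abundance (count / normalizer; the study normalized against miR-16-5p
    counts).  A 5' isomiR at offset -1 corresponds to a CL-1 cut.
    """
    if normalizer == 0:
        raise ReadProcessingError("normalizer count is zero; relative abundance undefined")
    offsets = Counter(start - cl0_start for start in read_starts)
    rows = [
        {"offset": off, "count": n, "relative_abundance": n / normalizer}
        for off, n in sorted(offsets.items())
    ]
    return pd.DataFrame(rows, columns=["offset", "count", "relative_abundance"])


# ---------------------------------------------------------------------------
# convenience: FASTQ -> assigned counter


def count_sample(
    path,
    index: ReferenceIndex,
    sample_class: str,
    umi_length: int = DEFAULT_UMI_LENGTH,
    adapter5: str = "",
    adapter3: str = "",
) -> tuple[Counter, PreprocessStats, AssignmentTallies]:
    """Read one sample file, collapse duplicates and assign reads."""
    inserts, pstats = preprocess_reads(
        read_sequences(path), umi_length=umi_length, adapter5=adapter5, adapter3=adapter3
    )
    counts, tallies = assign_reads(inserts, index, sample_class)
    return counts, pstats, tallies
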