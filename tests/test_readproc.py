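"""UMI collapse, exact assignment, cleavage-site calling, count tables."""

import random
from collections import Counter

import numpy as np
import pytest

from pristem.readproc import (
    CUT_RANGE,
    ReadProcessingError,
    ReferenceIndex,
    assign_and_call,
    assign_reads,
    build_count_table,
    preprocess_reads,
    read_sequences,
    tabulate_5p_isoforms,
)


# ---------------------------------------------------------------------------
# preprocessing


def test_umi_collapse_semantics():
    umi_a, umi_b = "AAAAAA", "CCCCCC"
    insert = "ACGUACGUACGU"
    reads = [umi_a + insert, umi_a + insert, umi_b + insert]
    inserts, stats = preprocess_reads(reads)
    # identical UMI+insert collapses; same insert under another UMI survives
    assert sorted(inserts) == [insert, insert]
    assert stats.duplicates_removed == 1
    assert stats.total == 3 and stats.unique == 2


def test_collapse_is_idempotent_and_short_reads_dropped():
    rng = random.Random(0)
    reads = ["".join(rng.choice("ACGU") for _ in range(20)) for _ in range(50)]
    reads = reads * 3 + ["ACGU"]  # triplicate everything, add a too-short read
    once, stats1 = preprocess_reads(reads)
    twice, stats2 = preprocess_reads(("AAAAAA" + r for r in once))
    assert sorted(r[6:] for r in set(reads) if len(r) > 6) == sorted(once)
    assert sorted(twice) == sorted(once)
    assert stats1.too_short == 1


def test_adapter_trimming_exact_match():
    reads = ["AAAAAA" + "GGUU" + "ACGUACGU" + "CCAA"]
    inserts, _ = preprocess_reads(reads, adapter5="GGUU", adapter3="CCAA")
    assert inserts == ["ACGUACGU"]


# ---------------------------------------------------------------------------
# assignment and cleavage-site calling


def test_substrate_and_product_calls(window4_library):
    lib = window4_library
    design = lib.design
    index = ReferenceIndex(lib)
    vid, seq = next(iter(lib.sequences()))
    assert assign_and_call(seq, index, "S") == (vid, None)
    assert assign_and_call(seq, index, "US") == (vid, None)
    # product starting at upper-stem position 1 is the canonical CL0 cut
    assert assign_and_call(seq[design.cut_index(0):], index, "P") == (vid, 0)
    # product starting 6 nt upstream (7 nt from the basal junction) is CL-6
    assert design.cut_index(-6) - design.basal_junction == 7
    assert assign_and_call(seq[design.cut_index(-6):], index, "P") == (vid, -6)
    # cut outside the observed range is tallied, not called
    assert assign_and_call(seq[design.cut_index(-8):], index, "P") == "out_of_range"
    assert assign_and_call("A" * len(seq), index, "S") == "unassigned"


def test_roundtrip_all_sites_all_window_variants(window4_library):
    # synthetic cut at every CLx is re-called as (variant, x): the window at
    # positions 4-6 lies downstream of every cut, so calls are unambiguous
    lib = window4_library
    design = lib.design
    index = ReferenceIndex(lib)
    rng = random.Random(42)
    vids = rng.sample(list(lib.id_to_seq), 100)
    for vid in vids:
        seq = lib.id_to_seq[vid]
        for x in CUT_RANGE:
            assert assign_and_call(seq[design.cut_index(x):], index, "P") == (vid, x)


def test_cl_plus1_product_ambiguous_when_window_covers_position_1(arti_library):
    # the CL+1 product loses the 5p nucleotide of position 1: variants of the
    # position-1 window differing only there share the identical suffix
    lib = arti_library
    design = lib.design
    index = ReferenceIndex(lib)
    g1_only = [v for v, g in lib.groups.items() if g == ("G1",)]
    seq = lib.id_to_seq[g1_only[0]]
    assert assign_and_call(seq[design.cut_index(1):], index, "P") == "ambiguous"
    # while the same variant's CL0 product is still called exactly
    assert assign_and_call(seq[design.cut_index(0):], index, "P") == (g1_only[0], 0)


def test_read_conservation(window4_library):
    lib = window4_library
    design = lib.design
    index = ReferenceIndex(lib)
    rng = random.Random(1)
    seqs = list(lib.id_to_seq.values())
    reads = []
    for _ in range(500):
        s = rng.choice(seqs)
        kind = rng.random()
        if kind < 0.5:
            reads.append(s[design.cut_index(rng.choice(CUT_RANGE)):])
        elif kind < 0.7:
            reads.append(s[design.cut_index(-9):])  # out of range
        else:
            reads.append("U" * (len(s) - design.cut_index(0)))  # unassignable
    counts, tallies = assign_reads(reads, index, "P")
    assert tallies.conserved()
    assert tallies.total == 500
    assert sum(counts.values()) == tallies.assigned


# ---------------------------------------------------------------------------
# count tables


def test_cpm_proportions_and_sum():
    assignments = {
        ("S", 1): Counter({("v1", None): 3, ("v2", None): 1}),
        ("P", 1): Counter({("v1", 0): 30, ("v1", -1): 10, ("v2", 0): 60}),
    }
    table = build_count_table(assignments, cutoffs={"S": 0, "US": 0, "P": 0})
    df = table.counts
    s = df[df["sample"] == "S"].set_index("variant_id")["cpm"]
    assert s["v1"] == pytest.approx(750_000.0)
    assert s["v2"] == pytest.approx(250_000.0)
    for (_sample, _rep), sub in df.groupby(["sample", "replicate"]):
        assert sub["cpm"].sum() == pytest.approx(1e6)


def test_cutoff_masking_is_monotone():
    assignments = {
        ("S", 1): Counter({("v1", None): 29, ("v2", None): 31}),
        ("P", 1): Counter({("v1", 0): 14, ("v2", 0): 15}),
    }
    table = build_count_table(assignments)  # defaults S:30, P:15
    assert table.is_masked("v1", 1, "S") and not table.is_masked("v2", 1, "S")
    assert table.is_masked("v1", 1, "P") and not table.is_masked("v2", 1, "P")
    stricter = build_count_table(assignments, cutoffs={"S": 40, "US": 30, "P": 20})
    assert table.masked <= stricter.masked
    looser = build_count_table(assignments, cutoffs={"S": 0, "US": 0, "P": 0})
    assert looser.masked <= table.masked


def test_negative_counts_rejected():
    import pandas as pd

    from pristem.readproc import build_count_table_from_frame

    df = pd.DataFrame(
        {"variant_id": ["v"], "replicate": [1], "sample": ["S"], "site": [None], "raw": [-1]}
    )
    with pytest.raises(ReadProcessingError):
        build_count_table_from_frame(df, {"S": 0})


# ---------------------------------------------------------------------------
# I/O


def test_fastq_reader_and_corrupt_record(tmp_path):
    good = tmp_path / "ok.fastq"
    good.write_text("@r1\nACGT\n+\nIIII\n@r2\nGGCC\n+\nIIII\n")
    assert list(read_sequences(good)) == ["ACGU", "GGCC"]
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nGGCC\n+\nII\n")
    with pytest.raises(ReadProcessingError, match="bad.fastq"):
        list(read_sequences(bad))


def test_fasta_reader(tmp_path):
    fa = tmp_path / "reads.fasta"
    fa.write_text(">a\nACGT\n>b\nGGGG\n")
    assert list(read_sequences(fa)) == ["ACGU", "GGGG"]


# ---------------------------------------------------------------------------
# isomiR 5' offsets


def test_isomir_offsets_basic():
    starts = [100] * 100 + [99] * 100
    df = tabulate_5p_isoforms(starts, cl0_start=100, normalizer=200)
    assert dict(zip(df["offset"], df["relative_abundance"])) == {-1: 0.5, 0: 0.5}
    single = tabulate_5p_isoforms([100] * 7, cl0_start=100, normalizer=14)
    assert list(single["offset"]) == [0]
    assert single["relative_abundance"].iloc[0] == pytest.approx(0.5)
    with pytest.raises(ReadProcessingError):
        tabulate_5p_isoforms(starts, 100, normalizer=0)


def test_isomir_offsets_recover_simulated_cut_mix():
    # oracle: binomial draw over two cut sites at a 70:30 CL-1:CL0 mix
    rng = np.random.default_rng(5)
    n = 20_000
    n_clm1 = rng.binomial(n, 0.7)
    starts = [99] * n_clm1 + [100] * (n - n_clm1)
    df = tabulate_5p_isoforms(starts, cl0_start=100, normalizer=n)
    rel = dict(zip(df["offset"], df["relative_abundance"]))
    assert rel[-1] == pytest.approx(0.7, abs=0.02)
    assert rel[0] == pytest.approx(0.3, abs=0.02)
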