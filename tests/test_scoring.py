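"""Score formulas against an independent recomputation, plus invariants."""

import math
import random
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from pristem.readproc import CUT_RANGE, CleavageCountTable, build_count_table
from pristem.scoring import (
    ScoringError,
    aggregate_by_pattern,
    average_replicates,
    cleavage_scores,
    positional_frequency,
    relative_score_vs_baseline,
    score_column,
)

SITES = list(CUT_RANGE)


def hand_built_table(seed=11, n_variants=10, replicates=2):
    """Raw counts for a small library, plus an independent plain-arithmetic
    recomputation of every score (spreadsheet style, no pandas)."""
    rng = random.Random(seed)
    raw = {}  # (vid, rep, sample, site) -> raw count
    for rep in range(1, replicates + 1):
        for i in range(n_variants):
            vid = f"v{i}"
            raw[(vid, rep, "S", None)] = rng.randrange(0, 500)
            raw[(vid, rep, "US", None)] = rng.randrange(0, 400)
            for x in SITES:
                raw[(vid, rep, "P", x)] = rng.randrange(0, 120)
    assignments = {}
    for rep in range(1, replicates + 1):
        for sample in ("S", "US", "P"):
            counter = Counter()
            for (vid, r, s, site), n in raw.items():
                if r == rep and s == sample and n > 0:
                    counter[(vid, site)] = n
            assignments[(sample, rep)] = counter
    table = build_count_table(assignments, cutoffs={"S": 0, "US": 0, "P": 0})

    # independent recomputation
    q = 0.1
    expected = {}
    for rep in range(1, replicates + 1):
        totals = {
            s: sum(n for (v, r, ss, x), n in raw.items() if r == rep and ss == s)
            for s in ("S", "US", "P")
        }
        for i in range(n_variants):
            vid = f"v{i}"
            cpm = lambda s, x: raw[(vid, rep, s, x)] * 1e6 / totals[s]
            n_s = cpm("S", None)
            n_us = cpm("US", None)
            n_x = {x: cpm("P", x) for x in SITES}
            n_p = sum(n_x.values())
            row = {
                "ps": math.log2(n_p + q) - math.log2(n_s + q),
                "uss": math.log2(n_us + q) - math.log2(n_s + q),
            }
            for x in SITES:
                row[score_column(x)] = math.log2(n_x[x] + q) - math.log2(n_s + q)
            total_prod = sum(raw[(vid, rep, "P", x)] for x in SITES)
            row["freqs"] = {x: raw[(vid, rep, "P", x)] / total_prod for x in SITES}
            expected[(vid, rep)] = row
    return table, expected


def test_scores_match_independent_recomputation_to_1e_minus_9():
    table, expected = hand_built_table()
    scores = cleavage_scores(table)
    freqs = positional_frequency(table)
    for (vid, rep), exp in expected.items():
        got = scores.loc[(vid, rep)]
        assert got["ps"] == pytest.approx(exp["ps"], abs=1e-9)
        assert got["uss"] == pytest.approx(exp["uss"], abs=1e-9)
        for x in SITES:
            assert got[score_column(x)] == pytest.approx(exp[score_column(x)], abs=1e-9)
            assert freqs.loc[(vid, rep), f"freq_cl{x}"] == pytest.approx(
                exp["freqs"][x], abs=1e-9
            )


def _single_row_table(n_s, n_p_by_site, n_us=0.0, rep=1):
    rows = [
        {"variant_id": "v", "replicate": rep, "sample": "S", "site": None, "raw": 1, "cpm": n_s},
        {"variant_id": "v", "replicate": rep, "sample": "US", "site": None, "raw": 1, "cpm": n_us},
    ]
    for x, n in n_p_by_site.items():
        rows.append(
            {"variant_id": "v", "replicate": rep, "sample": "P", "site": x, "raw": max(1, int(n)), "cpm": n}
        )
    return CleavageCountTable(counts=pd.DataFrame(rows), cutoffs={"S": 0, "US": 0, "P": 0})


def test_score_edge_cases_and_pseudocount():
    # equal counts -> 0; zero counts -> pseudocount cancels -> 0
    s = cleavage_scores(_single_row_table(100.0, {0: 100.0}))
    assert s["ps"].iloc[0] == pytest.approx(0.0)
    s = cleavage_scores(_single_row_table(0.0, {0: 0.0}))
    assert s["ps"].iloc[0] == pytest.approx(0.0)
    # log2((1599.9 + 0.1) / (99.9 + 0.1)) = 4 exactly
    s = cleavage_scores(_single_row_table(99.9, {0: 1599.9}))
    assert s[score_column(0)].iloc[0] == pytest.approx(4.0, abs=1e-12)


def test_score_antisymmetry_and_monotonicity():
    base = cleavage_scores(_single_row_table(50.0, {0: 400.0}))["ps"].iloc[0]
    swapped = cleavage_scores(_single_row_table(400.0, {0: 50.0}))["ps"].iloc[0]
    assert base == pytest.approx(-swapped)
    more_p = cleavage_scores(_single_row_table(50.0, {0: 500.0}))["ps"].iloc[0]
    more_s = cleavage_scores(_single_row_table(60.0, {0: 400.0}))["ps"].iloc[0]
    assert more_p > base > more_s


def test_positional_frequency_normalization_and_missing():
    table, _ = hand_built_table(seed=3, n_variants=5, replicates=1)
    freqs = positional_frequency(table)
    sums = freqs.sum(axis=1)
    assert np.allclose(sums, 1.0)
    assert ((freqs >= 0) & (freqs <= 1)).all().all()
    # a variant with zero products is missing, not zero-filled
    assignments = {
        ("S", 1): Counter({("a", None): 100, ("b", None): 100}),
        ("P", 1): Counter({("a", 0): 80, ("a", -1): 20}),
    }
    table2 = build_count_table(assignments, cutoffs={"S": 0, "US": 0, "P": 0})
    f2 = positional_frequency(table2)
    assert f2.loc[("a", 1), "freq_cl0"] == pytest.approx(0.8)
    assert f2.loc[("a", 1), "freq_cl-1"] == pytest.approx(0.2)
    assert ("b", 1) not in f2.index


def test_masked_variants_are_absent():
    assignments = {
        ("S", 1): Counter({("lo", None): 29, ("hi", None): 300}),
        ("P", 1): Counter({("lo", 0): 50, ("hi", 0): 50}),
    }
    table = build_count_table(assignments)
    scores = cleavage_scores(table)
    assert ("lo", 1) not in scores.index  # masked in S -> no scores at all
    assert ("hi", 1) in scores.index


def test_average_replicates():
    idx = pd.MultiIndex.from_tuples(
        [("v", 1), ("v", 2), ("v", 3), ("w", 2)], names=["variant_id", "replicate"]
    )
    df = pd.DataFrame({"ps": [1.0, 2.0, 3.0, 5.0]}, index=idx)
    avg = average_replicates(df)
    assert avg.loc["v", "ps"] == pytest.approx(2.0)
    assert avg.loc["v", "n_rep"] == 3
    assert avg.loc["w", "ps"] == pytest.approx(5.0)
    assert avg.loc["w", "n_rep"] == 1
    # permutation invariance over replicate order
    shuffled = average_replicates(df.iloc[[3, 1, 0, 2]])
    pd.testing.assert_frame_equal(avg, shuffled)


def _toy_annotations():
    return pd.DataFrame(
        {
            "class_p4": ["WC", "WC", "MM", "MM", "GU"],
            "class_p5": ["WC", "WC", "WC", "MM", "WC"],
            "subgroup": ["matched", "matched", "mismatched", "mismatched", "wobble"],
            "pattern_G4": ["mmm", "mmm", "Mmm", "MMm", "Wmm"],
            "seedMW": [False, False, True, True, True],
        },
        index=pd.Index([f"v{i}" for i in range(5)], name="variant_id"),
    )


def test_relative_score_is_difference_of_group_means():
    ann = _toy_annotations()
    avg = pd.DataFrame(
        {"score_cl0": [0.0, 1.0, -2.0, -4.0, -1.0]}, index=ann.index
    )
    rel = relative_score_vs_baseline(avg, ann, position=4, pair_class="MM")
    assert rel == pytest.approx((-3.0) - 0.5)
    # class set == baseline set -> 0
    assert relative_score_vs_baseline(avg, ann, 4, "WC") == pytest.approx(0.0)
    # shift invariance
    rel_shift = relative_score_vs_baseline(avg + 7.5, ann, 4, "MM")
    assert rel_shift == pytest.approx(rel)
    with pytest.raises(ScoringError, match="position 5"):
        relative_score_vs_baseline(avg, ann, 5, "GU")


def test_relative_score_matched_elsewhere_mode():
    ann = _toy_annotations()
    avg = pd.DataFrame({"score_cl0": [0.0, 1.0, -2.0, -4.0, -1.0]}, index=ann.index)
    # v3 (MM also at p5) excluded from the strict class set
    rel = relative_score_vs_baseline(
        avg, ann, 4, "MM", baseline_mode="matched-elsewhere"
    )
    assert rel == pytest.approx(-2.0 - 0.5)


def test_aggregate_by_pattern_groupings():
    ann = _toy_annotations()
    values = pd.DataFrame(
        {"score_cl0": [0.0, 1.0, -2.0, -4.0, -1.0], "freq_cl-1": [0.1, 0.1, 0.5, 0.6, 0.3]},
        index=ann.index,
    )
    by_sub = aggregate_by_pattern(values, ann, "subgroup")
    assert by_sub.loc["matched", "score_cl0_mean"] == pytest.approx(0.5)
    assert by_sub.loc["mismatched", "freq_cl-1_mean"] == pytest.approx(0.55)
    assert int(by_sub["score_cl0_count"].sum()) == len(ann)
    by_pat = aggregate_by_pattern(values, ann, "pattern", window="G4")
    assert by_pat.loc["Mmm", "score_cl0_mean"] == pytest.approx(-2.0)
    by_n = aggregate_by_pattern(values, ann, "mismatch_count")
    assert by_n.loc[2, "score_cl0_mean"] == pytest.approx(-4.0)
    by_flag = aggregate_by_pattern(values, ann, "seedMW")
    assert by_flag.loc[True, "score_cl0_count"] == 3
    with pytest.raises(ScoringError):
        aggregate_by_pattern(values, ann, "no-such-grouping")
    # all variants in one group -> group mean equals the global mean
    ann_one = ann.assign(subgroup="matched")
    one = aggregate_by_pattern(values, ann_one, "subgroup")
    assert one.loc["matched", "score_cl0_mean"] == pytest.approx(values["score_cl0"].mean())
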