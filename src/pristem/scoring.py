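"""Cleavage statistics: log-ratio scores, positional frequencies, aggregates.

All scores are log2 ratios of CPM-normalized counts with a pseudocount
(default 0.1) added to numerator and denominator:

* ``P/S  = log2(N_P + q)  - log2(N_S + q)`` - overall cleavage score, where
  ``N_P`` sums product counts over all cut sites of the variant;
* ``US/S = log2(N_US + q) - log2(N_S + q)`` - reciprocal (uncleaved) score;
* ``CLx  = log2(N_X + q)  - log2(N_S + q)`` - per-site cleavage score, with
  ``N_X`` the product count whose 5' end maps to upper-stem position x+1.

The relative positional cleavage frequency at CLx is the raw product count
at CLx divided by the variant's total product count over all sites.
Replicate scores are averaged arithmetically over the replicates in which
the variant passed the read cutoffs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .readproc import CUT_RANGE, CleavageCountTable

DEFAULT_PSEUDOCOUNT = 0.1


class ScoringError(ValueError):
    pass


def _log2q(values, pseudocount: float):
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ScoringError("negative counts")
    return np.log2(arr + pseudocount)


def score_column(x: int) -> str:
    return f"score_cl{x}"


def freq_column(x: int) -> str:
    return f"freq_cl{x}"


def _pivot(table: CleavageCountTable, value: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(S, US, P-by-site) frames indexed by (variant_id, replicate)."""
    df = table.counts
    idx = ["variant_id", "replicate"]
    sub = df[df["sample"] == "S"].set_index(idx)[value]
    uns = df[df["sample"] == "US"].set_index(idx)[value]
    prod = df[df["sample"] == "P"]
    psites = prod.pivot_table(index=idx, columns="site", values=value, aggfunc="sum")
    psites.columns = [int(c) for c in psites.columns]
    return sub, uns, psites


def cleavage_scores(
    table: CleavageCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cut_range: Sequence[int] = CUT_RANGE,
) -> pd.DataFrame:
    """Per-(variant, replicate) P/S, US/S and CLx scores from CPM counts.

    Variants masked in S contribute no scores for that replicate; a masked
    US or P side leaves the corresponding scores missing (NaN).
    """
    sub, uns, psites = _pivot(table, "cpm")
    index = sub.index
    out = pd.DataFrame(index=index)
    out["n_s"] = sub
    out["n_us"] = uns.reindex(index)
    psites = psites.reindex(index)
    site_cols = [x for x in cut_range]
    for x in site_cols:
        out[f"n_cl{x}"] = psites[x] if x in psites.columns else np.nan
    n_cl = out[[f"n_cl{x}" for x in site_cols]].fillna(0.0)
    has_product = ~psites.isna().all(axis=1)
    out["n_p"] = n_cl.sum(axis=1).where(has_product, np.nan)

    masked_s = [key + ("S",) in table.masked for key in index]
    masked_us = [key + ("US",) in table.masked for key in index]
    masked_p = [key + ("P",) in table.masked for key in index]
    out = out.loc[~pd.Series(masked_s, index=index)]
    masked_us = pd.Series(masked_us, index=index).loc[out.index]
    masked_p = pd.Series(masked_p, index=index).loc[out.index]

    logs = _log2q(out["n_s"], pseudocount)
    out["ps"] = _log2q(out["n_p"].fillna(0.0), pseudocount) - logs
    out.loc[out["n_p"].isna() | masked_p, "ps"] = np.nan
    out["uss"] = _log2q(out["n_us"].fillna(0.0), pseudocount) - logs
    out.loc[out["n_us"].isna() | masked_us, "uss"] = np.nan
    for x in site_cols:
        col = out[f"n_cl{x}"].fillna(0.0)
        out[score_column(x)] = _log2q(col, pseudocount) - logs
        out.loc[masked_p, score_column(x)] = np.nan
    return out


def positional_frequency(
    table: CleavageCountTable, cut_range: Sequence[int] = CUT_RANGE
) -> pd.DataFrame:
    """Relative positional cleavage frequency per (variant, replicate).

    Computed on raw product counts; frequencies over the observed cut range
    sum to 1 for every variant with at least one product read.  Variants
    with no products (or masked in P) are missing, not zero-filled.
    """
    _, _, psites = _pivot(table, "raw")
    psites = psites.reindex(columns=list(cut_range)).fillna(0.0)
    total = psites.sum(axis=1)
    keep = total > 0
    masked = pd.Series(
        [key + ("P",) in table.masked for key in psites.index], index=psites.index
    )
    keep &= ~masked
    freqs = psites.loc[keep].div(total.loc[keep], axis=0)
    freqs.columns = [freq_column(x) for x in cut_range]
    return freqs


def average_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Average per-replicate values per variant (mean over non-missing
    replicates); the replicate count enters as column ``n_rep``."""
    grouped = values.groupby(level="variant_id", sort=True)
    out = grouped.mean()
    out["n_rep"] = grouped.size()
    return out


def relative_score_vs_baseline(
    averaged: pd.DataFrame,
    annotations: pd.DataFrame,
    position: int,
    pair_class: str,
    score_col: str = "score_cl0",
    baseline_mode: str = "wc-at-position",
) -> float:
    """Group-mean score of a pair class at a position, relative to WC.

    Returns ``mean(score | pair_class at position) - mean(score | WC at
    position)`` in log2 units.  ``baseline_mode`` ``wc-at-position`` uses
    every variant with the queried class at the position regardless of the
    other positions (the marginal reading); ``matched-elsewhere`` restricts
    both sets to variants that are Watson-Crick everywhere else.
    """
    col = f"class_p{position}"
    if col not in annotations.columns:
        raise ScoringError(f"no pair-class annotation for position {position}")
    ann = annotations
    if baseline_mode == "matched-elsewhere":
        other = [c for c in ann.columns if c.startswith("class_p") and c != col]
        all_wc_elsewhere = (ann[other] == "WC").all(axis=1)
        ann = ann.loc[all_wc_elsewhere]
    elif baseline_mode != "wc-at-position":
        raise ScoringError(f"unknown baseline mode {baseline_mode!r}")
    scores = averaged[score_col]
    class_ids = ann.index[ann[col] == pair_class]
    wc_ids = ann.index[ann[col] == "WC"]
    class_scores = scores.reindex(class_ids).dropna()
    wc_scores = scores.reindex(wc_ids).dropna()
    if wc_scores.empty:
        raise ScoringError(f"empty Watson-Crick baseline at position {position}")
    if class_scores.empty:
        raise ScoringError(f"no scored {pair_class} variants at position {position}")
    return float(class_scores.mean() - wc_scores.mean())


def aggregate_by_pattern(
    values: pd.DataFrame,
    annotations: pd.DataFrame,
    grouping: str,
    window: str | None = None,
) -> pd.DataFrame:
    """Summarize scores/frequencies by variant class.

    ``grouping`` is one of ``subgroup`` (matched/mismatched/wobble),
    ``pattern`` (window pattern codes; ``window`` selects the group label
    when the design has several), ``mismatch_count`` or a region flag
    (``seedMW``, ``midMW_7_9``, ``midMW_10_12``).  Returns per-group mean,
    dispersion (std) and n for every value column.
    """
    ann = annotations
    if grouping == "subgroup":
        key = ann["subgroup"]
    elif grouping == "pattern":
        pattern_cols = [c for c in ann.columns if c.startswith("pattern_")]
        if window is not None:
            col = f"pattern_{window}"
            if col not in ann.columns:
                raise ScoringError(f"no pattern annotation for window {window!r}")
        elif len(pattern_cols) == 1:
            col = pattern_cols[0]
        else:
            raise ScoringError("several windows annotated; pass window=...")
        key = ann[col]
    elif grouping == "mismatch_count":
        class_cols = [c for c in ann.columns if c.startswith("class_p")]
        key = (ann[class_cols] == "MM").sum(axis=1)
    elif grouping in ("seedMW", "midMW_7_9", "midMW_10_12"):
        key = ann[grouping]
    else:
        raise ScoringError(f"unknown grouping key {grouping!r}")
    joined = values.join(key.rename("_group"), how="inner").dropna(subset=["_group"])
    agg = joined.groupby("_group").agg(["mean", "std", "count"])
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    agg.index.name = grouping
    return agg


def group_summary_json(aggregate: pd.DataFrame) -> dict:
    """JSON-serializable export of :func:`aggregate_by_pattern` output."""
    return {
        str(group): {col: (None if pd.isna(v) else float(v)) for col, v in row.items()}
        for group, row in aggregate.iterrows()
    }
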