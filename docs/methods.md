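# Methods

## Coordinate system

A hairpin design is three strings — `seq5p` (5′→3′, including the
single-stranded basal segment), an apical `loop`, and `seq3p` (5′→3′, the
descending strand) — plus a one-to-one pairing register between strand
indices.  All internal indices are 0-based; cut sites are
between-nucleotide boundaries.  The basal junction is the boundary on
`seq5p` where the lower stem begins, and the canonical cleavage site CL0
is fixed 13 nt above it (`cl0_cut = basal_junction + 13`).  Upper-stem
positions are reported 1-based: position 1 is the first nucleotide 3′ of
the CL0 cut on the 5p strand, matching how screen figures count from the
cleavage site.  A CLx cut (x ∈ [−6, +1]) is the boundary `cl0_cut + x`,
so a product read created by a CLx cut starts at upper-stem position
x + 1.

## Library enumeration

Each randomized window covers three consecutive upper-stem positions and
substitutes all 4⁶ ordered combinations of the three 5p nucleotides and
their three register partners.  Windows are enumerated independently and
full sequences deduplicated; a variant records every window group able to
generate it.  For L tiled positions the unique count has the closed form

    1 + 15·L + 225·(2L − 3) + 3375·(L − 2)

obtained by classifying variants by their set of mutated pair positions
(backbone; one mutated pair, 15 non-backbone ordered pairs; two within
distance ≤ 2; three consecutive).  For the 11-window tiling of positions
1–13 this gives 42,496 unique variants out of 11 × 4096 = 45,056 generated;
tests verify the closed form against independent brute-force set union for
L = 3…6.

## Pair classification

An ordered pair (5p nucleotide, 3p partner) is WC (4 of the 16 ordered
pairs), G–U (G on the 5p strand), U–G, or MM (the remaining 10).  Window
pattern codes classify by mismatch count and adjacency, not literal
order: `Mmm` = exactly one MM anywhere in the window, `MMm` = two
adjacent, `MmM` = two separated by a match, `MMM` = three; `W…` codes are
the wobble analogues.  Windows containing both an MM and a wobble are
coded `mixed` and excluded from single-class aggregates but kept in the
library.  The variant-level subgroup is a partition with precedence
mismatched > wobble > matched.  Region flags mark any non-WC pair at
positions 4–8 (seedMW), 7–9 and 10–12 (midMW).

## Read processing

Reads identical over the 5′ 6-nt UMI plus insert are PCR duplicates; one
survivor is kept, the UMI stripped, and optional adapters removed by exact
prefix/suffix match (quality filtering and pair merging are upstream
contracts).  Assignment is exact hash lookup against the designed
references — the designed pool makes exact lookup complete, so this is
equivalent to keeping only perfectly mapped reads.  Substrate (S, US)
reads must match a library sequence full-length; product (P) reads must
equal a CLx suffix.  Read length determines the implied cut, so cuts
outside [−6, +1] are tallied `out_of_range` rather than silently dropped.
A CL+1 product of a variant whose only randomized window covers position 1
loses one randomized nucleotide and can be shared by several variants;
such reads are tallied `ambiguous` and never assigned.  For every other
(variant, site) combination the round trip cut→call is exact, which the
suite checks property-style.

Raw counts below the per-sample cutoffs (30 for S and US, 15 for P; the US
cutoff is a package choice since US reads are full-length substrates) mask
that variant in that sample.  CPM is computed per sample over all assigned
reads *before* masking, keeping normalization a property of the sample
rather than of the surviving variant set.

## Scores

All scores are log2 ratios of CPM counts with pseudocount 0.1 added to
both terms (`P/S`, `US/S`, per-site `CLx`); positional cleavage
frequencies are raw product counts at CLx over the variant's total product
count, reported as missing (not zero) for variants without products.
Replicates are averaged arithmetically over the replicates where the
variant passed cutoffs, with the count recorded.  The relative score of a
pair class at a position is the difference of group means (class − WC at
the same position), which in the simulator's parameterization estimates
log2 of the rate multiplier directly.  The default baseline is marginal
(WC at the queried position regardless of other positions); a stricter
`matched-elsewhere` mode is available, and both coincide when only the
queried effect is present.

## Structure

The folding backend is pluggable and always recorded in outputs:
ViennaRNA MFE (default settings) when the `RNA` bindings import, otherwise
a built-in Nussinov base-pair maximization (minimum hairpin loop 3,
wobble pairs allowed, deterministic lowest-index traceback) which is a
topological approximation of thermodynamic folding, validated against
exhaustive enumeration for short sequences.  Structure filtering keeps a
variant iff its dot-bracket equals the backbone's everywhere outside the
variant's randomized windows, their register partners, and a ±2 nt margin
— exact string equality, the simplest reading of "similar structure
allowing for differences around the randomized region".

For the cross-species profile, an "unmatched" nucleotide is one unpaired
in the predicted structure (this covers mismatches rendered as internal
loops and bulges), counted on the 5p strand 1-based from the annotated
mature-5p start.  Positions are profiled up to 22 (the upper-stem extent);
an entry contributes to a position's denominator only if it is that long,
and to the 10–12 region counts only if position 12 exists.  Entries whose
mature-5p start lies outside the folded sequence are skipped and tallied.

## Simulator

Per replicate, variant abundances get lognormal noise (σ = 0.25), a pool
of `pool_factor × depth` molecules is drawn, and each molecule is cleaved
with probability `c · Σ_x p0(x)·m_x(v)` (site then drawn ∝ p0·m), so
molecule counts obey pool = cleaved + uncleaved exactly.  Effects are
multiplicative on per-site rates before renormalization of the site
choice; this maps a 2^k multiplier to an expected relative score of k and
keeps frequencies well-defined.  S, US and P samples are independently
subsampled to `depth` unique molecules, tagged with uniform random 6-nt
UMIs (collisions between molecules of the same variant are possible and
slightly deflate unique counts, as in real data), and expanded with
geometric PCR copy counts (duplicate rate 0.15).  FASTQ output is 4-line
with constant Phred-33 quality; a fixed seed yields byte-identical files,
and the truth table (expected scores at infinite depth) is
seed-independent.

Baseline site propensities put 0.90 at CL0, 0.04 at CL-1 and 0.01 at each
remaining site, and the default per-molecule cleavage probability is 0.4 —
a canonical-site-dominated endpoint assay.  The default effect multipliers
(seed-region MM 0.25, G–U 0.15, U–G 0.50 on CL0; mid-region 7–9 ×4 on
CL-1; mid-region 10–12 ×0.25 on an unproductive site when the design has
one) encode the study system's qualitative findings — the source data
quantify them only by gel densitometry — and are declared simulator
parameters, not measured values.  What the generator does **not** emulate:
sequence-dependent ligation/RT bias, quality degradation, indels and
sequencing errors (reads either match a reference exactly or are
unassignable), chimeric reads, and carry-over between groups; passing
recovery tests therefore demonstrates correctness of the analysis given
exact-match-clean reads, not robustness to platform artifacts.

## Problem sizes and numerical choices

Recovery analyses use single-window libraries (4096 variants) at 10⁶
unique molecules per sample and 3 replicates — about 244 substrate reads
per variant, comfortably above the cutoffs and comparable to the original
screen's per-variant coverage; the library-combinatorics checks use the
full 42,496-variant tiling.  The null-model check uses a Bonferroni-
corrected 99% confidence interval across its nine position×class
comparisons, with standard errors taken from per-variant dispersion.
Score computations are plain float64; ties in the Nussinov traceback are
broken toward the lowest pairing index; degenerate inputs (empty samples,
zero-product variants, zero normalizers) are reported as warnings,
missing values, or errors respectively rather than silently coerced.

## Known limitations

* Exact-match assignment cannot use reads with sequencing errors; real
  libraries lose a platform-dependent fraction of reads that BWA-style
  alignment would rescue.
* The built-in folder maximizes pair count, not free energy; structure
  filtering and unmatched-nucleotide profiles computed with it differ from
  MFE-based results, which is why the backend is recorded alongside any
  profile.
* Bulged (unequal-length) randomized windows and windows wider than the
  register are out of scope.
* Statistical testing of group differences (t-tests/Wilcoxon) is not
  provided beyond exporting group summaries.
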