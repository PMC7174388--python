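"""Ground-truth read simulator for the processing assay.

The generator emulates the endpoint in-vitro assay: a substrate pool of
library variants with noisy abundances is incubated with the enzyme; each
molecule is cleaved at most once (Bernoulli) and, if cleaved, the cut site
is drawn over CL-6..CL+1.  The per-molecule, per-site cleavage rate is a
baseline propensity multiplied by effects keyed on (upper-stem position
window, pair class, site), so a multiplier of 2**k on a site translates
into an expected relative cleavage score of exactly k log2 units -- the
recovery target for the pipeline.

Sequenced samples are S (pre-reaction pool), US (uncleaved survivors) and P
(product suffixes), each subsampled to a configured depth, tagged with 6-nt
UMIs, and expanded with geometric PCR duplicate counts.  The paper reports
no quantitative effect sizes (gel densitometry only), so the default
multipliers are declared simulator parameters, chosen to reproduce the
qualitative findings: mismatches and wobbles at positions 4-8 suppress CL0
(G-U stronger than U-G), mismatches/wobbles at 7-9 boost CL-1, and those at
10-12 suppress the unproductive site on two-junction designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .readproc import CUT_RANGE
from .scoring import DEFAULT_PSEUDOCOUNT, freq_column, score_column
from .variant_library import VariantLibrary, classify_variant


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectRule:
    """Multiplicative effect of a pair class at given upper-stem positions
    on the cleavage rate at one site."""

    positions: tuple[int, ...]
    pair_classes: tuple[str, ...]
    site: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise SimulationError("effect multiplier must be non-negative")


def _default_baseline() -> dict[int, float]:
    # canonical site dominates; alternative sites share the remainder
    base = {x: 0.01 for x in CUT_RANGE}
    base[0] = 0.90
    base[-1] = 0.04
    total = sum(base.values())
    return {x: v / total for x, v in base.items()}


@dataclass(frozen=True)
class EffectModel:
    """Simulator ground truth: baseline propensities + pair-class effects."""

    baseline: Mapping[int, float] = field(default_factory=_default_baseline)
    cleavage_prob: float = 0.4
    rules: tuple[EffectRule, ...] = ()
    abundance_sigma: float = 0.25
    depth: int = 1_000_000
    pcr_dup_rate: float = 0.15
    umi_length: int = 6
    pool_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cleavage_prob <= 1.0:
            raise SimulationError("cleavage_prob must be in [0, 1]")
        if any(v < 0 for v in self.baseline.values()):
            raise SimulationError("baseline propensities must be non-negative")
        if not 0.0 <= self.pcr_dup_rate < 1.0:
            raise SimulationError("pcr_dup_rate must be in [0, 1)")

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.baseline))

    def baseline_vector(self) -> np.ndarray:
        v = np.array([self.baseline[x] for x in self.sites], dtype=float)
        return v / v.sum()

    def site_multipliers(self, pair_classes: Mapping[int, str | None]) -> np.ndarray:
        """Combined multiplier per site for one variant's pair classes."""
        m = np.ones(len(self.sites), dtype=float)
        site_index = {x: i for i, x in enumerate(self.sites)}
        for rule in self.rules:
            if rule.site not in site_index:
                continue
            hits = sum(
                1
                for pos in rule.positions
                if pair_classes.get(pos) in rule.pair_classes
            )
            if hits:
                m[site_index[rule.site]] *= rule.multiplier ** hits
        return m

    def variant_rates(self, pair_classes: Mapping[int, str | None]) -> tuple[float, np.ndarray]:
        """(per-molecule cleavage probability, site distribution)."""
        rates = self.baseline_vector() * self.site_multipliers(pair_classes)
        total = rates.sum()
        c = min(1.0, self.cleavage_prob * total)
        probs = rates / total if total > 0 else np.zeros_like(rates)
        return c, probs


def default_effect_model(unproductive_site: int | None = None, **overrides) -> EffectModel:
    """Effect model encoding the study's qualitative findings.

    Multipliers are arbitrary simulator defaults: seed-region (4-8) effects
    suppress CL0 with ordering GU < UG < WC, mid-region 7-9 effects boost
    CL-1 four-fold, and -- when the design has an unproductive (apical
    junction) site -- mid-region 10-12 effects suppress it.
    """
    seed_positions = (4, 5, 6, 7, 8)
    rules = [
        EffectRule(seed_positions, ("MM",), 0, 0.25),
        EffectRule(seed_positions, ("GU",), 0, 0.15),
        EffectRule(seed_positions, ("UG",), 0, 0.50),
        EffectRule((7, 8, 9), ("MM", "GU", "UG"), -1, 4.0),
    ]
    if unproductive_site is not None:
        rules.append(EffectRule((10, 11, 12), ("MM", "GU", "UG"), unproductive_site, 0.25))
    return EffectModel(rules=tuple(rules), **overrides)


# ---------------------------------------------------------------------------
# per-variant ground truth


def variant_pair_classes(library: VariantLibrary) -> dict[str, dict[int, str | None]]:
    design = library.design
    return {
        vid: classify_variant(seq, design, groups=library.groups[vid]).pair_classes
        for vid, seq in library.sequences()
    }


def expected_scores(
    model: EffectModel,
    library: VariantLibrary,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pair_classes: Mapping[str, Mapping[int, str | None]] | None = None,
) -> pd.DataFrame:
    """Infinite-depth ScoreTable implied by the model (the recovery target).

    Expected CPM counts (equal variant abundances, depth -> infinity) are
    plugged into the same score formulas the pipeline applies to data.
    """
    if pair_classes is None:
        pair_classes = variant_pair_classes(library)
    vids = list(library.id_to_seq)
    n = len(vids)
    sites = model.sites
    cvec = np.empty(n)
    site_probs = np.empty((n, len(sites)))
    for i, vid in enumerate(vids):
        c, probs = model.variant_rates(pair_classes[vid])
        cvec[i] = c
        site_probs[i] = probs
    s_cpm = np.full(n, 1e6 / n)
    us_weight = 1.0 - cvec
    us_cpm = 1e6 * us_weight / us_weight.sum() if us_weight.sum() > 0 else np.zeros(n)
    p_weight = cvec[:, None] * site_probs
    total_p = p_weight.sum()
    p_cpm = 1e6 * p_weight / total_p if total_p > 0 else np.zeros_like(p_weight)

    q = pseudocount
    out = pd.DataFrame(index=pd.Index(vids, name="variant_id"))
    out["cleavage_prob"] = cvec
    out["n_s"] = s_cpm
    out["n_us"] = us_cpm
    out["n_p"] = p_cpm.sum(axis=1)
    out["ps"] = np.log2(out["n_p"] + q) - np.log2(out["n_s"] + q)
    out["uss"] = np.log2(out["n_us"] + q) - np.log2(out["n_s"] + q)
    for j, x in enumerate(sites):
        out[f"n_cl{x}"] = p_cpm[:, j]
        out[score_column(x)] = np.log2(p_cpm[:, j] + q) - np.log2(out["n_s"] + q)
        out[freq_column(x)] = site_probs[:, j]
    return out


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimulationResult:
    fastq: dict[tuple[str, int], Path]
    truth: pd.DataFrame
    truth_path: Path
    molecule_counts: dict[int, pd.DataFrame]

    def samples(self) -> Iterable[tuple[str, int, Path]]:
        for (sample, rep), path in self.fastq.items():
            yield sample, rep, path


def _umi_table(umi_length: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGU", repeat=umi_length)]


def _write_sample(
    path: Path,
    forms: Sequence[str],
    counts: np.ndarray,
    rng: np.random.Generator,
    umis: list[str],
    dup_rate: float,
    tag: str,
) -> None:
    """Write one FASTQ sample: ``counts[i]`` unique molecules of ``forms[i]``,
    each UMI-tagged and PCR-duplicated with geometric copy counts."""
    n_umi = len(umis)
    rid = 0
    with open(path, "w") as fh:
        chunk: list[str] = []
        for form, n in zip(forms, counts):
            if n == 0:
                continue
            umi_idx = rng.integers(0, n_umi, size=n)
            if dup_rate > 0:
                copies = rng.geometric(1.0 - dup_rate, size=n)
            else:
                copies = np.ones(n, dtype=int)
            qual = "I" * (len(form) + len(umis[0]))
            for u, k in zip(umi_idx, copies):
                rec = f"@{tag}:{rid}\n{umis[u]}{form}\n+\n{qual}\n"
                chunk.append(rec * int(k))
                rid += 1
            if len(chunk) > 20000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))


def simulate_experiment(
    library: VariantLibrary,
    model: EffectModel,
    outdir,
    replicates: int = 3,
    seed: int | None = None,
    pair_classes: Mapping[str, Mapping[int, str | None]] | None = None,
) -> SimulationResult:
    """Simulate FASTQ files per (sample class, replicate) plus truth tables.

    Per replicate: a substrate pool is drawn with lognormal abundance noise;
    each pool molecule is cleaved with its variant's Bernoulli probability
    and the cut site drawn from the renormalized propensities; S, US and P
    samples are then subsampled to ``model.depth`` unique molecules each and
    written as 4-line FASTQ with constant Phred-33 qualities.  The truth
    table (expected scores and site distributions) does not depend on the
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = model.seed
    if pair_classes is None:
        pair_classes = variant_pair_classes(library)
    design = library.design
    vids = list(library.id_to_seq)
    seqs = [library.id_to_seq[v] for v in vids]
    n = len(vids)
    sites = model.sites
    cvec = np.empty(n)
    site_probs = np.empty((n, len(sites)))
    for i, vid in enumerate(vids):
        c, probs = model.variant_rates(pair_classes[vid])
        cvec[i] = c
        site_probs[i] = probs
    suffixes = {x: [s[design.cut_index(x):] for s in seqs] for x in sites}
    umis = _umi_table(model.umi_length)

    truth = expected_scores(model, library, pair_classes=pair_classes)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t")

    fastq: dict[tuple[str, int], Path] = {}
    molecule_counts: dict[int, pd.DataFrame] = {}
    depth = int(model.depth)
    pool_size = depth * model.pool_factor
    for rep in range(1, replicates + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        abundance = rng.lognormal(0.0, model.abundance_sigma, size=n)
        pool = rng.multinomial(pool_size, abundance / abundance.sum())
        cleaved = rng.binomial(pool, cvec)
        uncleaved = pool - cleaved
        site_counts = np.zeros((n, len(sites)), dtype=np.int64)
        for i in range(n):
            if cleaved[i] > 0:
                site_counts[i] = rng.multinomial(cleaved[i], site_probs[i])
        molecule_counts[rep] = pd.DataFrame(
            {"variant_id": vids, "pool": pool, "cleaved": cleaved, "uncleaved": uncleaved}
        ).set_index("variant_id")

        def draw(weights: np.ndarray) -> np.ndarray:
            total = weights.sum()
            if total == 0 or depth == 0:
                return np.zeros(weights.shape, dtype=np.int64)
            flat = rng.multinomial(depth, (weights / total).ravel())
            return flat.reshape(weights.shape)

        s_counts = draw(pool.astype(float))
        us_counts = draw(uncleaved.astype(float))
        p_counts = draw(site_counts.astype(float))

        for sample, counts, forms in (
            ("S", s_counts, seqs),
            ("US", us_counts, seqs),
        ):
            path = outdir / f"{sample}_rep{rep}.fastq"
            _write_sample(
                path, forms, counts, rng, umis, model.pcr_dup_rate, f"{sample}.{rep}"
            )
            fastq[(sample, rep)] = path
        path = outdir / f"P_rep{rep}.fastq"
        p_forms: list[str] = []
        p_flat: list[int] = []
        for j, x in enumerate(sites):
            p_forms.extend(suffixes[x])
            p_flat.extend(p_counts[:, j])
        _write_sample(
            path, p_forms, np.asarray(p_flat), rng, umis, model.pcr_dup_rate, f"P.{rep}"
        )
        fastq[("P", rep)] = path

    return SimulationResult(
        fastq=fastq, truth=truth, truth_path=truth_path, molecule_counts=molecule_counts
    )


def load_effect_model(path) -> EffectModel:
    """Read an effect model from the documented plain-text (YAML) schema."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = tuple(
        EffectRule(
            tuple(int(p) for p in r["positions"]),
            tuple(r["pair_classes"]),
            int(r["site"]),
            float(r["multiplier"]),
        )
        for r in raw.get("rules", [])
    )
    kwargs = {}
    if "baseline" in raw:
        kwargs["baseline"] = {int(k): float(v) for k, v in raw["baseline"].items()}
    for key in (
        "cleavage_prob", "abundance_sigma", "depth", "pcr_dup_rate",
        "umi_length", "pool_factor", "seed",
    ):
        if key in raw:
            kwargs[key] = type(EffectModel.__dataclass_fields__[key].default)(raw[key])
    return EffectModel(rules=rules, **kwargs)
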