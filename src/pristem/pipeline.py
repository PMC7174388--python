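"""Orchestration: design -> library -> (simulate | count) -> score.

A :class:`RunConfig` fully determines a run; the resolved config (plus tool
version and config hash) is written next to the outputs, and identical
config + inputs produce identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .readproc import (
    DEFAULT_CUTOFFS,
    DEFAULT_UMI_LENGTH,
    ReferenceIndex,
    build_count_table,
    count_sample,
)
from .scoring import (
    DEFAULT_PSEUDOCOUNT,
    average_replicates,
    cleavage_scores,
    positional_frequency,
)
from .synthetic_data import load_effect_model, simulate_experiment
from .variant_library import HairpinDesign, enumerate_variants

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    design: str
    outdir: str
    model: str | None = None  # simulate when set
    reads_dir: str | None = None  # count pre-existing reads when set
    replicates: int = 3
    cutoff_s: int = DEFAULT_CUTOFFS["S"]
    cutoff_us: int = DEFAULT_CUTOFFS["US"]
    cutoff_p: int = DEFAULT_CUTOFFS["P"]
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    umi_length: int = DEFAULT_UMI_LENGTH
    adapter5: str = ""
    adapter3: str = ""
    fold_backend: str = "auto"
    baseline_mode: str = "wc-at-position"
    seed: int = 0
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True).encode()
        return {
            **d,
            "tool_version": __version__,
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    @property
    def cutoffs(self) -> dict[str, int]:
        return {"S": self.cutoff_s, "US": self.cutoff_us, "P": self.cutoff_p}


def _find_reads(reads_dir: Path) -> dict[tuple[str, int], Path]:
    pattern = re.compile(r"^(S|US|P)_rep(\d+)\.(fastq|fq|fasta|fa)(\.gz)?$")
    found = {}
    for path in sorted(reads_dir.iterdir()):
        m = pattern.match(path.name)
        if m:
            found[(m.group(1), int(m.group(2)))] = path
    if not found:
        raise PipelineError(f"no read files matching S|US|P_rep<N>.* in {reads_dir}")
    return found


def run_pipeline(config: RunConfig) -> dict:
    """Execute the stages in dependency order; returns an output manifest.

    Stages whose outputs already exist are skipped unless ``overwrite`` is
    set.  A stage failure aborts downstream stages (the exception
    propagates).  Structured per-stage tallies go to the run log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pristem")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"outdir": str(outdir), "log": str(log_path)}
    try:
        design_path = Path(config.design)
        if not design_path.exists():
            raise PipelineError(f"design file not found: {design_path}")
        design = HairpinDesign.from_yaml(design_path)
        library = enumerate_variants(design)
        logger.info("library: %d unique variants from %d windows", len(library), len(design.windows))

        fasta = outdir / "library.fasta"
        annot_path = outdir / "library_annotations.tsv"
        if config.overwrite or not fasta.exists():
            library.to_fasta(fasta)
        if config.overwrite or not annot_path.exists():
            library.annotate().to_csv(annot_path, sep="\t")
        else:
            logger.info("library outputs exist; skipped")
        manifest["library_fasta"] = str(fasta)
        manifest["annotations"] = str(annot_path)

        if config.model is not None:
            model_path = Path(config.model)
            if not model_path.exists():
                raise PipelineError(f"model file not found: {model_path}")
            model = load_effect_model(model_path)
            reads_dir = outdir / "reads"
            sim = simulate_experiment(
                library, model, reads_dir, replicates=config.replicates, seed=config.seed
            )
            reads = dict(sim.fastq)
            manifest["truth"] = str(sim.truth_path)
        elif config.reads_dir is not None:
            reads = _find_reads(Path(config.reads_dir))
        else:
            raise PipelineError("config needs either a simulation model or a reads_dir")

        index = ReferenceIndex(library)
        assignments = {}
        for (sample, rep), path in sorted(reads.items()):
            counts, pstats, tallies = count_sample(
                path,
                index,
                sample,
                umi_length=config.umi_length,
                adapter5=config.adapter5,
                adapter3=config.adapter3,
            )
            logger.info(
                "%s rep%d: %d reads, %d duplicates removed, %d assigned, "
                "%d unassigned, %d out-of-range, %d ambiguous",
                sample, rep, pstats.total, pstats.duplicates_removed,
                tallies.assigned, tallies.unassigned, tallies.out_of_range,
                tallies.ambiguous,
            )
            assignments[(sample, rep)] = counts
        table = build_count_table(assignments, cutoffs=config.cutoffs)
        counts_path = outdir / "counts.tsv"
        table.to_tsv(counts_path)
        manifest["counts"] = str(counts_path)
        logger.info("count table: %d rows, %d masked entries", len(table.counts), len(table.masked))

        scores = cleavage_scores(table, pseudocount=config.pseudocount)
        freqs = positional_frequency(table)
        joined = scores.join(freqs, how="left")
        averaged = average_replicates(joined)
        scores_path = outdir / "scores.tsv"
        avg_path = outdir / "scores_averaged.tsv"
        joined.to_csv(scores_path, sep="\t")
        averaged.to_csv(avg_path, sep="\t")
        manifest["scores"] = str(scores_path)
        manifest["scores_averaged"] = str(avg_path)

        with open(outdir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)
        manifest["config"] = str(outdir / "run_config.yaml")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def simulate_and_score(
    library,
    model,
    replicates: int = 3,
    seed: int = 0,
    cutoffs: dict[str, int] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    workdir=None,
):
    """Simulate an experiment and run it through the full read pipeline.

    Convenience wrapper used for recovery analyses: simulates FASTQ files
    (in ``workdir`` or a temporary directory), collapses UMIs, assigns
    reads, builds the count table and returns ``(averaged scores+freqs,
    truth table, per-sample tallies)``.
    """
    import tempfile

    from .scoring import positional_frequency

    def _run(outdir):
        sim = simulate_experiment(library, model, outdir, replicates=replicates, seed=seed)
        index = ReferenceIndex(library)
        assignments = {}
        tallies = {}
        for sample, rep, path in sim.samples():
            counts, _pstats, t = count_sample(path, index, sample)
            assignments[(sample, rep)] = counts
            tallies[(sample, rep)] = t
        table = build_count_table(assignments, cutoffs=cutoffs or DEFAULT_CUTOFFS)
        scores = cleavage_scores(table, pseudocount=pseudocount).join(
            positional_frequency(table), how="left"
        )
        return average_replicates(scores), sim.truth, tallies

    if workdir is not None:
        return _run(workdir)
    with tempfile.TemporaryDirectory() as td:
        return _run(td)
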