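"""End-to-end pipeline: one declarative config, a run directory, a report.

Stages: simulate (optional) -> read/merge/filter tags -> island calling per
sample and mark -> genome binning, replicate correlation and Ward
clustering -> element annotation, size densities and TSS meta-profiles ->
promoter quantification, enrichment sets, log2 fold-change ranking,
bivalency states and co-occupancy dynamics. Deterministic under a fixed
seed; a machine-readable JSON report records parameters, output files and
the headline counts of every stage.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .io import (
    DEFAULT_FRAGMENT_SHIFT,
    GenomeLayout,
    TagCollection,
    filter_redundant_tags,
    merge_replicates,
    read_chrom_sizes,
    read_expression_table,
    read_gene_models,
    read_tags,
    write_expression_table,
)
from .islands import (
    IslandCallingParams,
    find_islands,
    genome_fraction_covered,
    read_islands,
    write_islands,
)
from .bincluster import (
    bin_genome,
    normalize,
    sample_correlation,
    ward_cluster,
    write_bin_matrix,
    write_correlation,
    write_newick,
)
from .annotate import (
    build_annotation,
    element_distribution,
    select_expression_extremes,
    size_density,
    tss_metaprofile,
    write_distribution,
    write_profile,
)
from .promoters import (
    bivalency_states,
    cooccupancy_dynamics,
    count_promoter_reads,
    enriched_promoter_sets,
    promoter_log2fc,
    promoter_windows,
    state_counts,
    venn_partition,
    write_states,
    write_transitions,
    write_venn,
)
from .sim import MARKS, REFERENCE_SAMPLE, SAMPLES, GroundTruth, SimulationConfig, simulate

logger = logging.getLogger("chromshift")


class ConfigError(ValueError):
    """A run configuration violates the schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

_ISLAND_DEFAULTS = {
    "H3K4me3": {"window_size": 200, "gap_size": 200, "eligibility_p0": 0.2,
                "fdr_threshold": 0.01, "effective_genome_fraction": 0.8},
    "H3K27me3": {"window_size": 200, "gap_size": 600, "eligibility_p0": 0.2,
                 "fdr_threshold": 0.01, "effective_genome_fraction": 0.8},
}

_TOP_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "chromshift_out",
    "bin_size": 500,
    "fragment_shift": DEFAULT_FRAGMENT_SHIFT,
    "max_per_position": 1,
    "pseudocount": 1.0,
    "n_extremes": 2000,
    "profile_flank": 3000,
    "profile_step": 50,
    "promoter": {"upstream": 1000, "downstream": 500},
    "resume": False,
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    seed: int
    outdir: str
    bin_size: int
    fragment_shift: int
    max_per_position: int
    pseudocount: float
    n_extremes: int
    profile_flank: int
    profile_step: int
    promoter: dict[str, int]
    resume: bool
    islands: dict[str, IslandCallingParams]
    simulate: SimulationConfig | None = None
    inputs: dict[str, Any] | None = None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            k: getattr(self, k)
            for k in ("seed", "outdir", "bin_size", "fragment_shift", "max_per_position",
                      "pseudocount", "n_extremes", "profile_flank", "profile_step",
                      "promoter", "resume")
        }
        d["islands"] = {
            m: {f: getattr(p, f) for f in _ISLAND_DEFAULTS[m]}
            for m, p in self.islands.items()
        }
        if self.simulate is not None:
            sim = {}
            for f in SimulationConfig.__dataclass_fields__:
                v = getattr(self.simulate, f)
                sim[f] = list(v) if isinstance(v, tuple) else v
            d["simulate"] = sim
        if self.inputs is not None:
            d["inputs"] = self.inputs
        return d


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a config file or dict, filling and logging defaults.

    Errors name the offending key. Exactly one of ``simulate`` / ``inputs``
    must be present; referenced input files must exist.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")

    allowed = set(_TOP_DEFAULTS) | {"islands", "simulate", "inputs"}
    _check_keys(raw, allowed, "config")

    merged = {**_TOP_DEFAULTS, **{k: v for k, v in raw.items() if k in _TOP_DEFAULTS}}
    for k in _TOP_DEFAULTS:
        if k not in raw:
            logger.debug("config: default applied %s=%r", k, merged[k])
    for key in ("seed", "bin_size", "fragment_shift", "max_per_position",
                "n_extremes", "profile_flank", "profile_step"):
        if not isinstance(merged[key], (int, np.integer)) or isinstance(merged[key], bool):
            raise ConfigError(f"config key {key!r} must be an integer")
    for key in ("bin_size", "max_per_position", "n_extremes", "profile_flank", "profile_step"):
        if merged[key] <= 0:
            raise ConfigError(f"config key {key!r} must be positive")
    if not isinstance(merged["promoter"], Mapping):
        raise ConfigError("config key 'promoter' must be a mapping")
    _check_keys(merged["promoter"], {"upstream", "downstream"}, "promoter")
    merged["promoter"] = {**_TOP_DEFAULTS["promoter"], **merged["promoter"]}

    island_raw = raw.get("islands", {})
    _check_keys(island_raw, set(_ISLAND_DEFAULTS), "islands")
    islands = {}
    for mark, defaults in _ISLAND_DEFAULTS.items():
        block = dict(island_raw.get(mark, {}))
        _check_keys(block, set(defaults), f"islands.{mark}")
        try:
            islands[mark] = IslandCallingParams(**{**defaults, **block})
        except ValueError as exc:
            raise ConfigError(f"islands.{mark}: {exc}") from exc

    sim_cfg = None
    inputs = None
    if "simulate" in raw and "inputs" in raw:
        raise ConfigError("give either 'simulate' or 'inputs', not both")
    if "simulate" in raw:
        block = dict(raw["simulate"] or {})
        _check_keys(block, set(SimulationConfig.__dataclass_fields__), "simulate")
        for key in ("k27_domain_width_range", "gene_length_range"):
            if key in block and isinstance(block[key], list):
                block[key] = tuple(block[key])
        block.setdefault("seed", merged["seed"])
        try:
            sim_cfg = SimulationConfig(**block)
        except ValueError as exc:
            raise ConfigError(f"simulate: {exc}") from exc
    elif "inputs" in raw:
        inputs = dict(raw["inputs"])
        _check_keys(inputs, {"chrom_sizes", "genes", "expression", "manifest"}, "inputs")
        for key in ("chrom_sizes", "genes", "expression"):
            if key not in inputs:
                raise ConfigError(f"inputs.{key} is required")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"inputs.{key}: file not found: {inputs[key]}")
        manifest = inputs.get("manifest")
        if not manifest:
            raise ConfigError("inputs.manifest must list tag files")
        seen = set()
        for i, entry in enumerate(manifest):
            _check_keys(entry, {"sample", "mark", "replicate", "path"}, f"inputs.manifest[{i}]")
            for key in ("sample", "mark", "path"):
                if key not in entry:
                    raise ConfigError(f"inputs.manifest[{i}].{key} is required")
            label = (entry["sample"], entry["mark"], entry.get("replicate", 1))
            if label in seen:
                raise ConfigError(f"inputs.manifest[{i}]: duplicate label {label}")
            seen.add(label)
            if not Path(entry["path"]).exists():
                raise ConfigError(f"inputs.manifest[{i}].path: file not found: {entry['path']}")
    else:
        raise ConfigError("config needs a 'simulate' or an 'inputs' block")

    return RunConfig(
        seed=int(merged["seed"]),
        outdir=str(merged["outdir"]),
        bin_size=int(merged["bin_size"]),
        fragment_shift=int(merged["fragment_shift"]),
        max_per_position=int(merged["max_per_position"]),
        pseudocount=float(merged["pseudocount"]),
        n_extremes=int(merged["n_extremes"]),
        profile_flank=int(merged["profile_flank"]),
        profile_step=int(merged["profile_step"]),
        promoter=dict(merged["promoter"]),
        resume=bool(merged["resume"]),
        islands=islands,
        simulate=sim_cfg,
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Per-stage record of parameters, outputs and headline counts."""

    version: str
    config: dict[str, Any]
    stages: list[dict[str, Any]] = field(default_factory=list)
    files: list[str] = field(default_factory=list)

    def add_stage(self, name: str, t0: float, **counts: Any) -> None:
        self.stages.append({"stage": name, "elapsed_s": round(time.time() - t0, 3), **counts})

    def add_file(self, path: Path) -> None:
        self.files.append(str(path))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"version": self.version, "config": self.config,
                 "stages": self.stages, "files": self.files},
                indent=1, default=str,
            )
        )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage; idempotent given the same config and seed."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=config.to_dict())
    shift = config.fragment_shift

    # -- stage: acquire tags (simulate or load) -----------------------------
    t0 = time.time()
    try:
        if config.simulate is not None:
            sim_dir = out / "sim"
            marker = sim_dir / "ground_truth.json"
            if config.resume and marker.exists():
                layout = read_chrom_sizes(sim_dir / "genome.chrom.sizes")
                genes = read_gene_models(sim_dir / "genes.bed12", layout)
                expression_by_sample = {
                    REFERENCE_SAMPLE: read_expression_table(sim_dir / "expression.tsv")
                }
                truth = GroundTruth.from_json(marker)
                replicate_tags = {}
                for p in sorted(sim_dir.glob("*.rep*.bed")):
                    sample, mark, rep = p.name.split(".")[:3]
                    replicate_tags[(sample, mark, int(rep[3:]) - 1)] = read_tags(
                        p, layout, sample=sample, mark=mark
                    )
                logger.info("simulate: resumed from %s", sim_dir)
            else:
                result = simulate(config.simulate, outdir=sim_dir)
                layout, genes = result.layout, result.genes
                replicate_tags, truth = result.tags, result.truth
                expression_by_sample = {REFERENCE_SAMPLE: result.expression}
            # per-sample expression derived from each sample's planted states
            from .sim import generate_expression
            for sample in SAMPLES:
                if sample not in expression_by_sample:
                    expression_by_sample[sample] = generate_expression(
                        truth.gene_states[sample], config.simulate
                    )
            samples = list(SAMPLES)
            marks = list(MARKS)
        else:
            layout = read_chrom_sizes(config.inputs["chrom_sizes"])
            genes = read_gene_models(config.inputs["genes"], layout)
            expr = read_expression_table(config.inputs["expression"])
            replicate_tags = {}
            for entry in config.inputs["manifest"]:
                key = (entry["sample"], entry["mark"], entry.get("replicate", 1))
                replicate_tags[key] = read_tags(
                    entry["path"], layout, sample=entry["sample"], mark=entry["mark"]
                )
            truth = None
            samples = list(dict.fromkeys(k[0] for k in replicate_tags))
            marks = list(dict.fromkeys(k[1] for k in replicate_tags))
            expression_by_sample = {s: expr for s in samples}
    except Exception as exc:
        raise StageError(f"stage 'acquire' failed: {exc}") from exc
    n_raw = {k: len(v) for k, v in replicate_tags.items()}
    report.add_stage("acquire", t0, n_samples=len(samples), n_genes=len(genes),
                     tags_read=int(sum(n_raw.values())))

    # -- stage: merge replicates + redundancy filter ------------------------
    t0 = time.time()
    try:
        merged: dict[tuple[str, str], TagCollection] = {}
        for sample in samples:
            for mark in marks:
                reps = [v for k, v in sorted(replicate_tags.items())
                        if k[0] == sample and k[1] == mark]
                if not reps:
                    continue
                mg = merge_replicates(reps)
                merged[(sample, mark)] = filter_redundant_tags(mg, config.max_per_position)
    except Exception as exc:
        raise StageError(f"stage 'merge_filter' failed: {exc}") from exc
    report.add_stage(
        "merge_filter", t0,
        tags_after_filter={f"{s}|{m}": len(t) for (s, m), t in merged.items()},
    )

    # -- stage: island calling ----------------------------------------------
    t0 = time.time()
    try:
        islands_by: dict[tuple[str, str], list] = {}
        for (sample, mark), tags in merged.items():
            path = out / f"islands.{sample}.{mark}.bed"
            if config.resume and path.exists():
                islands_by[(sample, mark)] = read_islands(path)
            else:
                islands_by[(sample, mark)] = find_islands(
                    tags, layout, config.islands[mark], shift=shift
                )
                write_islands(islands_by[(sample, mark)], path)
            report.add_file(path)
        fractions = {
            f"{s}|{m}": genome_fraction_covered(v, layout)
            for (s, m), v in islands_by.items()
        }
    except Exception as exc:
        raise StageError(f"stage 'islands' failed: {exc}") from exc
    report.add_stage(
        "islands", t0,
        islands_called={f"{s}|{m}": len(v) for (s, m), v in islands_by.items()},
        genome_fraction=fractions,
    )

    # -- stage: binning, correlation, clustering ----------------------------
    t0 = time.time()
    try:
        cluster_files = []
        for mark in marks:
            mark_tags = [merged[(s, mark)] for s in samples if (s, mark) in merged]
            labels = [s for s in samples if (s, mark) in merged]
            if len(mark_tags) < 2:
                continue
            bm = bin_genome(mark_tags, layout, config.bin_size, shift=shift, labels=labels)
            bm = normalize(bm, "log2cpm")
            corr = sample_correlation(bm)
            dend = ward_cluster(bm)
            for path, writer, obj in [
                (out / f"bins.{mark}.tsv", write_bin_matrix, bm),
                (out / f"correlation.{mark}.tsv", write_correlation, corr),
                (out / f"dendrogram.{mark}.nwk", write_newick, dend),
            ]:
                writer(obj, path)
                report.add_file(path)
                cluster_files.append(str(path))
    except Exception as exc:
        raise StageError(f"stage 'cluster' failed: {exc}") from exc
    report.add_stage("cluster", t0, bin_size=config.bin_size, outputs=len(cluster_files))

    # -- stage: annotation, size densities, meta-profiles -------------------
    t0 = time.time()
    try:
        annotation = build_annotation(genes, layout)
        dist_rows = {}
        for (sample, mark), isls in islands_by.items():
            if isls:
                dist = element_distribution(isls, annotation)
                path = out / f"elements.{sample}.{mark}.tsv"
                write_distribution(dist, path)
                report.add_file(path)
                dist_rows[f"{sample}|{mark}"] = dist.to_dict()
        n_ext = min(config.n_extremes, len(expression_by_sample[samples[0]]) // 2)
        profiles = 0
        if n_ext > 0 and genes:
            ref = REFERENCE_SAMPLE if REFERENCE_SAMPLE in samples else samples[0]
            top, bottom = select_expression_extremes(expression_by_sample[ref], n_ext)
            for (sample, mark), tags in merged.items():
                for label, gene_set in (("top", top), ("bottom", bottom)):
                    prof = tss_metaprofile(
                        tags, genes, gene_set,
                        flank=config.profile_flank, step=config.profile_step, shift=shift,
                    )
                    path = out / f"profile.{sample}.{mark}.{label}.tsv"
                    write_profile(prof, path)
                    report.add_file(path)
                    profiles += 1
    except Exception as exc:
        raise StageError(f"stage 'annotate' failed: {exc}") from exc
    report.add_stage("annotate", t0, element_distributions=dist_rows, profiles=profiles)

    # -- stage: promoter dynamics -------------------------------------------
    t0 = time.time()
    try:
        windows = promoter_windows(
            genes, layout,
            upstream=config.promoter["upstream"], downstream=config.promoter["downstream"],
        )
        gene_ids = [g.gene_id for g in genes]
        cpm = {
            (s, m): count_promoter_reads(t, windows, shift=shift, normalize=True)
            for (s, m), t in merged.items()
        }
        k4_sets = enriched_promoter_sets(
            {s: islands_by[(s, "H3K4me3")] for s in samples if (s, "H3K4me3") in islands_by},
            windows,
        )
        k27_sets = enriched_promoter_sets(
            {s: islands_by[(s, "H3K27me3")] for s in samples if (s, "H3K27me3") in islands_by},
            windows,
        )
        states = bivalency_states(k4_sets, k27_sets, gene_ids)
        counts = state_counts(states)
        write_states(states, out / "bivalency_states.tsv")
        report.add_file(out / "bivalency_states.tsv")

        venn_samples = [s for s in samples if s != "CD34neg"] or samples
        for mark, sets in (("H3K4me3", k4_sets), ("H3K27me3", k27_sets)):
            sub = {s: sets[s] for s in venn_samples if s in sets}
            if len(sub) >= 2:
                path = out / f"venn.{mark}.json"
                write_venn(venn_partition(sub), list(sub), path)
                report.add_file(path)

        lfc_info = {}
        if "STFIA" in samples and "STF" in samples:
            for mark in marks:
                if ("STFIA", mark) in cpm and ("STF", mark) in cpm:
                    table = promoter_log2fc(
                        cpm[("STFIA", mark)], cpm[("STF", mark)],
                        pseudocount=config.pseudocount,
                        expression_a=expression_by_sample.get("STFIA"),
                        expression_b=expression_by_sample.get("STF"),
                    )
                    path = out / f"promoter_log2fc.{mark}.tsv"
                    table.to_csv(path, sep="\t")
                    report.add_file(path)
                    lfc_info[mark] = {
                        "min": float(table["log2fc"].min()),
                        "max": float(table["log2fc"].max()),
                        "n": int(len(table)),
                    }

        cmap = cooccupancy_dynamics(states) if states.shape[1] >= 2 else None
        if cmap is not None:
            write_transitions(cmap, out / "bivalency_transitions.tsv")
            report.add_file(out / "bivalency_transitions.tsv")
    except Exception as exc:
        raise StageError(f"stage 'promoters' failed: {exc}") from exc
    report.add_stage(
        "promoters", t0,
        promoter_set_sizes={
            "H3K4me3": {s: len(v) for s, v in k4_sets.items()},
            "H3K27me3": {s: len(v) for s, v in k27_sets.items()},
        },
        bivalent_counts={s: int(c) for s, c in counts.loc["bivalent"].items()},
        log2fc=lfc_info,
        retained_fractions=(
            {f"{a}->{b}": v for (a, b), v in cmap.retained_fraction.items()}
            if cmap is not None else {}
        ),
    )

    report.to_json(out / "report.json")
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def setup_logging(outdir: str | Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr and, when a run directory is given, to run.log inside it."""
    logger.setLevel(logging.DEBUG)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setLevel(level)
    stream.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(stream)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(outdir) / "run.log")
        fh.setLevel(logging.DEBUG)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
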