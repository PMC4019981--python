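"""End-to-end orchestration: scoring, clustering, network assembly, quant.

The analysis is a fixed DAG — simulate (or load) -> NSAF -> control
enrichment -> WD^N -> rescue -> clustering -> network -> quantification —
driven by one YAML config file.  Every stage is also callable as a plain
library function; :func:`score_interactions` runs the scoring cascade in
memory and is what the tests and the CLI build on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .comppass import StatsTable, build_stats_table, simulate_threshold, wdn_filter
from .config import PipelineConfig
from .datamodel import Dataset, InteractionNetwork
from .errors import ConfigError, DataError, StageError
from .io import read_dataset, write_dataset, write_network
from .modules import (
    GeneDistanceMatrix,
    ModuleAssignment,
    assemble_network,
    assign_bait_modules,
    gene_distance_matrix,
    hierarchical_modules,
    relative_abundance,
    rescue_subthreshold,
)
from .nsaf import ControlProfile, build_control_profile, compute_nsaf, enrichment_filter
from .quant import compare_bait_conditions
from .simulate import BASELINE_CONDITION, GeneratorConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    """Everything the scoring cascade produced for one dataset."""

    scores: pd.DataFrame  # bait, prey, xbar, enrichment, wd, wdn, flags
    threshold: float
    profile: ControlProfile
    stats: StatsTable
    nsaf: pd.DataFrame
    control_nsaf: pd.DataFrame
    rel: pd.DataFrame
    gdm: GeneDistanceMatrix | None
    modules: ModuleAssignment | None
    bait_modules: dict[str, int]
    rescued: set[tuple[str, str]]
    network: InteractionNetwork

    @property
    def hcip_pairs(self) -> set[tuple[str, str]]:
        """Pairs passing both filters (before rescue)."""
        mask = self.scores["is_hcip"]
        return set(
            zip(self.scores.loc[mask, "bait"], self.scores.loc[mask, "prey"])
        )


def score_interactions(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    condition: str | None = BASELINE_CONDITION,
) -> ScoreResult:
    """Run NSAF -> enrichment -> WD^N -> rescue -> clustering -> network.

    ``condition`` restricts scoring to one condition's runs (pass ``None``
    to pool every run).  Returns a :class:`ScoreResult` whose ``scores``
    DataFrame has one row per detected candidate with all score components
    and the ``is_hcip`` / ``rescued`` flags.
    """
    config = config or PipelineConfig()
    if condition is not None and condition in dataset.conditions:
        ds = dataset.subset_condition(condition)
    else:
        ds = dataset
    nsaf = compute_nsaf(ds)
    control_nsaf = compute_nsaf(ds, controls=True)
    profile = build_control_profile(control_nsaf, config.control_top_n)
    enriched = enrichment_filter(nsaf, ds, profile, config)

    table = build_stats_table(nsaf, ds, omega_floor=config.omega_floor)
    threshold = simulate_threshold(table, config)
    wdn = wdn_filter(table, threshold, config)

    scores = enriched.merge(wdn, on=["bait", "prey"], how="inner")
    scores["is_hcip"] = scores["passed_enrichment"] & scores["passed_wdn"]

    rel = relative_abundance(nsaf, ds)
    candidates = sorted(scores["prey"].unique())
    gdm = None
    rescued: set[tuple[str, str]] = set()
    if len(candidates) >= 2:
        gdm = gene_distance_matrix(rel.loc[candidates])
        rescued = rescue_subthreshold(
            scores[["bait", "prey", "is_hcip", "passed_enrichment"]], gdm, config
        )
    scores["rescued"] = [
        (b, p) in rescued for b, p in zip(scores["bait"], scores["prey"])
    ]

    hcip_preys = sorted(scores.loc[scores["is_hcip"], "prey"].unique())
    modules = None
    bait_modules: dict[str, int] = {}
    module_labels: dict[str, int] = {}
    if len(hcip_preys) >= max(2, config.n_major_clusters):
        modules = hierarchical_modules(
            gene_distance_matrix(rel.loc[hcip_preys]), config.n_major_clusters
        )
        bait_modules = assign_bait_modules(rel, modules)
        module_labels = {**modules.labels, **bait_modules}

    network = assemble_network(scores, rescued, module_labels, rel)
    return ScoreResult(
        scores=scores,
        threshold=threshold,
        profile=profile,
        stats=table,
        nsaf=nsaf,
        control_nsaf=control_nsaf,
        rel=rel,
        gdm=gdm,
        modules=modules,
        bait_modules=bait_modules,
        rescued=rescued,
        network=network,
    )


@dataclass
class PipelineSpec:
    """Parsed and validated pipeline config file."""

    pipeline: PipelineConfig
    generator: GeneratorConfig | None = None
    inputs: dict[str, str] | None = None
    quant: dict | None = None
    stages: dict[str, bool] = field(default_factory=dict)


_TOP_LEVEL_KEYS = {"pipeline", "generator", "inputs", "quant", "stages"}
_STAGE_NAMES = ("simulate", "nsaf", "enrichment", "wdn", "cluster", "network", "quant")


def validate_config(path: str | Path) -> PipelineSpec:
    """Parse a YAML config file, rejecting unknown keys and bad values."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    if "pipeline" not in raw or not isinstance(raw["pipeline"], dict):
        raise ConfigError("config requires a 'pipeline' section")
    if "rng_seed" not in raw["pipeline"]:
        raise ConfigError("pipeline.rng_seed is mandatory (no wall-clock seeding)")
    pipeline = PipelineConfig.from_mapping(raw["pipeline"])
    generator = None
    if "generator" in raw:
        if "rng_seed" not in raw["generator"]:
            raise ConfigError("generator.rng_seed is mandatory")
        generator = GeneratorConfig.from_mapping(raw["generator"])
    inputs = raw.get("inputs")
    if inputs is not None:
        missing = {"runs", "proteins"} - set(inputs)
        if missing:
            raise ConfigError(f"inputs section missing key(s): {', '.join(sorted(missing))}")
    if generator is None and inputs is None:
        raise ConfigError("config requires a 'generator' or an 'inputs' section")
    quant = raw.get("quant")
    if quant is not None:
        missing = {"bait", "condition_a", "condition_b"} - set(quant)
        if missing:
            raise ConfigError(f"quant section missing key(s): {', '.join(sorted(missing))}")
    stages = raw.get("stages", {})
    bad = set(stages) - set(_STAGE_NAMES)
    if bad:
        raise ConfigError(f"unknown stage name(s): {', '.join(sorted(bad))}")
    return PipelineSpec(
        pipeline=pipeline, generator=generator, inputs=inputs, quant=quant,
        stages={s: bool(stages.get(s, True)) for s in _STAGE_NAMES},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_nsaf_long(nsaf: pd.DataFrame, path: Path) -> None:
    long = nsaf.stack().reset_index()
    long.columns = ["run_id", "protein_id", "nsaf"]
    long = long[long["nsaf"] > 0]
    long.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages and write all outputs plus a run record.

    Outputs: ``runs.tsv``/``proteins.tsv`` (when simulating), ``nsaf.tsv``,
    ``scores.tsv``, ``modules.tsv``, ``network.{tsv,sif,graphml}``,
    ``quant.tsv`` (when configured) and ``run_record.json`` carrying the
    config snapshot, input checksums, stage timings, the seed and an output
    manifest with checksums.  A stage failure raises :class:`StageError`
    naming the stage; outputs already written are renamed with a
    ``.partial`` suffix.
    """
    spec = validate_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    timings: dict[str, float] = {}
    record: dict = {
        "config": {
            "pipeline": dataclasses.asdict(spec.pipeline),
            "generator": dataclasses.asdict(spec.generator) if spec.generator else None,
            "inputs": spec.inputs,
            "quant": spec.quant,
            "stages": spec.stages,
        },
        "seed": spec.pipeline.rng_seed,
        "input_checksums": {},
    }
    stage = "setup"
    try:
        stage = "simulate" if spec.generator is not None else "load"
        t0 = time.perf_counter()
        if spec.generator is not None and spec.stages.get("simulate", True):
            dataset, truth = simulate_dataset(spec.generator)
            write_dataset(dataset, out / "runs.tsv", out / "proteins.tsv")
            produced += [out / "runs.tsv", out / "proteins.tsv"]
        elif spec.inputs is not None:
            runs_path, prot_path = Path(spec.inputs["runs"]), Path(spec.inputs["proteins"])
            dataset = read_dataset(runs_path, prot_path)
            record["input_checksums"] = {
                str(runs_path): _sha256(runs_path),
                str(prot_path): _sha256(prot_path),
            }
        else:
            raise StageError("simulate: stage disabled and no inputs configured")
        if not dataset.control_runs:
            raise DataError(
                "enrichment: no control runs in the dataset "
                "(mock-control table missing)"
            )
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])

        stage = "score"
        t0 = time.perf_counter()
        result = score_interactions(dataset, spec.pipeline)
        _write_nsaf_long(result.nsaf, out / "nsaf.tsv")
        result.scores.to_csv(out / "scores.tsv", sep="\t", index=False, lineterminator="\n")
        produced += [out / "nsaf.tsv", out / "scores.tsv"]
        timings[stage] = time.perf_counter() - t0
        logger.info(
            "stage score done in %.2fs: %d candidates, %d HCIPs, %d rescued, WD threshold %.4g",
            timings[stage], len(result.scores), int(result.scores["is_hcip"].sum()),
            len(result.rescued), result.threshold,
        )

        stage = "cluster"
        t0 = time.perf_counter()
        if spec.stages.get("cluster", True) and result.modules is not None:
            rows = [
                {"protein_id": p, "module": m, "kind": "prey"}
                for p, m in result.modules.labels.items()
            ] + [
                {"protein_id": b, "module": m, "kind": "bait"}
                for b, m in result.bait_modules.items()
                if b not in result.modules.labels
            ]
            pd.DataFrame(rows, columns=["protein_id", "module", "kind"]).to_csv(
                out / "modules.tsv", sep="\t", index=False, lineterminator="\n"
            )
            produced.append(out / "modules.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "network"
        t0 = time.perf_counter()
        for fmt, name in (("edge-table", "network.tsv"), ("sif", "network.sif"),
                          ("graphml", "network.graphml")):
            write_network(result.network, out / name, fmt)
            produced.append(out / name)
        timings[stage] = time.perf_counter() - t0

        if spec.quant is not None and spec.stages.get("quant", True):
            stage = "quant"
            t0 = time.perf_counter()
            comparison = compare_bait_conditions(
                dataset,
                spec.quant["bait"],
                spec.quant["condition_a"],
                spec.quant["condition_b"],
                spec.pipeline,
            )
            comparison.table.to_csv(out / "quant.tsv", sep="\t", index=False, lineterminator="\n")
            produced.append(out / "quant.tsv")
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        for p in produced:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        if isinstance(exc, StageError):
            raise
        raise StageError(f"{stage}: {exc}") from exc

    record["stage_timings_s"] = timings
    record["outputs"] = {p.name: _sha256(p) for p in produced}
    with open(out / "run_record.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return record


__all__ = [
    "PipelineSpec",
    "ScoreResult",
    "run_pipeline",
    "score_interactions",
    "validate_config",
]
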