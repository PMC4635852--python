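"""End-to-end pipeline: preprocess -> outlier removal -> clustering and
k-selection -> differential expression -> core/unique partition -> per-list
enrichment and interaction networks.

Configuration is a strict dataclass tree (unknown keys are rejected before
any stage runs, YAML-friendly); every run writes its stage outputs plus a
JSON manifest with the effective configuration, library versions, and
sha256 checksums, so a rerun with the same config and inputs is
byte-identical (floats serialize at 6 significant digits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .preprocess import FilterConfig, filter_genes, zscore_normalize
from .subtype_discovery import (
    classical_mds,
    flag_outliers,
    hierarchical_cluster,
    pairwise_distances,
    select_k,
)
from .diffexpr import differential_genes, partition_genes
from .enrichment_networks import EnrichmentConfig, run_three_way
from .synthetic_data import SyntheticConfig, generate, simulate_to_dir

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

logger = logging.getLogger("txsubtypes")

FLOAT_FORMAT = "%.6g"


@dataclass
class InputsConfig:
    expression: str | None = None
    groups: str | None = None
    gene_sets: str | None = None
    ppi: str | None = None
    regulatory: str | None = None
    drug_target: str | None = None
    synthetic: bool = False          # generate inputs instead of reading them
    synthetic_seed: int = 0


@dataclass
class LabelsConfig:
    case_group: str = "TCMR"
    control_group: str = "Control"
    subtype_prefix: str = "TCMR0"    # discovered clusters become TCMR01, TCMR02, ...


@dataclass
class DiscoveryConfig:
    mds_dim: int = 2
    z_threshold: float = 2.0
    center_mode: str = "medoid"
    mds_distance: str = "euclidean"
    cluster_distance: str = "one_minus_pearson"
    linkage: str = "average"
    k_min: int = 2
    k_max: int = 6
    neighbors: int = 10


@dataclass
class DifferentialConfig:
    alpha: float = 0.05
    variance_mode: str = "pooled"
    gate: str = "q"


@dataclass
class PipelineConfig:
    inputs: InputsConfig = field(default_factory=InputsConfig)
    labels: LabelsConfig = field(default_factory=LabelsConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    universe: str = "filtered"       # hypergeometric universe: filtered | all
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or "top level"
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.type, str) and f.type in _SECTION_TYPES):
            section_cls = _SECTION_TYPES.get(f.type, f.type) if isinstance(
                f.type, str) else f.type
            kwargs[name] = _build_dataclass(section_cls, value,
                                            f"{path}.{name}" if path else name)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "InputsConfig": InputsConfig,
    "LabelsConfig": LabelsConfig,
    "FilterConfig": FilterConfig,
    "DiscoveryConfig": DiscoveryConfig,
    "DifferentialConfig": DifferentialConfig,
    "EnrichmentConfig": EnrichmentConfig,
}


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    filter_report: object
    embedding: object
    solution: object
    subtype_samples: dict[str, list[str]]
    de_between: object
    de_vs_control: dict[str, object]
    partition: object
    three_way: dict | None
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_all(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the full pipeline and write all stage outputs under
    *out_dir*.  Any stage failure aborts with the stage named in the
    exception; outputs written so far are retained."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest: dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = path

    stage = "load_inputs"
    try:
        t0 = _stage(stage)
        if config.inputs.synthetic:
            sim_cfg = SyntheticConfig(seed=config.inputs.synthetic_seed,
                                      case_group=config.labels.case_group,
                                      control_group=config.labels.control_group)
            sim_paths = simulate_to_dir(out / "simulated", sim_cfg)
            matrix = io.read_expression_tsv(sim_paths["expr"], sim_paths["groups"])
            gene_sets = io.read_gmt(sim_paths["gmt"])
            interactions = {
                "ppi": io.read_interactions(sim_paths["ppi"], "ppi"),
                "regulatory": io.read_interactions(sim_paths["regulatory"],
                                                   "regulatory"),
                "drug_target": io.read_interactions(sim_paths["drugs"],
                                                    "drug_target"),
            }
        else:
            if not config.inputs.expression:
                raise ValueError("inputs.expression is required unless "
                                 "inputs.synthetic is true")
            matrix = io.read_expression_tsv(config.inputs.expression,
                                            config.inputs.groups)
            gene_sets = (io.read_gmt(config.inputs.gene_sets)
                         if config.inputs.gene_sets else None)
            interactions = {}
            for kind, attr in (("ppi", "ppi"), ("regulatory", "regulatory"),
                               ("drug_target", "drug_target")):
                path = getattr(config.inputs, attr)
                if path:
                    interactions[kind] = io.read_interactions(path, kind)
        manifest["stages"][stage] = {
            "n_genes": matrix.n_genes, "n_samples": matrix.n_samples,
            "seconds": round(time.perf_counter() - t0, 3)}

        stage = "preprocess"
        t0 = _stage(stage)
        filtered, report = filter_genes(matrix, config.filter)
        zmatrix = zscore_normalize(filtered)
        io.write_expression_tsv(zmatrix, out / "filtered_zscored.tsv")
        report.stats.to_csv(out / "filter_report.tsv", sep="\t",
                            float_format=FLOAT_FORMAT)
        record("filtered_zscored", out / "filtered_zscored.tsv")
        record("filter_report", out / "filter_report.tsv")
        manifest["stages"][stage] = {
            "n_input_genes": report.n_input_genes,
            "n_retained_genes": report.n_retained_genes,
            "seconds": round(time.perf_counter() - t0, 3)}

        stage = "outlier_removal"
        t0 = _stage(stage)
        case_samples = zmatrix.samples_in_group(config.labels.case_group)
        if len(case_samples) < 4:
            raise ValueError(
                f"need >= 4 samples in case group {config.labels.case_group!r}")
        case_matrix = zmatrix.subset_samples(case_samples)
        dist = pairwise_distances(case_matrix.values.T,
                                  config.discovery.mds_distance)
        coords = classical_mds(dist, config.discovery.mds_dim)
        embedding = flag_outliers(coords, case_samples,
                                  config.discovery.center_mode,
                                  config.discovery.z_threshold)
        emb = pd.DataFrame({
            "sample_id": embedding.sample_ids,
            **{f"mds_{i + 1}": embedding.coordinates[:, i]
               for i in range(embedding.coordinates.shape[1])},
            "distance": embedding.distance,
            "zscore": embedding.zscore,
            "outlier": [s in embedding.outliers for s in embedding.sample_ids],
        })
        emb.to_csv(out / "embedding.tsv", sep="\t", index=False,
                   float_format=FLOAT_FORMAT)
        record("embedding", out / "embedding.tsv")
        manifest["stages"][stage] = {
            "outliers": sorted(embedding.outliers),
            "degenerate": embedding.degenerate,
            "seconds": round(time.perf_counter() - t0, 3)}

        stage = "clustering"
        t0 = _stage(stage)
        retained = embedding.retained_sample_ids
        cluster_matrix = zmatrix.subset_samples(retained)
        observations = cluster_matrix.values.T
        tree = hierarchical_cluster(observations,
                                    config.discovery.cluster_distance,
                                    config.discovery.linkage)
        cdist = pairwise_distances(observations,
                                   config.discovery.cluster_distance)
        k_max = min(config.discovery.k_max, len(retained) - 1)
        solution = select_k(cdist, tree,
                            range(config.discovery.k_min, k_max + 1),
                            L=config.discovery.neighbors)
        labels = solution.labels
        subtype_of = {
            s: f"{config.labels.subtype_prefix}{lab}"
            for s, lab in zip(retained, labels)
        }
        pd.DataFrame({"sample_id": retained,
                      "cluster": labels,
                      "subtype": [subtype_of[s] for s in retained]}).to_csv(
            out / "labels.tsv", sep="\t", index=False)
        record("labels", out / "labels.tsv")
        def _finite(x: float):
            return round(float(x), 6) if np.isfinite(x) else None

        solution_json = {
            "selected_k": solution.selected_k,
            "votes": solution.selection_votes,
            "indices_by_k": {
                str(k): {name: _finite(val)
                         for name, val in dataclasses.asdict(v).items()}
                for k, v in solution.indices_by_k.items()},
            "merge_tree": [
                {"a": int(a), "b": int(b), "height": round(float(h), 6),
                 "size": int(n)}
                for a, b, h, n in solution.merge_tree],
        }
        (out / "solution.json").write_text(
            json.dumps(solution_json, indent=2, allow_nan=False))
        record("solution", out / "solution.json")
        manifest["stages"][stage] = {
            "selected_k": solution.selected_k,
            "votes": solution.selection_votes,
            "seconds": round(time.perf_counter() - t0, 3)}

        stage = "differential_expression"
        t0 = _stage(stage)
        subtype_samples: dict[str, list[str]] = {}
        for s in retained:
            subtype_samples.setdefault(subtype_of[s], []).append(s)
        names = sorted(subtype_samples)
        first, second = names[0], names[1]
        de_cfg = config.differential
        de_between = differential_genes(
            zmatrix, subtype_samples[first], subtype_samples[second],
            alpha=de_cfg.alpha, variance_mode=de_cfg.variance_mode,
            gate=de_cfg.gate, group1=first, group2=second)
        controls = zmatrix.samples_in_group(config.labels.control_group)
        de_vs_control: dict[str, object] = {}
        if controls:
            for name in (first, second):
                de_vs_control[name] = differential_genes(
                    zmatrix, subtype_samples[name], controls,
                    alpha=de_cfg.alpha, variance_mode=de_cfg.variance_mode,
                    gate=de_cfg.gate, group1=name,
                    group2=config.labels.control_group)
            partition = partition_genes(de_vs_control[first].significant,
                                        de_vs_control[second].significant)
        else:
            partition = partition_genes(set(), set())
        de_between.table.to_csv(out / f"de_{first}_vs_{second}.tsv", sep="\t",
                                float_format=FLOAT_FORMAT)
        record("de_between", out / f"de_{first}_vs_{second}.tsv")
        for name, res in de_vs_control.items():
            res.table.to_csv(out / f"de_{name}_vs_control.tsv", sep="\t",
                             float_format=FLOAT_FORMAT)
            record(f"de_{name}_vs_control", out / f"de_{name}_vs_control.tsv")
        (out / "partition.json").write_text(
            json.dumps(partition.as_dict(), indent=2))
        record("partition", out / "partition.json")
        manifest["stages"][stage] = {
            "contrast": f"{first} vs {second}",
            "n_significant_between": len(de_between.significant),
            "partition_sizes": {k: len(v) for k, v in
                                partition.as_dict().items()},
            "seconds": round(time.perf_counter() - t0, 3)}

        stage = "enrichment_networks"
        t0 = _stage(stage)
        three_way = None
        if gene_sets is not None:
            universe = (zmatrix.gene_ids if config.universe == "filtered"
                        else matrix.gene_ids)
            three_way = run_three_way(partition, gene_sets, interactions,
                                      universe, config.enrichment)
            list_names = {"core": "core", "unique_a": first,
                          "unique_b": second}
            for key, result in three_way.items():
                label = list_names[key]
                if result.enrichment is not None:
                    frame = result.enrichment.table.copy()
                    frame["overlap_genes"] = frame["overlap_genes"].map(
                        ";".join)
                    frame.to_csv(out / f"enrich_{label}.tsv", sep="\t",
                                 float_format=FLOAT_FORMAT)
                    record(f"enrich_{label}", out / f"enrich_{label}.tsv")
                if result.pathway_graph is not None:
                    io.graph_to_graphml(result.pathway_graph,
                                        out / f"pathways_{label}.graphml")
                    record(f"pathways_{label}",
                           out / f"pathways_{label}.graphml")
                for kind, module in result.modules.items():
                    io.graph_to_graphml(module,
                                        out / f"module_{label}_{kind}.graphml")
                    io.write_sif(
                        ((u, d.get("kind", kind), v)
                         for u, v, d in module.edges(data=True)),
                        out / f"module_{label}_{kind}.sif")
                    record(f"module_{label}_{kind}",
                           out / f"module_{label}_{kind}.graphml")
            manifest["stages"][stage] = {
                "lists": {list_names[k]: (len(r.enrichment.hits)
                                          if r.enrichment is not None else 0)
                          for k, r in three_way.items()},
                "seconds": round(time.perf_counter() - t0, 3)}
        else:
            manifest["stages"][stage] = {"skipped": "no gene sets supplied"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {name: {"path": str(p.relative_to(out)),
                                  "sha256": _sha256(p)}
                           for name, p in sorted(outputs.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return PipelineResult(
        config=config, filter_report=report, embedding=embedding,
        solution=solution, subtype_samples=subtype_samples,
        de_between=de_between, de_vs_control=de_vs_control,
        partition=partition, three_way=three_way, manifest=manifest,
        out_dir=out)


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "txsubtypes": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
    }
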