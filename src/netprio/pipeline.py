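"""End-to-end orchestration: network in, core genes and statistics out.

A run is described by a single declarative :class:`RunConfig` (YAML or
constructed in code).  Stages execute in a fixed order — read network,
centrality table, hub intersection, prioritization (clean / standardize /
elbow K-means / Isolation Forest / PCA / composite score / core genes),
then the optional overlap test and ORA enrichment — and every stage's
output is written to the output directory together with a reproducibility
manifest (config echo, input hashes, per-stage cardinalities, version,
timestamps).  All randomness flows from the one configured seed through
stage-name-derived substreams, so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, field_validator, model_validator

from . import __version__
from .graph_io import (
    GeneList,
    read_edge_list,
    read_gene_list,
    read_string_tsv,
    write_gene_list,
    write_table,
)
from .prioritizer import ASCENDING_INDICES, DESCENDING_INDICES, CoreTargetModel
from .stats import ora_enrich, overlap_test, read_gmt
from .topology import CENTRALITY_COLUMNS, centrality_table, hub_intersection

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report", "stage_seed"]

log = logging.getLogger("netprio")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage substream seed derived from the run seed and stage name."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Declarative configuration of a full pipeline run.

    Defaults mirror the reference workflow: STRING confidence cutoff 0.4,
    K-means with max_iter 300 and tol 1e-4 over k = 1..10, Isolation
    Forest with 100 trees, 0.8 subsampling and contamination 0.10, two
    PCA components, core-gene rank threshold 20, and seed 42.  The hub
    intersection size ``hub_top_k`` has no reference value and must be
    set explicitly.
    """

    # inputs
    network: Path
    network_format: Literal["string", "edgelist"] = "string"
    targets_a: Optional[Path] = None
    targets_b: Optional[Path] = None
    gmt: Optional[Path] = None
    output_dir: Path = Path("netprio_out")

    # network reading
    string_min_score: float = 0.4
    drop_isolated: bool = True

    # topology
    epc_retain_p: float = 0.5
    epc_iterations: int = 1000
    hub_metrics: tuple[str, ...] = ("MNC", "EPC", "Bottleneck", "Betweenness")
    hub_top_k: int
    ml_on_hub_subset: bool = True

    # prioritization
    descending_indices: tuple[str, ...] = DESCENDING_INDICES
    ascending_indices: tuple[str, ...] = ASCENDING_INDICES
    feature_missing_max: float = 0.005
    sample_missing_max: float = 0.005
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-4
    kmeans_n_init: int = 1
    k_min: int = 1
    k_max: int = 10
    if_n_trees: int = 100
    if_subsample: float = 0.8
    if_contamination: float = 0.10
    n_components: int = 2
    rank_threshold: int = 20

    # statistics
    universe_n: Optional[int] = None

    seed: int = 42

    @field_validator("string_min_score")
    @classmethod
    def _score_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("string_min_score must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _directions_partition(self) -> "RunConfig":
        desc, asc = set(self.descending_indices), set(self.ascending_indices)
        if desc & asc:
            raise ValueError(f"direction sets overlap: {sorted(desc & asc)}")
        if desc | asc != set(CENTRALITY_COLUMNS):
            raise ValueError(
                "descending_indices and ascending_indices must partition the "
                "14 centrality columns"
            )
        if not set(self.hub_metrics) <= set(CENTRALITY_COLUMNS):
            raise ValueError(f"unknown hub metrics: "
                             f"{sorted(set(self.hub_metrics) - set(CENTRALITY_COLUMNS))}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_jsonable(self) -> dict:
        out = json.loads(self.model_dump_json())
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write tables plus a manifest to the output
    directory.  On failure a ``.partial`` marker naming the failed stage is
    left next to whatever outputs were already written."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    manifest: dict = {
        "tool": "netprio",
        "version": __version__,
        "config": config.to_jsonable(),
        "inputs": {},
        "stages": {},
        "timestamps": {"started": datetime.now(timezone.utc).isoformat()},
    }
    for key in ("network", "targets_a", "targets_b", "gmt"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    stage = "read_network"
    try:
        marker.write_text(stage + "\n")
        if config.network_format == "string":
            g = read_string_tsv(
                config.network, config.string_min_score,
                drop_isolated=config.drop_isolated,
            )
        else:
            g = read_edge_list(config.network, drop_isolated=config.drop_isolated)
        manifest["stages"][stage] = {
            "nodes": g.number_of_nodes(), "edges": g.number_of_edges()
        }
        log.info("%s: %d nodes, %d edges", stage, g.number_of_nodes(),
                 g.number_of_edges())

        stage = "centrality"
        marker.write_text(stage + "\n")
        table = centrality_table(
            g,
            epc_retain_p=config.epc_retain_p,
            epc_iterations=config.epc_iterations,
            seed=stage_seed(config.seed, "epc"),
        )
        write_table(table, out / "centrality.csv")
        manifest["stages"][stage] = {"genes": len(table), "indices": len(table.columns)}
        log.info("%s: %d genes x %d indices", stage, len(table), len(table.columns))

        stage = "hub_intersection"
        marker.write_text(stage + "\n")
        hubs = hub_intersection(table, config.hub_metrics, config.hub_top_k)
        write_gene_list(hubs, out / "hubs.txt")
        manifest["stages"][stage] = {
            "top_k": config.hub_top_k, "metrics": list(config.hub_metrics),
            "hubs": len(hubs),
        }
        log.info("%s: %d genes in the %d-way top-%d intersection", stage,
                 len(hubs), len(config.hub_metrics), config.hub_top_k)

        stage = "prioritize"
        marker.write_text(stage + "\n")
        features = table.loc[list(hubs)] if config.ml_on_hub_subset else table
        model = CoreTargetModel(
            features,
            descending_indices=config.descending_indices,
            ascending_indices=config.ascending_indices,
            feature_missing_max=config.feature_missing_max,
            sample_missing_max=config.sample_missing_max,
            k_range=range(config.k_min, config.k_max + 1),
            kmeans_max_iter=config.kmeans_max_iter,
            kmeans_tol=config.kmeans_tol,
            kmeans_n_init=config.kmeans_n_init,
            if_n_trees=config.if_n_trees,
            if_subsample_fraction=config.if_subsample,
            if_contamination=config.if_contamination,
            rank_threshold=config.rank_threshold,
        )
        results = model.fit(seed=config.seed)
        results.to_csv(out / "prioritization.csv")
        write_gene_list(results.core_genes, out / "core_genes.txt")
        manifest["stages"][stage] = {
            "genes": len(results.table),
            "chosen_k": results.chosen_k,
            "weak_elbow": bool(results.cluster.weak_elbow),
            "wcss": {str(k): v for k, v in sorted(results.cluster.wcss.items())},
            "outliers_flagged": results.outliers.n_flagged,
            "explained_variance_ratio": [
                float(v) for v in results.explained_variance_ratio
            ],
            "core_genes": list(results.core_genes),
        }
        log.info("%s: k=%d, %d outliers, %d core genes", stage, results.chosen_k,
                 results.outliers.n_flagged, len(results.core_genes))

        lists: dict[str, GeneList] = {}
        if config.targets_a and config.targets_b:
            stage = "overlap_test"
            marker.write_text(stage + "\n")
            if config.universe_n is None:
                raise ValueError("universe_n is required for the overlap test")
            lists["a"] = read_gene_list(config.targets_a)
            lists["b"] = read_gene_list(config.targets_b)
            ot = overlap_test(lists["a"], lists["b"], config.universe_n)
            ot.to_json(out / "overlap.json")
            manifest["stages"][stage] = ot.to_dict()
            log.info("%s: x=%d of K=%d, M=%d in N=%d (log10 p = %.2f)", stage,
                     ot.observed_x, ot.draws_K, ot.successes_M, ot.universe_N,
                     ot.log10_p)

        if config.gmt:
            stage = "enrich"
            marker.write_text(stage + "\n")
            if config.universe_n is None:
                raise ValueError("universe_n is required for enrichment")
            collection = read_gmt(config.gmt)
            universe = GeneList.from_iterable("universe", table.index)
            query = results.core_genes if len(results.core_genes) else hubs
            enr = ora_enrich(query, collection, universe)
            enr.to_csv(out / "enrichment.csv", index=False)
            manifest["stages"][stage] = {
                "sets_tested": len(enr),
                "query": query.name,
                "significant_fdr_05": int((enr["bh_fdr"] <= 0.05).sum()) if len(enr) else 0,
            }
            log.info("%s: %d sets tested", stage, len(enr))
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc

    manifest["timestamps"]["finished"] = datetime.now(timezone.utc).isoformat()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "report.txt").write_text(report(out), encoding="utf-8")
    marker.unlink(missing_ok=True)
    return out


def report(output_dir: str | Path, top_n: int = 10) -> str:
    """Human-readable run summary, regenerable from the saved tables alone."""
    import pandas as pd

    out = Path(output_dir)
    lines: list[str] = ["netprio run summary", "===================", ""]
    manifest_path = out / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        rn = manifest.get("stages", {}).get("read_network", {})
        if rn:
            lines.append(f"network: {rn.get('nodes')} nodes, {rn.get('edges')} edges")
        hi = manifest.get("stages", {}).get("hub_intersection", {})
        if hi:
            lines.append(
                f"hub intersection (top-{hi.get('top_k')} of "
                f"{', '.join(hi.get('metrics', []))}): {hi.get('hubs')} genes"
            )
    overlap_path = out / "overlap.json"
    if overlap_path.exists():
        ot = json.loads(overlap_path.read_text())
        lines += [
            "",
            "overlap test",
            f"  universe N = {ot['universe_N']}, K = {ot['draws_K']}, "
            f"M = {ot['successes_M']}, observed x = {ot['observed_x']}",
            f"  expected overlap = {ot['expected']:.1f}",
            f"  one-sided hypergeometric log10 p = {ot['log10_p']:.2f}",
        ]
    pri_path = out / "prioritization.csv"
    if pri_path.exists():
        t = pd.read_csv(pri_path)
        pr = manifest.get("stages", {}).get("prioritize", {})
        lines += [
            "",
            f"prioritization: {len(t)} genes"
            + (f", elbow k = {pr['chosen_k']}" if "chosen_k" in pr else "")
            + (" [weak elbow]" if pr.get("weak_elbow") else ""),
            f"outliers flagged: {int(t['is_outlier'].sum())}",
            "",
            f"top {min(top_n, len(t))} by composite score",
            "Gene\tComposite Score",
        ]
        head = t.sort_values("composite_rank", kind="mergesort").head(top_n)
        for _, row in head.iterrows():
            lines.append(f"{row['gene']}\t{row['composite_score']:.2f}")
        core = t.loc[t["is_core"] == 1].sort_values("composite_rank")
        lines.append("")
        if len(core):
            lines.append("core genes: " + ", ".join(core["gene"]))
        else:
            lines.append("core genes: none selected")
    enr_path = out / "enrichment.csv"
    if enr_path.exists():
        e = pd.read_csv(enr_path)
        lines += ["", f"enrichment: {len(e)} sets tested"]
        for _, row in e.head(5).iterrows():
            lines.append(
                f"  {row['set_name']}: overlap {row['overlap_count']}/"
                f"{row['set_size']}, p = {row['p_value']:.3g}, "
                f"FDR = {row['bh_fdr']:.3g}"
            )
    lines.append("")
    return "\n".join(lines)
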