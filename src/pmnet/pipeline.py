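"""End-to-end orchestration: cohort on disk -> tables on disk.

``run_pipeline`` sequences the full analysis for both hemispheres —
normalization, group aggregation, the threshold/admission sweep, distance
ranking on the parieto-premotor graph, the two-stage node characterization,
and the edge-wise lateralization and variability statistics — and writes
every table plus a JSON run manifest.  Outputs are deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group import (GroupGraph, ThresholdSpec, admissibility_sweep,
                    admit_graphs, aggregate_group, records_to_frame)
from .io import (NormalizedConnectome, SubjectConnectome, mask_interlobar,
                 normalize_connectome, read_connectivity_matrix,
                 write_connectivity_matrix)
from .paths import (classify_edge_percentiles, distance_frame,
                    distance_matrix, select_analysis_graph)
from .roi import RoiSet
from .roles import (ThresholdMetrics, node_betweenness, node_role_table,
                    node_strength, participation_coefficient,
                    within_module_degree_z)
from .stats import edge_statistics, variability_table
from .synthetic import SyntheticSpec, SyntheticTruth

HEMISPHERES = ("left", "right")


@dataclass
class PipelineConfig:
    cohort_dir: str
    outdir: str
    roi_metadata: str | None = None       # default: <cohort_dir>/roi_metadata.csv
    waytotals: str | None = None          # default: <cohort_dir>/waytotals.csv
    normalized: bool = False              # inputs already waytotal-normalized
    aggregation: str = "mean"
    threshold_lo: float = 0.01
    threshold_hi: float = 0.1
    threshold_step: float = 0.0025
    n_null: int = 100
    seed: int = 0
    alpha: float = 0.05
    percentiles: tuple[float, ...] = (15.0, 25.0, 50.0, 75.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = raw.pop("threshold", {})
        for key, name in (("lo", "threshold_lo"), ("hi", "threshold_hi"),
                          ("step", "threshold_step")):
            if key in thr:
                raw[name] = thr[key]
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        return cls(**raw)

    def threshold_spec(self) -> ThresholdSpec:
        return ThresholdSpec(self.threshold_lo, self.threshold_hi,
                             self.threshold_step)


@dataclass
class HemisphereResult:
    roiset: RoiSet
    subjects: list[NormalizedConnectome]
    group: GroupGraph
    records: list
    graphs: list
    analysis_graph: object
    D: np.ndarray
    edge_classes: pd.DataFrame
    node_table: pd.DataFrame
    metrics: list[ThresholdMetrics]
    variability: pd.DataFrame


@dataclass
class PipelineResult:
    hemispheres: dict[str, HemisphereResult]
    edge_stats: pd.DataFrame
    manifest: dict


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


# ---------------------------------------------------------------------------
# cohort I/O

def write_cohort(outdir: str | Path, left: list[SubjectConnectome],
                 right: list[SubjectConnectome], truth: SyntheticTruth,
                 spec: SyntheticSpec) -> None:
    """Write a cohort in the CSV dialect the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for hemi, subjects in (("left", left), ("right", right)):
        hemi_dir = outdir / hemi
        hemi_dir.mkdir(exist_ok=True)
        roiset = subjects[0].roiset
        meta.append(roiset.table)
        for sub in subjects:
            write_connectivity_matrix(hemi_dir / f"{sub.subject_id}.csv",
                                      sub.counts, roiset)
    pd.concat(meta, ignore_index=True).to_csv(outdir / "roi_metadata.csv",
                                              index=False)
    pd.DataFrame({"name": left[0].roiset.names,
                  "waytotal": left[0].waytotal}).to_csv(
        outdir / "waytotals.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    (outdir / "spec.yaml").write_text(yaml.safe_dump(spec.to_dict()))


@_stage("read_cohort")
def load_cohort(config: PipelineConfig) -> dict[str, list[SubjectConnectome]]:
    cohort_dir = Path(config.cohort_dir)
    meta_path = Path(config.roi_metadata or cohort_dir / "roi_metadata.csv")
    if not meta_path.exists():
        raise FileNotFoundError(f"ROI metadata not found: {meta_path}")
    meta = pd.read_csv(meta_path, dtype=str)
    wt_path = Path(config.waytotals or cohort_dir / "waytotals.csv")
    waytotal_path = wt_path if wt_path.exists() else None
    cohort: dict[str, list[SubjectConnectome]] = {}
    for hemi in HEMISPHERES:
        sub_meta = meta[meta["hemisphere"] == hemi]
        roiset = RoiSet(sub_meta if len(sub_meta) else meta)
        files = sorted((cohort_dir / hemi).glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no subject matrices under "
                                    f"{cohort_dir / hemi}")
        cohort[hemi] = [
            read_connectivity_matrix(f, roiset, waytotal_path=waytotal_path,
                                     hemisphere=hemi)
            for f in files]
    left_ids = [s.subject_id for s in cohort["left"]]
    right_ids = [s.subject_id for s in cohort["right"]]
    if left_ids != right_ids:
        raise ValueError("left/right subject sets differ: "
                         f"{left_ids} vs {right_ids}")
    return cohort


# ---------------------------------------------------------------------------
# per-hemisphere analysis

@_stage("admission")
def _admission(group: GroupGraph, config: PipelineConfig, seed: int):
    graphs, records = admissibility_sweep(
        group, config.threshold_spec(), n_null=config.n_null, seed=seed)
    if not admit_graphs(records):
        raise ValueError("no thresholded graph passed the admission criteria")
    return graphs, records


@_stage("node_roles")
def _node_roles(roiset: RoiSet, graphs, records, analysis_graph):
    metrics = []
    by_threshold = {g.threshold: g for g in graphs}
    for rec in admit_graphs(records):
        g = by_threshold[rec.threshold]
        aff = rec.modularity.affiliation
        metrics.append(ThresholdMetrics(
            threshold=rec.threshold,
            participation=participation_coefficient(g.weights, aff),
            wmdz=within_module_degree_z(g.weights, aff),
            affiliation=aff))
    strength = node_strength(analysis_graph.weights)
    betweenness = node_betweenness(analysis_graph.weights)
    return node_role_table(roiset, metrics, strength, betweenness), metrics


def analyze_hemisphere(subjects: list[NormalizedConnectome],
                       config: PipelineConfig, seed: int) -> HemisphereResult:
    roiset = subjects[0].roiset
    group = aggregate_group(subjects, method=config.aggregation)
    graphs, records = _admission(group, config, seed)
    analysis_graph = select_analysis_graph(graphs, records)
    D = distance_matrix(analysis_graph, interlobar_only=True)
    edge_classes = classify_edge_percentiles(D, roiset,
                                             cutoffs=config.percentiles)
    node_table, metrics = _node_roles(roiset, graphs, records, analysis_graph)
    values = np.stack([s.interlobar_values() for s in subjects])
    variability = variability_table(values)
    return HemisphereResult(
        roiset=roiset, subjects=subjects, group=group, records=records,
        graphs=graphs, analysis_graph=analysis_graph, D=D,
        edge_classes=edge_classes, node_table=node_table, metrics=metrics,
        variability=variability)


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config)

    normalized: dict[str, list[NormalizedConnectome]] = {}
    for hemi in HEMISPHERES:
        normalized[hemi] = [
            mask_interlobar(normalize_connectome(
                s, already_normalized=config.normalized))
            for s in cohort[hemi]]

    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    results: dict[str, HemisphereResult] = {}
    for hemi, hemi_seed in zip(HEMISPHERES, seeds):
        results[hemi] = analyze_hemisphere(normalized[hemi], config,
                                           seed=int(hemi_seed % (2 ** 31)))

    left_vals = np.stack([s.interlobar_values() for s in normalized["left"]])
    right_vals = np.stack([s.interlobar_values() for s in normalized["right"]])
    edge_stats = edge_statistics(left_vals, right_vals, alpha=config.alpha)
    roiset = results["left"].roiset
    pairs = roiset.interlobar_pairs()
    edge_stats.insert(0, "parietal", [roiset.names[i] for i, _ in pairs])
    edge_stats.insert(1, "premotor", [roiset.names[j] for _, j in pairs])

    manifest = {
        "software": {"name": "pmnet", "version": __version__},
        "config": asdict(config),
        "seed": config.seed,
        "n_subjects": len(cohort["left"]),
        "n_thresholds": len(results["left"].records),
        "admitted_thresholds": {
            hemi: [r.threshold for r in admit_graphs(results[hemi].records)]
            for hemi in HEMISPHERES},
        "analysis_threshold": {
            hemi: results[hemi].analysis_graph.threshold
            for hemi in HEMISPHERES},
        "row_counts": {
            "edge_stats": int(len(edge_stats)),
            **{f"edge_classes_{h}": int(len(results[h].edge_classes))
               for h in HEMISPHERES},
            **{f"node_roles_{h}": int(len(results[h].node_table))
               for h in HEMISPHERES},
        },
        "warnings": [],
    }

    _write_outputs(outdir, results, edge_stats, manifest)
    return PipelineResult(hemispheres=results, edge_stats=edge_stats,
                          manifest=manifest)


def _cluster_matrix(variability: pd.DataFrame, roiset: RoiSet) -> pd.DataFrame:
    p_names = [roiset.names[i] for i in roiset.parietal_indices]
    f_names = [roiset.names[j] for j in roiset.premotor_indices]
    mat = pd.DataFrame("", index=p_names, columns=f_names)
    for (i, j), cluster in zip(roiset.interlobar_pairs(),
                               variability["cluster"]):
        mat.loc[roiset.names[i], roiset.names[j]] = cluster
    return mat


def _write_outputs(outdir: Path, results: dict[str, HemisphereResult],
                   edge_stats: pd.DataFrame, manifest: dict) -> None:
    for hemi, res in results.items():
        records_to_frame(res.records).to_csv(
            outdir / f"admissibility_{hemi}.csv", index=False)
        distance_frame(res.D, res.roiset).to_csv(
            outdir / f"distance_{hemi}.csv", float_format="%.17g")
        res.edge_classes.to_csv(outdir / f"edge_classes_{hemi}.csv",
                                index=False)
        res.node_table.to_csv(outdir / f"node_roles_{hemi}.csv", index=False)
        res.variability.assign(
            parietal=[res.roiset.names[i]
                      for i, _ in res.roiset.interlobar_pairs()],
            premotor=[res.roiset.names[j]
                      for _, j in res.roiset.interlobar_pairs()],
        ).to_csv(outdir / f"variability_{hemi}.csv", index=False)
        _cluster_matrix(res.variability, res.roiset).to_csv(
            outdir / f"cv_clusters_{hemi}.csv")
    edge_stats.to_csv(outdir / "edge_stats.csv", index=False)
    roiset = results["left"].roiset
    padj = pd.DataFrame(
        np.reshape(edge_stats["p_adj"].to_numpy(),
                   (roiset.n_parietal, roiset.n_premotor)),
        index=[roiset.names[i] for i in roiset.parietal_indices],
        columns=[roiset.names[j] for j in roiset.premotor_indices])
    padj.to_csv(outdir / "edge_stats_padj_matrix.csv", float_format="%.17g")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
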