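"""End-to-end pipeline: preprocess -> segment -> graph -> features -> classify.

``process_core`` turns a raw core image into nuclei, cell graphs and feature
vectors; ``train_models`` fits the subgraph SVM (22 features, top-k by
F-score) and the per-nucleus SVM (12 node features) on truth-labeled cores;
``predict_core`` labels every emitted nucleus, optionally including the
single-cell fallback; ``run_core_to_dir`` writes the full artifact set.
Everything is deterministic under a fixed config and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import io as tio
from .classify import (STROMA_LABEL, TUMOR_LABEL, ClassificationReport,
                       SvmModel, assign_truth_label, classify_subgraphs,
                       evaluate_classification, propagate_to_nuclei,
                       train_classifier)
from .features import feature_matrix, node_feature_matrix
from .graph import StructuringElement, build_cell_graph, connected_subgraphs
from .preprocess import PreprocessConfig, preprocess_core
from .segment import NucleusRecord, segment_nuclei
from .singlecell import SingleCellRuleParams, classify_single_cells
from .synthetic import GroundTruth

__all__ = [
    "PipelineConfig",
    "CoreResult",
    "process_core",
    "truth_for_records",
    "train_models",
    "predict_core",
    "run_core_to_dir",
]


@dataclass
class PipelineConfig:
    """All stage parameters.  Published constants are the defaults; the rest
    are documented free parameters."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    h_maxima: int = 10
    se_radius: int = 2
    link_intensity_threshold: float = 30.0
    top_k: int = 15
    svm_C: float = 1.0
    svm_gamma: Optional[float] = None            # None -> 1/top_k
    single_cells: bool = True
    single_cell: SingleCellRuleParams = field(default_factory=SingleCellRuleParams)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "single_cell" in d and isinstance(d["single_cell"], dict):
            d["single_cell"] = SingleCellRuleParams(**d["single_cell"])
        return cls(**d)


@dataclass
class CoreResult:
    """All intermediate artifacts of one processed core."""

    corrected: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    records: List[NucleusRecord]
    subgraphs: List[nx.Graph]
    isolated: List[NucleusRecord]
    features: pd.DataFrame
    log: Dict[str, int]

    @property
    def records_by_label(self) -> Dict[int, NucleusRecord]:
        return {r.label: r for r in self.records}


def process_core(image: np.ndarray, config: PipelineConfig | None = None,
                 background: Optional[np.ndarray] = None) -> CoreResult:
    """Preprocess, segment and graph one core image."""
    cfg = config or PipelineConfig()
    corrected, mask, log = preprocess_core(image, cfg.preprocess, background)
    labels, records = segment_nuclei(corrected, mask, h=cfg.h_maxima)
    g = build_cell_graph(records, StructuringElement(radius=cfg.se_radius),
                         cfg.link_intensity_threshold)
    subs, isolated = connected_subgraphs(g)
    feats = feature_matrix(subs)
    log["n_nuclei"] = len(records)
    log["n_edges"] = g.number_of_edges()
    log["n_subgraphs"] = len(subs)
    log["n_isolated"] = len(isolated)
    return CoreResult(corrected, mask, labels, records, subs, isolated, feats, log)


def truth_for_records(records: Sequence[NucleusRecord],
                      truth: GroundTruth) -> Dict[int, int]:
    """Ground-truth +-1 label per segmented nucleus.

    Each record takes the class of the truth nucleus it overlaps most; a
    record with no truth overlap falls back to the tumor-region-mask test at
    its centroid.
    """
    tl = truth.label_image
    out: Dict[int, int] = {}
    for rec in records:
        vals = tl[rec.coords[:, 0], rec.coords[:, 1]]
        vals = vals[vals > 0]
        if vals.size:
            best = int(np.bincount(vals).argmax())
            cls = truth.classes.get(best, "stroma")
            out[rec.label] = TUMOR_LABEL if cls == "tumor" else STROMA_LABEL
        else:
            r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
            h, w = tl.shape
            inside = 0 <= r < h and 0 <= c < w and truth.tumor_region_mask[r, c]
            out[rec.label] = TUMOR_LABEL if inside else STROMA_LABEL
    return out


def train_models(cores: Sequence[Tuple[np.ndarray, GroundTruth]],
                 config: PipelineConfig | None = None
                 ) -> Tuple[SvmModel, SvmModel, List[CoreResult]]:
    """Fit the subgraph model and the per-nucleus model on training cores.

    Returns ``(graph_model, node_model, per-core results)``.  Subgraph truth
    labels come from the majority of member centroids inside the tumor mask;
    per-nucleus truth from maximal overlap with the truth label image.
    """
    cfg = config or PipelineConfig()
    feat_frames, graph_labels = [], []
    node_frames, node_labels = [], []
    results = []
    for image, truth in cores:
        res = process_core(image, cfg)
        results.append(res)
        if not res.features.empty:
            feat_frames.append(res.features)
            graph_labels.extend(assign_truth_label(g, truth) for g in res.subgraphs)
        if res.records:
            node_frames.append(node_feature_matrix(res.records))
            per_rec = truth_for_records(res.records, truth)
            node_labels.extend(per_rec[r.label] for r in res.records)
    if not feat_frames:
        raise ValueError("no subgraphs found in the training cores")
    graph_x = pd.concat(feat_frames, ignore_index=True)
    graph_model = train_classifier(graph_x, np.asarray(graph_labels),
                                   k=cfg.top_k, C=cfg.svm_C, gamma=cfg.svm_gamma)
    node_x = pd.concat(node_frames, ignore_index=True)
    node_model = train_classifier(node_x, np.asarray(node_labels),
                                  k=node_x.shape[1], C=cfg.svm_C, gamma=cfg.svm_gamma)
    return graph_model, node_model, results


def predict_core(result: CoreResult, graph_model: SvmModel,
                 node_model: Optional[SvmModel] = None,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-nucleus predictions for one processed core.

    Subgraph predictions are propagated to member nuclei
    (``source='graph'``); with ``config.single_cells`` the isolated nuclei
    are labeled by the rule/SVM fallback (``source`` = the rule applied).
    """
    cfg = config or PipelineConfig()
    rows = []
    preds = classify_subgraphs(graph_model, result.features)
    per_nucleus = propagate_to_nuclei(result.subgraphs, preds)
    for lab, p in per_nucleus.items():
        rows.append({"label": lab, "pred": p, "source": "graph"})
    if cfg.single_cells and result.isolated:
        sc = classify_single_cells(result.isolated, cfg.single_cell, node_model)
        for lab, r in sc.iterrows():
            rows.append({"label": int(lab), "pred": int(r["pred"]),
                         "source": str(r["rule_applied"])})
    df = pd.DataFrame(rows, columns=["label", "pred", "source"])
    return df.sort_values("label", ignore_index=True)


def run_core_to_dir(image: np.ndarray, config: PipelineConfig,
                    out_dir, graph_model: Optional[SvmModel] = None,
                    node_model: Optional[SvmModel] = None,
                    truth: Optional[GroundTruth] = None,
                    stop_after: Optional[str] = None) -> Dict[str, str]:
    """Run the pipeline on one core and write every artifact to ``out_dir``.

    ``stop_after`` in {'preprocess', 'segment', 'graph', 'features'} gates
    later stages.  Returns a manifest mapping artifact names to file names
    (also written as ``manifest.json`` with content hashes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["preprocess", "segment", "graph", "features", "classify"]
    stop_idx = stages.index(stop_after) if stop_after else len(stages) - 1

    manifest: Dict[str, str] = {}

    def emit(name: str, fname: str):
        manifest[name] = fname

    corrected, mask, log = preprocess_core(image, config.preprocess)
    tio.write_image(out / "corrected.tif", corrected)
    tio.write_mask(out / "mask.tif", mask)
    emit("corrected", "corrected.tif")
    emit("mask", "mask.tif")
    result = None
    if stop_idx >= 1:
        labels, records = segment_nuclei(corrected, mask, h=config.h_maxima)
        tio.write_label_image(out / "labels.tif", labels)
        tio.write_records(out / "nuclei.csv", records)
        emit("labels", "labels.tif")
        emit("nuclei", "nuclei.csv")
    if stop_idx >= 2:
        g = build_cell_graph(records, StructuringElement(radius=config.se_radius),
                             config.link_intensity_threshold)
        subs, isolated = connected_subgraphs(g)
        edges = pd.DataFrame(sorted((min(u, v), max(u, v)) for u, v in g.edges),
                             columns=["node_label_a", "node_label_b"])
        edges.to_csv(out / "edges.csv", index=False)
        emit("edges", "edges.csv")
    if stop_idx >= 3:
        feats = feature_matrix(subs)
        feats.to_csv(out / "features.csv")
        emit("features", "features.csv")
    if stop_idx >= 4:
        result = CoreResult(corrected, mask, labels, records, subs, isolated,
                            feats, log)
        if graph_model is None:
            raise ValueError("classification requires a trained subgraph model")
        pred = predict_core(result, graph_model, node_model, config)
        pred.to_csv(out / "predictions.csv", index=False)
        emit("predictions", "predictions.csv")
        tio.write_overlay(out / "overlay.png", labels,
                          dict(zip(pred["label"], pred["pred"])))
        emit("overlay", "overlay.png")
        if truth is not None:
            per_rec = truth_for_records(records, truth)
            table = pred.assign(core_id=0,
                                truth=[per_rec[l] for l in pred["label"]])
            report = evaluate_classification(table)
            tio.write_json(out / "report.json", report.as_dict())
            emit("report", "report.json")
    log_obj = {"stages": stages[:stop_idx + 1], "log": log}
    tio.write_json(out / "run_log.json", log_obj)
    emit("run_log", "run_log.json")

    hashed = {}
    for name, fname in sorted(manifest.items()):
        digest = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        hashed[name] = {"file": fname, "sha256": digest}
    tio.write_json(out / "manifest.json", hashed)
    return manifest
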