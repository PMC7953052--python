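"""One-shot pipeline: fuse -> coarsen -> embed -> refine -> cross-validate.

``PipelineConfig`` gathers every stage parameter with the reference defaults,
can be loaded from a YAML mapping of the same field names, and is validated
before any stage runs. ``run_pipeline`` persists the intermediate artifacts
as plain text, writes the per-fold report CSV and a JSON manifest (full
configuration, seeds, achieved coarsening depth, per-stage graph sizes) from
which the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .graph import (
    AttributeMatrix,
    Graph,
    write_edge_list,
)
from .linkpred import PAIR_OPERATORS, MetricsReport, cross_validate
from .model import MultilevelEmbedding

log = logging.getLogger("lppi")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    beta: float = 0.1
    knn_k: int = 10
    level: int = 1
    t: int = 16
    gs_iters: int = 2
    sigma: float = 1.0
    method: str = "node2vec"
    dim: int = 128
    num_walks: int = 10
    walk_length: int = 80
    p: float = 1.0
    q: float = 0.5
    window: int = 10
    epochs: int = 5
    neg_samples: int = 5
    power: int = 2
    operator: str = "hadamard"
    folds: int = 5
    inductive: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if self.method not in ("deepwalk", "node2vec"):
            raise ParameterError(f"unknown method {self.method!r}")
        if self.operator not in PAIR_OPERATORS:
            raise ParameterError(f"unknown operator {self.operator!r}")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if min(self.knn_k, self.level + 1, self.t, self.gs_iters, self.dim,
               self.num_walks, self.walk_length, self.window) < 1:
            raise ParameterError("counts must be >= 1 (level >= 0)")
        if self.p <= 0 or self.q <= 0 or self.sigma <= 0:
            raise ParameterError("p, q and sigma must be > 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(
                f"unknown config keys: {', '.join(sorted(unknown))}"
            )
        raw.update(overrides)
        return cls(**raw)


def run_pipeline(
    cfg: PipelineConfig,
    graph: Graph,
    attributes: AttributeMatrix | None = None,
    compartments: dict[int, str] | None = None,
    out_dir: str | Path | None = None,
) -> MetricsReport:
    """Run every stage in order and cross-validate link prediction."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info(
        "[input] %d nodes, %d edges%s",
        graph.n_nodes,
        graph.n_edges,
        "" if attributes is None else f", {attributes.n_features} features",
    )

    embedder_params = dict(
        beta=cfg.beta,
        knn_k=cfg.knn_k,
        level=cfg.level,
        t=cfg.t,
        gs_iters=cfg.gs_iters,
        sigma=cfg.sigma,
        method=cfg.method,
        num_walks=cfg.num_walks,
        walk_length=cfg.walk_length,
        p=cfg.p,
        q=cfg.q,
        dim=cfg.dim,
        window=cfg.window,
        epochs=cfg.epochs,
        neg_samples=cfg.neg_samples,
        power=cfg.power,
    )

    stage_sizes: list[dict] = []

    def emb_builder(g: Graph) -> np.ndarray:
        est = MultilevelEmbedding(random_state=cfg.seed, **embedder_params)
        emb = est.fit_transform(g, attributes)
        fused = est.fused_graph_
        log.info("[fuse] %d nodes, %d edges", fused.n_nodes, fused.n_edges)
        for i, lvl in enumerate(est.hierarchy_.levels):
            log.info(
                "[coarsen] level %d: %d nodes, %d edges",
                i,
                lvl.n_nodes,
                lvl.n_edges,
            )
            stage_sizes.append(
                {"level": i, "nodes": lvl.n_nodes, "edges": lvl.n_edges}
            )
        log.info(
            "[embed] coarsest level %d embedded at dim %d (%s)",
            est.achieved_level_,
            cfg.dim,
            cfg.method,
        )
        emb_builder.last_estimator = est
        if out is not None:
            for i, lvl in enumerate(est.hierarchy_.levels[1:], start=1):
                write_edge_list(lvl, out / f"level{i}.tsv")
            for i, h in enumerate(est.hierarchy_.mappings, start=1):
                np.savetxt(
                    out / f"mapping{i}.tsv",
                    np.column_stack(
                        [np.arange(h.n_fine), h.assignment]
                    ),
                    fmt="%d",
                    delimiter="\t",
                    header="fine\tcoarse",
                )
            np.savetxt(out / "embedding.tsv", emb, delimiter="\t")
        return emb

    report = cross_validate(
        graph,
        emb_builder,
        comp=compartments,
        folds=cfg.folds,
        seed=cfg.seed,
        operator=cfg.operator,
        inductive=cfg.inductive,
    )
    log.info(
        "[predict] mean Acc %.4f, AUC %.4f over %d folds",
        report.means["Acc"],
        report.means["AUC"],
        cfg.folds,
    )

    if out is not None:
        report.to_frame().to_csv(out / "report.csv", index=False)
        est = getattr(emb_builder, "last_estimator", None)
        manifest = {
            "config": dataclasses.asdict(cfg),
            "n_nodes": graph.n_nodes,
            "n_edges": graph.n_edges,
            "achieved_level": None if est is None else est.achieved_level_,
            "levels": stage_sizes,
            "mean_metrics": {
                k: float(v)
                for k, v in report.means.items()
                if k != "fold"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
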