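"""End-to-end pipeline: expression matrices -> networks -> comparison.

``single`` mode builds one network per experiment (S-GCN path); ``multi``
mode first merges all experiments into one matrix and builds a single
network (M-GCN path).  Every stage writes its artifact into the run
directory together with a JSON manifest (parameters, input hashes,
versions), and a global seed expands into per-stage sub-seeds through a
counter scheme so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import cross_tab, kmeans_bic, pca
from .expression import filter_expression, merge_experiments, read_expression_tsv
from .graph_metrics import AnnotationTable, characterize, read_annotations_tsv
from .network_io import write_curve_csv, write_edgelist_tsv, write_sif
from .similarity import similarity_matrix
from .thresholding import adjacency, select_threshold, threshold_curve

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression_paths: list
    annotation_path: str | None = None
    measure: str = "ncmi"
    bins: int | str = "auto"
    sample_min: float = 0.5
    gene_min: float = 0.75
    attack_fraction: float = 0.05
    retained_pcs: int = 3
    k_max: int = 10
    n_starts: int = 100
    seed: int | None = None
    labels: list | None = None
    groups: list | None = None

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_seed(seed: int | None, stage: int) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence((seed, stage)).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, mode: str, out_dir) -> Path:
    """Run the full construction-and-comparison pipeline.

    Returns the run directory.  Stage failures raise with the failing stage
    named; artifacts written before the failure are preserved.
    """
    if mode not in ("single", "multi"):
        raise ValueError("mode must be 'single' or 'multi'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    manifest = {
        "version": __version__,
        "mode": mode,
        "config": asdict(config),
        "inputs": {str(p): _sha256(p) for p in config.expression_paths},
        "stages": [],
    }

    def log(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        with open(log_path, "a") as fh:
            fh.write(f"{stage}\t{json.dumps(info, default=str)}\n")

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:
            log(stage, error=str(exc))
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    labels = config.labels or [f"exp{i + 1}" for i in
                               range(len(config.expression_paths))]
    matrices = run_stage("read", lambda: [read_expression_tsv(p)
                                          for p in config.expression_paths])
    annotations = (read_annotations_tsv(config.annotation_path)
                   if config.annotation_path else AnnotationTable({}, {}, {}))

    if mode == "multi" and len(matrices) > 1:
        merged = run_stage("merge", lambda: merge_experiments(matrices, labels))
        units = [("merged", merged)]
    else:
        units = list(zip(labels, matrices))

    rows, sizes = [], []
    for label, E in units:
        common = E.index
        Ef = run_stage(f"filter[{label}]",
                       lambda E=E, c=common: filter_expression(
                           E, c, config.sample_min, config.gene_min))
        kwargs = {"bins": config.bins} if config.measure == "ncmi" else {}
        S = run_stage(f"similarity[{label}]",
                      lambda Ef=Ef: similarity_matrix(Ef, config.measure, **kwargs))
        curve = run_stage(f"threshold[{label}]", lambda S=S: threshold_curve(S))
        write_curve_csv(curve, out / f"{label}.curve.csv")
        tau = run_stage(f"select[{label}]", lambda c=curve: select_threshold(c))
        net = adjacency(S, tau).subgraph(adjacency(S, tau).degrees() > 0)
        write_sif(net, out / f"{label}.sif")
        write_edgelist_tsv(net, out / f"{label}.edges.tsv")
        row = run_stage(f"characterize[{label}]",
                        lambda net=net, label=label, tau=tau: characterize(
                            net, annotations, config.attack_fraction,
                            metadata={"network_id": label, "tau_star": tau,
                                      "n_nodes": net.n_nodes,
                                      "n_edges": net.n_edges}))
        rows.append(row)
        sizes.append(net.n_nodes)
        log(f"network[{label}]", tau_star=tau, n_nodes=net.n_nodes,
            n_edges=net.n_edges)

    charac = pd.DataFrame(rows)
    charac.to_csv(out / "characterization.csv", index=False)

    if len(rows) >= 3:
        from .graph_metrics import VARIABLE_NAMES

        T = charac[VARIABLE_NAMES]
        pres = run_stage("pca", lambda: pca(T))
        (out / "pca.json").write_text(json.dumps({
            "eigenvalues": pres.eigenvalues.tolist(),
            "explained_variance_pct": pres.explained_variance_pct.tolist(),
            "variable_correlations": pres.variable_correlations.to_dict(),
        }, indent=2))
        pres.scores.to_csv(out / "scores.csv", index=False)
        n_pcs = min(config.retained_pcs, pres.scores.shape[1])
        k_max = min(config.k_max, len(rows) - 1)
        if k_max >= 1:
            cres = run_stage("kmeans", lambda: kmeans_bic(
                pres.scores.iloc[:, :n_pcs], k_max, config.n_starts,
                _stage_seed(config.seed, 7)))
            (out / "clusters.json").write_text(json.dumps({
                "bic": {int(k): float(v) for k, v in cres.bic.items()},
                "chosen_k": cres.chosen_k,
                "chosen_k_min_bic": cres.chosen_k_min_bic,
                "assignments": cres.assignments.tolist(),
            }, indent=2))
            if config.groups:
                ct = cross_tab(cres.assignments, config.groups)
                ct.to_csv(out / "cross_tab.csv")
            log("kmeans", chosen_k=cres.chosen_k)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
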