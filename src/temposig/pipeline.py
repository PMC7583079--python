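"""End-to-end pipeline: collapse/filter -> preprocess -> cluster -> jackstraw
-> PIP selection -> enrichment, with a self-describing artifact directory.

Every run writes each intermediate as TSV/JSON, the resolved configuration,
and a manifest recording stage-by-stage variable counts (the analysis
"funnel") plus file checksums, so a run is reproducible bitwise from its
output directory and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import data as _data
from . import enrich as _enrich
from . import jackstraw as _jackstraw
from . import preprocess as _preprocess
from .errors import ConfigError, ParameterError, PipelineError

logger = logging.getLogger("temposig")

DEFAULT_CONFIG = {
    "io.input": None,
    "io.replicates": None,
    "io.annotations_variable_protein": None,
    "io.annotations_protein_function": None,
    "io.outdir": "temposig_run",
    "data.log_base": 2.0,
    "data.fold_change": 1.2,          # null disables the pre-filter
    "preprocess.method": "spline",     # spline | pca
    "preprocess.dof": "cv.global",     # cv.global | cv.per_variable | number
    "preprocess.dof_grid": [2, 3, 4, 5],
    "preprocess.rank": "auto",
    "preprocess.impute": "svdimpute",  # svdimpute | nipals
    "preprocess.fallback_rank": 2,
    "preprocess.var_fraction": 0.9,
    "cluster.method": "kmeans",        # kmeans | hierarchical
    "cluster.K": 5,
    "cluster.K_range": None,           # e.g. [2,...,8] -> also write a scree table
    "cluster.restarts": 20,
    "cluster.distance": "euclidean",
    "cluster.linkage": "average",
    "cluster.standardize": False,
    "jackstraw.s": None,               # default ceil(0.1 m)
    "jackstraw.B": None,               # default so s*B >= 10000
    "jackstraw.pip_threshold": 0.8,
    "enrich.universe": "selected",
    "seed": 20200603,
}


class RunConfig(dict):
    """Flat key-value configuration; unknown keys are rejected."""

    def __init__(self, overrides=None):
        super().__init__(DEFAULT_CONFIG)
        for key, value in (overrides or {}).items():
            if key not in DEFAULT_CONFIG:
                raise ConfigError(f"unknown configuration key: {key!r}")
            self[key] = value

    @classmethod
    def from_yaml(cls, path, overrides=None) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must hold a flat key-value mapping")
        merged = dict(loaded)
        merged.update(overrides or {})  # CLI flags win
        return cls(merged)

    def write(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def run_pipeline(config: RunConfig, log_level=logging.INFO) -> dict:
    """Execute the full pipeline described by `config`.

    Returns the run manifest (also written to ``<outdir>/manifest.json``).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config["io.outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(log_level)
    seed = int(config["seed"])
    manifest = {"stages": [], "files": {}, "seed": seed}

    def record(stage, n_in, n_out, **extra):
        entry = {"stage": stage, "n_in": n_in, "n_out": n_out, **extra}
        manifest["stages"].append(entry)
        logger.info("stage %s: %d -> %d %s", stage, n_in, n_out, extra or "")

    def emit(name, writer):
        path = outdir / name
        writer(path)
        manifest["files"][name] = _sha256(path)
        return path

    try:
        stage = "load"
        if config["io.replicates"]:
            table = _data.read_replicate_table(config["io.replicates"])
            matrix = _data.collapse_replicates(
                table, log_base=float(config["data.log_base"]))
        elif config["io.input"]:
            matrix = _data.read_temporal_matrix(
                config["io.input"],
                meta={"log_base": str(config["data.log_base"])})
        else:
            raise ParameterError("config must set io.input or io.replicates")
        record(stage, matrix.n_variables, matrix.n_variables)

        stage = "fold_change_filter"
        if config["data.fold_change"]:
            n_in = matrix.n_variables
            matrix, report = _data.fold_change_filter(
                matrix, float(config["data.fold_change"]))
            emit("filter_report.json",
                 lambda p: report.write_json(p))
            emit("filtered_matrix.tsv",
                 lambda p: _data.write_temporal_matrix(matrix, p))
            record(stage, n_in, matrix.n_variables)

        stage = "preprocess"
        if config["preprocess.method"] == "spline":
            dof = config["preprocess.dof"]
            if not isinstance(dof, str):
                dof = float(dof)
            pre, qc = _preprocess.preprocess_spline(
                matrix, dof=dof, dof_grid=config["preprocess.dof_grid"],
                fallback_rank=int(config["preprocess.fallback_rank"]),
                seed=seed)
        elif config["preprocess.method"] == "pca":
            r = config["preprocess.rank"]
            r = r if r == "auto" else int(r)
            pre, qc = _preprocess.preprocess_pca(
                matrix, r=r, impute=config["preprocess.impute"],
                var_fraction=float(config["preprocess.var_fraction"]))
        else:
            raise ParameterError(
                f"unknown preprocess.method: {config['preprocess.method']!r}")
        emit("preprocessed.tsv", lambda p: _data.write_temporal_matrix(
            pre.as_temporal_matrix(), p))
        emit("preprocess.json", lambda p: _write_json(
            {"method": pre.method, "params": pre.params, "qc": qc.to_dict()},
            p))
        record(stage, matrix.n_variables, matrix.n_variables,
               method=pre.method, median_pearson=qc.median_pearson,
               median_msd=qc.median_msd)

        stage = "scree"
        if config["cluster.K_range"]:
            scree = _cluster.wcss_scree(
                pre.values, config["cluster.K_range"],
                restarts=int(config["cluster.restarts"]), seed=seed)
            emit("scree.tsv", lambda p: pd.DataFrame(scree.rows).to_csv(
                p, sep="\t", index=False))
            record(stage, matrix.n_variables, matrix.n_variables,
                   elbow_k=_cluster.elbow_k(scree)
                   if len(scree.rows) >= 3 else None)

        stage = "cluster"
        K = int(config["cluster.K"])
        if config["cluster.method"] == "kmeans":
            clustering = _cluster.kmeans_cluster(
                pre.values, K, restarts=int(config["cluster.restarts"]),
                seed=seed, standardize=bool(config["cluster.standardize"]))
        elif config["cluster.method"] == "hierarchical":
            clustering = _cluster.hierarchical_cluster(
                pre.values, K, distance=config["cluster.distance"],
                linkage=config["cluster.linkage"])
        else:
            raise ParameterError(
                f"unknown cluster.method: {config['cluster.method']!r}")
        emit("cluster_labels.tsv", lambda p: pd.DataFrame(
            {"variable_id": matrix.variable_ids,
             "cluster": clustering.labels}).to_csv(p, sep="\t", index=False))
        emit("cluster_centers.tsv", lambda p: pd.DataFrame(
            clustering.centers, columns=matrix.time_points,
            index=pd.Index(range(1, clustering.K + 1), name="cluster"),
        ).to_csv(p, sep="\t"))
        emit("cluster.json", lambda p: _write_json(clustering.to_dict(), p))
        record(stage, matrix.n_variables, matrix.n_variables,
               K=clustering.K, wcss=clustering.wcss)

        stage = "jackstraw"
        js = _jackstraw.jackstraw_membership(
            matrix, pre, clustering,
            s=config["jackstraw.s"] and int(config["jackstraw.s"]),
            B=config["jackstraw.B"] and int(config["jackstraw.B"]),
            seed=seed)
        emit("jackstraw.tsv", lambda p: pd.DataFrame(
            {"variable_id": matrix.variable_ids,
             "cluster": clustering.labels, "F": js.observed_f,
             "p": js.p_values, "q": js.q_values, "lfdr": js.lfdr,
             "pip": js.pip}).to_csv(p, sep="\t", index=False))
        emit("jackstraw.json", lambda p: _write_json(js.to_dict(), p))
        record(stage, matrix.n_variables, matrix.n_variables,
               s=js.s, B=js.B, pi0=js.pi0)

        stage = "pip_filter"
        selection = _jackstraw.pip_filter(
            js, float(config["jackstraw.pip_threshold"]))
        emit("selection.json", lambda p: _write_json(selection.to_dict(), p))
        record(stage, selection.n_input, selection.n_retained,
               pip_threshold=selection.pip_threshold)

        stage = "enrich"
        if (config["io.annotations_variable_protein"]
                and config["io.annotations_protein_function"]):
            annot = _enrich.read_annotation_map(
                config["io.annotations_variable_protein"],
                config["io.annotations_protein_function"])
            bubble = _enrich.build_bubble_table(
                selection, clustering, annot,
                variable_ids=matrix.variable_ids,
                universe=config["enrich.universe"])
            emit("bubble_table.tsv", lambda p: bubble.to_csv(
                p, sep="\t", index=False))
            record(stage, selection.n_retained, len(bubble),
                   n_significant=int(bubble["significant"].sum())
                   if len(bubble) else 0)
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    config.write(outdir / "resolved_config.yaml")
    manifest["files"]["resolved_config.yaml"] = _sha256(
        outdir / "resolved_config.yaml")
    _write_json(manifest, outdir / "manifest.json")
    return manifest
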