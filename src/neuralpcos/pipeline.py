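"""End-to-end pipeline: DEG screen -> enrichment -> RF selection -> network
scoring -> ROC evaluation, with a manifest recording seeds, parameters, and
input checksums so any stage can be re-run in isolation.

One global seed expands deterministically into per-stage seeds by hashing the
stage name, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .datatypes import ConfigurationError, DataError, ExpressionMatrix
from .io import read_expression, read_gmt, write_expression
from .preprocess import to_log2, combat_adjust
from .deg import deg_gene_signs, filter_degs, moderated_t
from .enrich import enrich, prune_redundant
from .rf import select_genes
from .ann import build_score_model
from .evaluate import EC_PCOS, GC_PCOS, ComparatorGeneSet, compare_models


@dataclass
class PipelineConfig:
    """All tunables of the six pipeline stages.

    Defaults are the screening constants of the reference procedure:
    p < 0.01 with |logFC| > 0.26 and a bottom-25% expression filter for DEGs,
    adjusted p < 0.01 with 75% overlap pruning for enrichment, mtry looped to
    2000 and ntree to 3000 with a Gini-importance threshold of 0.15 for the
    forest, and a 3-unit hidden layer for the network.
    """

    train_expr: str = ""
    train_samples: str = ""
    validation_expr: str = ""
    validation_samples: str = ""
    gmt: str = ""
    scale: str = "log2"
    combat: str = "off"  # off | parametric | nonparametric
    p_cut: float = 0.01
    lfc_cut: float = 0.26
    low_expr_quantile: float = 0.25
    adj_p_cut: float = 0.01
    overlap_frac: float = 0.75
    mtry_max: int = 2000
    ntree_probe: int = 500
    ntree_max: int = 3000
    stability_eps: float = 0.005
    gini_threshold: float = 0.15
    n_hidden: int = 3
    max_genes: int | None = None
    use_builtin_comparators: bool = False
    seed: int = 0
    out_dir: str = "neuralpcos_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load(expr: str, samples: str, scale: str, combat: str) -> ExpressionMatrix:
    m = read_expression(expr, samples, scale=scale)
    m = to_log2(m)
    if combat != "off":
        m = combat_adjust(m, parametric=(combat == "parametric"))
    return m


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage outputs are TSV/JSON files with headers; ``manifest.json`` records
    versions, seeds, parameter values, and input checksums. A stage failure
    raises with the stage named; outputs of completed stages are retained.
    """
    for field_name in ("train_expr", "train_samples", "validation_expr", "validation_samples"):
        path = getattr(cfg, field_name)
        if not path or not Path(path).exists():
            raise ConfigurationError(f"config field {field_name!r}: missing input path {path!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stage_seeds": {},
        "parameters": asdict(cfg),
        "inputs": {
            name: {"path": getattr(cfg, name), "sha256_16": _checksum(getattr(cfg, name))}
            for name in ("train_expr", "train_samples", "validation_expr", "validation_samples")
        },
        "stages": [],
    }
    if cfg.gmt:
        manifest["inputs"]["gmt"] = {"path": cfg.gmt, "sha256_16": _checksum(cfg.gmt)}

    def _run_stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "status": "ok"})
        return result

    # stage 1: load + preprocess + DEG screen
    train = _run_stage("preprocess", lambda: _load(cfg.train_expr, cfg.train_samples, cfg.scale, cfg.combat))
    write_expression(train, out / "train_preprocessed")

    def _degs():
        table = filter_degs(
            moderated_t(train),
            p_cut=cfg.p_cut,
            lfc_cut=cfg.lfc_cut,
            low_expr_quantile=cfg.low_expr_quantile,
        )
        table.to_csv(out / "deg_table.tsv", sep="\t", index_label="gene_id")
        return table

    deg_table = _run_stage("deg_screen", _degs)
    deg_signs = deg_gene_signs(deg_table)
    manifest["deg_counts"] = {
        k: deg_table.attrs[k]
        for k in ("n_up_prefilter", "n_down_prefilter", "n_pass_p_lfc", "n_up", "n_down", "n_degs")
    }
    if not deg_signs:
        raise RuntimeError("pipeline stage 'deg_screen' produced no DEGs; nothing to select from")

    # stage 2: enrichment (optional, needs an annotation)
    if cfg.gmt:
        def _enrich():
            annotation = read_gmt(cfg.gmt)
            table = enrich(deg_signs, annotation, universe=train.gene_ids)
            table = prune_redundant(table, overlap_frac=cfg.overlap_frac, adj_p_cut=cfg.adj_p_cut)
            table.to_csv(out / "enrichment.tsv", sep="\t", index_label="term_id")
            return table

        _run_stage("enrichment", _enrich)

    # stage 3: random-forest selection on the DEG matrix
    deg_genes = list(deg_signs)
    X = train.values.loc[deg_genes].T  # samples x genes
    y = train.classes

    def _rf():
        sel = select_genes(
            X,
            y,
            mtry_max=cfg.mtry_max,
            ntree_probe=cfg.ntree_probe,
            ntree_max=cfg.ntree_max,
            stability_eps=cfg.stability_eps,
            gini_threshold=cfg.gini_threshold,
            seed=stage_seed(cfg.seed, "rf_select"),
        )
        sel.importance.to_csv(out / "rf_importance.tsv", sep="\t", index_label="gene_id")
        pd.DataFrame(sel.mtry_sweep, columns=["mtry", "oob_error"]).to_csv(
            out / "rf_mtry_sweep.tsv", sep="\t", index=False
        )
        pd.DataFrame(sel.ntree_sweep, columns=["ntree", "oob_error"]).to_csv(
            out / "rf_ntree_sweep.tsv", sep="\t", index=False
        )
        return sel

    selection = _run_stage("rf_select", _rf)
    manifest["rf"] = {
        "chosen_mtry": selection.chosen_mtry,
        "chosen_ntree": selection.chosen_ntree,
        "n_selected": len(selection.selected_genes),
        "selected_genes": selection.selected_genes,
    }
    if not selection.selected_genes:
        raise RuntimeError("pipeline stage 'rf_select' selected no genes at the Gini threshold")

    # stage 4+5: network training and score model
    def _train():
        sm = build_score_model(
            train,
            selection.selected_genes,
            seed=stage_seed(cfg.seed, "ann_score"),
            n_hidden=cfg.n_hidden,
            max_genes=cfg.max_genes,
        )
        sm.to_json(out / "score_model.json")
        pd.DataFrame({"gene_id": sm.gene_ids, "weight": sm.weights}).to_csv(
            out / "gene_weights.tsv", sep="\t", index=False
        )
        return sm

    score_model = _run_stage("train_score", _train)

    # stage 6: validation
    def _evaluate():
        validation = _load(cfg.validation_expr, cfg.validation_samples, cfg.scale, "off")
        comparators: list[ComparatorGeneSet] = []
        if cfg.use_builtin_comparators:
            comparators = [EC_PCOS, GC_PCOS]
        results = compare_models(validation, score_model, comparators)
        summary = [r.summary() for r in results]
        (out / "roc_summary.json").write_text(json.dumps(summary, indent=2))
        for r in results:
            r.points.to_csv(out / f"roc_{r.model_name}.tsv", sep="\t", index=False)
        return results

    roc_results = _run_stage("evaluate", _evaluate)
    manifest["evaluation"] = [r.summary() for r in roc_results]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
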