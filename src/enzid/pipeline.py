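"""End-to-end workflow: encode -> rank -> select -> tune -> CV -> evaluate.

A :class:`RunConfig` captures every knob (paths, encoding, selection, SVM
grid, CV, seed) in a JSON-serializable form; a saved config re-executes to
identical results on identical inputs, because all randomness flows from its
single seed.  Every output file carries the tool version and a hash of the
config that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .classifier import (
    COARSE_LOG2C_GRID,
    COARSE_LOG2GAMMA_GRID,
    SVMConfig,
    cross_validate,
    grid_search,
    save_model,
    train,
)
from .encoding import EncodingSpec, encode_dataset
from .evaluation import plot_roc, roc_auc
from .selection import incremental_selection
from .sequence_io import load_labeled_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable settings for one pipeline run."""

    pos_path: str
    neg_path: str
    out_dir: str
    k: int = 3
    max_m: int = 30
    convention: str = "paper"
    n_folds: int = 6
    seed: int = 0
    stratified: bool = True
    fold_safe: bool = False
    on_invalid: str = "drop"
    # fixed SVM config (used when retune is False, and for fold-safe mode)
    c: float = 1.0
    gamma: float = 1.0
    # grid retuning (per subset size and for the final model)
    retune: bool = True
    log2c_grid: list[float] = field(
        default_factory=lambda: [float(a) for a in COARSE_LOG2C_GRID]
    )
    log2gamma_grid: list[float] = field(
        default_factory=lambda: [float(b) for b in COARSE_LOG2GAMMA_GRID]
    )
    plot: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    best_features: list[str]
    best_m: int
    svm_config: SVMConfig
    acc: float  # pooled CV accuracy, percent
    sp_paper: float
    se_paper: float
    auc: float
    outputs: dict[str, Path]


def _header(cfg: RunConfig) -> str:
    return f"enzid v{__version__} config_hash={cfg.config_hash}"


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full workflow and write all artifacts under ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _header(cfg)

    log.info("loading dataset: %s / %s", cfg.pos_path, cfg.neg_path)
    dataset = load_labeled_dataset(cfg.pos_path, cfg.neg_path, on_invalid=cfg.on_invalid)
    dataset.require_both_classes()
    log.info("loaded %d positives, %d negatives", dataset.n_pos, dataset.n_neg)

    log.info(
        "incremental selection: k=%d, max_m=%d, %d-fold CV, seed=%d",
        cfg.k, cfg.max_m, cfg.n_folds, cfg.seed,
    )
    sel = incremental_selection(
        dataset,
        k=cfg.k,
        max_m=cfg.max_m,
        convention=cfg.convention,
        n_folds=cfg.n_folds,
        seed=cfg.seed,
        stratified=cfg.stratified,
        svm=SVMConfig(cfg.c, cfg.gamma),
        log2c_grid=cfg.log2c_grid if cfg.retune and not cfg.fold_safe else None,
        log2gamma_grid=cfg.log2gamma_grid if cfg.retune and not cfg.fold_safe else None,
        fold_safe=cfg.fold_safe,
    )
    log.info("best subset: AAC + top %d pairs (CV acc %.4f)", sel.best_m, sel.best_accuracy)

    spec = EncodingSpec(
        include_aac=True,
        convention=cfg.convention,
        subset=tuple(sel.best_pairs),
    )
    fm = encode_dataset(dataset, spec)

    if cfg.retune:
        gs = grid_search(
            fm, log2c_grid=cfg.log2c_grid, log2gamma_grid=cfg.log2gamma_grid,
            n_folds=cfg.n_folds, seed=cfg.seed, stratified=cfg.stratified,
        )
        best_cfg = gs.best
        grid_table = gs.table
        log.info(
            "tuned c=2^%g=%.4f, gamma=2^%g=%.4f",
            gs.best_log2[0], best_cfg.c, gs.best_log2[1], best_cfg.gamma,
        )
    else:
        best_cfg = SVMConfig(cfg.c, cfg.gamma)
        grid_table = None

    cv = cross_validate(
        fm, config=best_cfg, n_folds=cfg.n_folds, seed=cfg.seed,
        stratified=cfg.stratified,
    )
    roc = roc_auc(fm.labels, cv.scores)
    log.info(
        "final %d-fold CV: ACC %.4f%%, SP %.4f, SE %.4f, AUC %.4f",
        cfg.n_folds, cv.metric_set.acc, cv.metric_set.sp_paper,
        cv.metric_set.se_paper, roc.auc,
    )

    model = train(fm, config=best_cfg)

    outputs: dict[str, Path] = {}

    outputs["fscores"] = out / "fscores.tsv"
    sel.fscores.to_tsv(outputs["fscores"], header_comment=hdr)

    outputs["curve"] = out / "selection_curve.tsv"
    with open(outputs["curve"], "w") as fh:
        fh.write(f"# {hdr}\n")
        sel.curve.to_csv(fh, sep="\t", index=False)

    outputs["best_features"] = out / "best_features.txt"
    with open(outputs["best_features"], "w") as fh:
        fh.write(f"# {hdr}\n")
        fh.write("\n".join(sel.best_features) + "\n")

    if grid_table is not None:
        outputs["grid"] = out / "grid.tsv"
        with open(outputs["grid"], "w") as fh:
            fh.write(f"# {hdr}\n")
            grid_table.to_csv(fh, sep="\t", index=False)

    outputs["metrics"] = out / "metrics.json"
    payload = {
        "tool": {"name": "enzid", "version": __version__, "config_hash": cfg.config_hash},
        "n_pos": dataset.n_pos,
        "n_neg": dataset.n_neg,
        "k": cfg.k,
        "best_m": sel.best_m,
        "n_features": len(sel.best_features),
        "svm": {"c": best_cfg.c, "gamma": best_cfg.gamma},
        "cv": {"n_folds": cfg.n_folds, "seed": cfg.seed, "stratified": cfg.stratified},
        "confusion": {
            "tp": cv.pooled.tp, "tn": cv.pooled.tn,
            "fp": cv.pooled.fp, "fn": cv.pooled.fn,
        },
        "metrics": cv.metric_set.to_dict(),
        "auc": roc.auc,
    }
    with open(outputs["metrics"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")

    outputs["roc"] = out / "roc.tsv"
    with open(outputs["roc"], "w") as fh:
        fh.write(f"# {hdr}\nfpr\ttpr\n")
        for x, t in zip(roc.fpr, roc.tpr):
            fh.write(f"{x:.6g}\t{t:.6g}\n")
    if cfg.plot:
        outputs["roc_plot"] = out / "roc.png"
        plot_roc(roc, outputs["roc_plot"])

    outputs["model"] = out / "model.joblib"
    save_model(
        outputs["model"], model, best_cfg, spec,
        meta={"version": __version__, "config_hash": cfg.config_hash},
    )

    outputs["run_config"] = out / "run_config.json"
    with open(outputs["run_config"], "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        config=cfg,
        best_features=sel.best_features,
        best_m=sel.best_m,
        svm_config=best_cfg,
        acc=cv.metric_set.acc,
        sp_paper=cv.metric_set.sp_paper,
        se_paper=cv.metric_set.se_paper,
        auc=roc.auc,
        outputs=outputs,
    )
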