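"""End-to-end orchestration: simulate/read -> matrix -> split -> balance ->
normalize -> train -> evaluate -> cross-validate.

Stage order follows the method: the class balancer runs on the training
portion only, then z-normalization statistics are fitted on the balanced
training rows and reused for the test rows.  Cross-validation partitions the
training portion only (the test portion stays held out); balancing and
normalization are re-fitted inside each fold to keep folds leak-free.

All randomness flows from one master seed, split deterministically into
per-stage seeds that are recorded in the run manifest, so a saved manifest
re-executes to identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import adasyn, dataset, metrics, nn
from .io import read_cohort
from .simulate import SimulationConfig, simulate_cohort

_STAGES = ("simulate", "split", "balance", "train", "cv")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; fully serializable."""

    seed: int = 0
    data_root: str | None = None  # None -> simulate
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    train_fraction: float = 0.7
    stratified: bool = True
    adasyn: adasyn.AdasynConfig = field(default_factory=adasyn.AdasynConfig)
    arch_mode: Literal["reconstructed", "literal"] = "reconstructed"
    training: nn.TrainingConfig = field(default_factory=nn.TrainingConfig)
    normalize_scope: Literal["train_only", "all"] = "train_only"
    sigma_ddof: int = 0
    cv_folds: int = 3

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimulationConfig(**raw["sim"])
        if "adasyn" in raw and isinstance(raw["adasyn"], dict):
            raw["adasyn"] = adasyn.AdasynConfig(**raw["adasyn"])
        if "training" in raw and isinstance(raw["training"], dict):
            raw["training"] = nn.TrainingConfig(**raw["training"])
        return cls(**raw)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministically split the master seed into named per-stage seeds."""
    rng = np.random.default_rng(master_seed)
    return {name: int(rng.integers(2**31)) for name in _STAGES}


def _reseed(config: RunConfig) -> RunConfig:
    """Propagate the per-stage seeds derived from the master seed."""
    seeds = stage_seeds(config.seed)
    return dataclasses.replace(
        config,
        sim=dataclasses.replace(config.sim, seed=seeds["simulate"]),
        adasyn=dataclasses.replace(config.adasyn, seed=seeds["balance"]),
        training=dataclasses.replace(config.training, seed=seeds["train"]),
    )


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def prepare(config: RunConfig) -> tuple[dataset.LabeledDataset, dataset.LabeledDataset]:
    """Cohort -> observation matrix -> seeded train/test split (raw counts)."""
    seeds = stage_seeds(config.seed)
    if config.data_root is None:
        cohort = simulate_cohort(
            dataclasses.replace(config.sim, seed=seeds["simulate"])
        )
    else:
        cohort = read_cohort(config.data_root)
    ds = dataset.build_matrix(cohort)
    return dataset.split_train_test(
        ds, config.train_fraction, seed=seeds["split"], stratified=config.stratified
    )


def balance_and_normalize(
    train: dataset.LabeledDataset,
    test: dataset.LabeledDataset,
    config: RunConfig,
) -> tuple[dataset.LabeledDataset, dataset.LabeledDataset, adasyn.AdasynDiagnostics]:
    """ADASYN on the training rows, then z-normalization fitted on them."""
    seeds = stage_seeds(config.seed)
    bal_cfg = dataclasses.replace(config.adasyn, seed=seeds["balance"])
    Xb, yb, diag = adasyn.fit_resample(train.X, train.y, bal_cfg)
    balanced = dataset.LabeledDataset(X=Xb, y=yb)
    train_n, test_n, _ = dataset.normalize_split(
        balanced, test, scope=config.normalize_scope, ddof=config.sigma_ddof
    )
    return train_n, test_n, diag


def _fit_and_score(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    config: RunConfig,
    seed_offset: int = 0,
) -> tuple[nn.Model, nn.TrainingHistory, dataset.LabeledDataset, dataset.LabeledDataset]:
    """Balance+normalize one train/val split, then train the classifier."""
    train_ds = dataset.LabeledDataset(X=Xtr, y=ytr)
    val_ds = dataset.LabeledDataset(X=Xval, y=yval)
    train_n, val_n, _ = balance_and_normalize(train_ds, val_ds, config)
    seeds = stage_seeds(config.seed)
    model = nn.build_model(
        nn.ArchitectureSpec(mode=config.arch_mode), seed=seeds["train"] + seed_offset
    )
    cfg = dataclasses.replace(config.training, seed=seeds["train"] + seed_offset)
    history = nn.train(
        model,
        (dataset.to_images(train_n), train_n.y),
        (dataset.to_images(val_n), val_n.y),
        cfg,
    )
    return model, history, train_n, val_n


def evaluate_model(
    model: nn.Model, test: dataset.LabeledDataset
) -> dict:
    """Full held-out evaluation: report, confusion, ROC/AUC, sens/spec."""
    scores, y_pred = nn.predict(model, dataset.to_images(test))
    cm = metrics.confusion(test.y, y_pred)
    report = metrics.report_from_confusion(cm)
    roc = metrics.roc_auc(scores[:, 1], test.y)
    return {
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "accuracy": metrics.accuracy(cm),
        "sensitivity": metrics.sensitivity(cm),
        "specificity": metrics.specificity(cm),
        "auc": roc.auc,
        "report": report.to_dict(),
        "report_text": report.render(),
    }


def cross_validate(
    train: dataset.LabeledDataset, config: RunConfig
) -> metrics.FoldResults:
    """k-fold CV on the training portion; balancing/normalizing per fold."""
    seeds = stage_seeds(config.seed)

    def fit_eval(Xtr, ytr, Xval, yval, fold_index):
        model, _, _, val_n = _fit_and_score(
            Xtr, ytr, Xval, yval, config, seed_offset=fold_index + 1
        )
        return nn.evaluate(model, dataset.to_images(val_n), val_n.y)[::-1]

    return metrics.kfold_cv(
        train.X, train.y, fit_eval, k=config.cv_folds, seed=seeds["cv"]
    )


def run_all(config: RunConfig, out_dir: str | Path | None = None,
            with_cv: bool = True) -> dict:
    """Execute the whole pipeline; returns (and optionally writes) a manifest.

    The manifest carries the config, the derived stage seeds, dataset hashes
    and every computed metric, so two runs with the same config are
    byte-comparable.
    """
    train_raw, test_raw = prepare(config)
    model, history, train_n, test_n = _fit_and_score(
        train_raw.X, train_raw.y, test_raw.X, test_raw.y, config
    )
    _, _, diag = balance_and_normalize(train_raw, test_raw, config)
    results = {
        "config": config.to_dict(),
        "stage_seeds": stage_seeds(config.seed),
        "n_observations": len(train_raw) + len(test_raw),
        "n_train": len(train_raw),
        "n_test": len(test_raw),
        "n_train_balanced": len(train_n),
        "balance_diagnostics": {"d": diag.d, "G": diag.G},
        "data_sha256": {
            "train_raw": _sha256(train_raw.X),
            "test_raw": _sha256(test_raw.X),
            "train_balanced_normalized": _sha256(train_n.X),
        },
        "history": history.to_dict(),
        "fit_assessment": nn.overfitting_check(history),
        "evaluation": evaluate_model(model, test_n),
    }
    if with_cv:
        results["cross_validation"] = cross_validate(train_raw, config).to_dict()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nn.save_checkpoint(model, out_dir / "model.npz", config.training, history)
        history.to_csv(out_dir / "history.csv")
        (out_dir / "manifest.json").write_text(json.dumps(results, indent=2))
        (out_dir / "report.txt").write_text(results["evaluation"]["report_text"] + "\n")
    return results
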