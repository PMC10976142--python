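"""End-to-end workflow: simulate → screen → split → pretreat → select
intervals → train the three decompositions → evaluate and compare.

Every stage is driven by one :class:`RunConfig` whose single seed fans out
to all randomness, so an identical config yields an identical report.
Preprocessing is fitted on the training set only and reused for validation
and test spectra (no information leakage).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import decompose, outliers, preprocess, sipls, splitting, synthetic
from .spectra import SpectraSet, WavenumberGrid

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "render_report",
           "model_to_dict", "model_from_dict"]


@dataclass
class RunConfig:
    """Fully determines one end-to-end run."""

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig)
    preprocessing: str = "SNV+SG-17+2D"
    outlier_policy: str = "either"
    outlier_alpha: float = 0.95
    cumvar_target: float = 0.999
    split_method: str = "duplex"
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    sipls_enabled: bool = False
    sipls_k: int = 10
    sipls_j: int = 2
    sipls_lv_max: int = 6
    sipls_top: int = 5
    strategies: tuple[str, ...] = ("oao", "oaa", "ephah")
    max_lv: int = 8
    mccv_splits: int = 20
    holdout_fraction: float = 0.2
    threshold_c: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["grid"] = dataclasses.asdict(self.simulation.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "grid" in sim and isinstance(sim["grid"], dict):
            sim["grid"] = WavenumberGrid(**sim["grid"])
        if "samples_per_class" in sim and isinstance(sim["samples_per_class"], list):
            sim["samples_per_class"] = tuple(sim["samples_per_class"])
        cfg = cls(simulation=synthetic.SimulationConfig(**sim), **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()
        })
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ComparisonReport:
    """Per-strategy metrics plus run provenance."""

    per_strategy: dict[str, dict[str, Any]]
    removed_outlier_ids: list[str]
    split_counts: dict[str, int]
    chosen_intervals: dict[str, list[int]]
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "per_strategy": self.per_strategy,
            "removed_outlier_ids": self.removed_outlier_ids,
            "split_counts": self.split_counts,
            "chosen_intervals": self.chosen_intervals,
            "config": self.config,
        }


def _labels_coded(y: np.ndarray, task: decompose.ClassPartition) -> np.ndarray:
    return np.where(np.isin(y, task.positive_group), 1.0, -1.0)


def run_pipeline(cfg: RunConfig) -> ComparisonReport:
    """Execute the full workflow and return the comparison report."""
    # 1. simulate
    sim = dataclasses.replace(cfg.simulation, seed=cfg.simulation.seed or cfg.seed)
    data = synthetic.simulate_spectra(sim)

    # 2. outlier screening on raw spectra
    report = outliers.screen_outliers(
        data, policy=cfg.outlier_policy, alpha=cfg.outlier_alpha,
        per_class=True, cumvar_target=cfg.cumvar_target)
    clean = report.kept(data)

    # 3. split
    if cfg.split_method == "duplex":
        split = splitting.duplex_stratified(clean, cfg.split_ratios)
    elif cfg.split_method == "spxy":
        split = splitting.spxy_split(clean, train_fraction=cfg.split_ratios[0])
    elif cfg.split_method == "random":
        split = splitting.random_split(clean, cfg.split_ratios, seed=cfg.seed)
    else:
        raise ValueError(f"unknown split method {cfg.split_method!r}")
    train = clean.select_ids(split.train_ids)
    test = clean.select_ids(split.test_ids or split.val_ids)

    # 4. pretreat (fitted on train only)
    pipe = preprocess.parse_pipeline_name(cfg.preprocessing)
    train_p = preprocess.apply_pipeline(pipe, train)
    test_p = preprocess.apply_pipeline(pipe, test, fit_context=train)

    Xtr_full, ytr = train_p.absorbance, np.asarray(train_p.labels)
    Xte_full, yte = test_p.absorbance, np.asarray(test_p.labels)

    per_strategy: dict[str, dict[str, Any]] = {}
    chosen_intervals: dict[str, list[int]] = {}
    for strategy in cfg.strategies:
        cols = np.arange(Xtr_full.shape[1])
        freq_counts: list[int] | None = None
        if cfg.sipls_enabled:
            combo, freq = _select_intervals(cfg, strategy, train_p)
            igrid = sipls.divide_intervals(train_p.grid, cfg.sipls_k)
            cols = igrid.columns(tuple(combo))
            chosen_intervals[strategy] = list(combo)
            freq_counts = freq.counts.tolist()
        clf = decompose.DecompositionClassifier(
            strategy=strategy, threshold_c=cfg.threshold_c, max_lv=cfg.max_lv,
            mccv_splits=cfg.mccv_splits, holdout_fraction=cfg.holdout_fraction,
            random_state=cfg.seed,
        ).fit(Xtr_full[:, cols], ytr)
        pred = clf.predict(Xte_full[:, cols])
        n_correct = int(np.sum(pred == yte))
        cm = clf.confusion_matrix(Xte_full[:, cols], yte)
        per_strategy[strategy] = {
            "accuracy": n_correct / len(yte),
            "n_correct": n_correct,
            "n_total": int(len(yte)),
            "lv_mean": clf.lv_mean_,
            "ermccv_mean": clf.ermccv_mean_,
            "n_tasks": clf.plan_.n_tasks,
            "confusion_matrix": cm.tolist(),
            "classes": clf.classes_.tolist(),
            "interval_frequency": freq_counts,
        }

    return ComparisonReport(
        per_strategy=per_strategy,
        removed_outlier_ids=report.removed_ids,
        split_counts={
            "train": len(split.train_ids),
            "val": len(split.val_ids),
            "test": len(split.test_ids),
        },
        chosen_intervals=chosen_intervals,
        config=cfg.to_dict(),
    )


def _select_intervals(cfg: RunConfig, strategy: str, train: SpectraSet):
    """Per-task SI-PLS searches; characteristic region = most-selected intervals."""
    igrid = sipls.divide_intervals(train.grid, cfg.sipls_k)
    plan = decompose.make_plan(strategy, train.class_order())
    y = np.asarray(train.labels)
    results = []
    for t, task in enumerate(plan.tasks):
        mask = np.isin(y, task.members)
        coded = _labels_coded(y[mask], task)
        results.append(sipls.sipls_search(
            train.absorbance[mask], coded, igrid, j=cfg.sipls_j,
            lv_max=cfg.sipls_lv_max, seed=cfg.seed + t))
    freq = sipls.selection_frequency(results)
    top = np.argsort(-freq.counts, kind="stable")[:cfg.sipls_top]
    return sorted(int(i) for i in top), freq


# ---------------------------------------------------------------------------
# report rendering and model serialization

def render_report(r: ComparisonReport, fmt: str, path: str | Path) -> Path:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(r.to_json_dict(), indent=2, sort_keys=True))
    elif fmt == "tsv":
        lines = ["strategy\tn_tasks\tlv_mean\termccv_mean\taccuracy"]
        for s, d in r.per_strategy.items():
            lines.append(f"{s}\t{d['n_tasks']}\t{d['lv_mean']:.2f}"
                         f"\t{d['ermccv_mean']:.4f}\t{d['accuracy']:.4f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "markdown":
        lines = ["| strategy | tasks | mean LVs | ERMCCV | accuracy |",
                 "|---|---|---|---|---|"]
        for s, d in r.per_strategy.items():
            lines.append(f"| {s} | {d['n_tasks']} | {d['lv_mean']:.2f} "
                         f"| {d['ermccv_mean']:.4f} | {d['accuracy']:.4f} |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def model_to_dict(clf: decompose.DecompositionClassifier) -> dict:
    """JSON-serializable snapshot of a fitted decomposition classifier.

    Stores the per-task regression vectors and centers — enough to predict.
    Tie resolution on a reloaded model uses the margin fallback (the
    training spectra are not stored).
    """
    return {
        "strategy": clf.strategy,
        "threshold_c": clf.threshold_c,
        "classes": clf.classes_.tolist(),
        "lv_per_task": list(clf.lv_per_task_),
        "ermccv_per_task": [float(e) for e in clf.ermccv_per_task_],
        "tasks": [
            {
                "positive_group": list(t.positive_group),
                "negative_group": list(t.negative_group),
                "coef": m.pls_.coef_.tolist(),
                "x_mean": m.pls_.x_mean_.tolist(),
                "y_mean": m.pls_.y_mean_,
            }
            for t, m in zip(clf.plan_.tasks, clf.models_)
        ],
    }


def model_from_dict(d: dict) -> decompose.DecompositionClassifier:
    from .pls import PLSDABinary, PLSRegressionNIPALS

    clf = decompose.DecompositionClassifier(
        strategy=d["strategy"], threshold_c=d["threshold_c"], tie_depth=0)
    clf.classes_ = np.asarray(d["classes"])
    tasks = tuple(
        decompose.ClassPartition(tuple(t["positive_group"]),
                                 tuple(t["negative_group"]))
        for t in d["tasks"]
    )
    clf.plan_ = decompose.DecompositionPlan(d["strategy"], tuple(d["classes"]), tasks)
    clf.models_ = []
    for t in d["tasks"]:
        pls = PLSRegressionNIPALS()
        pls.coef_ = np.asarray(t["coef"], dtype=float)
        pls.x_mean_ = np.asarray(t["x_mean"], dtype=float)
        pls.y_mean_ = float(t["y_mean"])
        m = PLSDABinary(threshold_c=d["threshold_c"])
        m.pls_ = pls
        m.classes_ = np.asarray([1.0, -1.0])
        clf.models_.append(m)
    clf.lv_per_task_ = list(d["lv_per_task"])
    clf.ermccv_per_task_ = list(d["ermccv_per_task"])
    clf.lv_mean_ = float(np.mean(clf.lv_per_task_))
    clf.ermccv_mean_ = float(np.mean(clf.ermccv_per_task_))
    clf._tie_cache = {}
    return clf
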