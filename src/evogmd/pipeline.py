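"""Two-stage experiment protocol tying the modules together.

Stage 1 runs several independent DE optimizations on the training set only
(run ``i`` is seeded ``base_seed + i``; the CV fold seed equals the run seed,
so folds are fixed within a run and differ across runs), summarises the final
fitness values, and selects the best / median / worst descriptors.  Stage 2
retrains a single linear SVM on the full training set with a chosen descriptor
and reports confusion-matrix metrics on the untouched test set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .de import DEConfig, OptimizationResult, run_optimization
from .fitness import CVConfig, build_feature_table, fit_final_svm, make_fitness
from .gabor import GaborBank
from .metrics import (MetricsReport, RunSummary, evaluate_predictions,
                      pick_representatives, summarize_runs)
from .preprocess import LabeledSample

__all__ = [
    "Stage1Result",
    "run_stage1",
    "run_stage2",
    "save_descriptor",
    "load_descriptor",
]


@dataclass
class Stage1Result:
    runs: list[OptimizationResult]
    summary: RunSummary
    best: OptimizationResult
    median: OptimizationResult
    worst: OptimizationResult


def run_stage1(train_samples: Sequence[LabeledSample], de_cfg: DEConfig,
               cv_cfg: CVConfig, n_runs: int = 31, base_seed: int = 0,
               out_dir: str | Path | None = None,
               log: Callable[[str], None] | None = None) -> Stage1Result:
    """Independent DE runs on the training set; never touches test data."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    runs: list[OptimizationResult] = []
    for i in range(n_runs):
        seed = base_seed + i
        run_de = replace(de_cfg, seed=seed)
        run_cv = replace(cv_cfg, fold_seed=seed)
        fitness = make_fitness(train_samples, run_cv)
        result = run_optimization(run_de, fitness)
        runs.append(result)
        if log is not None:
            log(f"run {i + 1}/{n_runs} seed={seed} "
                f"best_E={result.best_fitness:.4f} ({result.termination_reason})")
        if out_dir is not None:
            pd.DataFrame(result.history).to_csv(
                out_dir / f"history_run{i:03d}.csv", index=False
            )
    summary = summarize_runs([r.best_fitness for r in runs])
    best, median, worst = pick_representatives(runs)
    if out_dir is not None:
        (out_dir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
        for name, result in (("best", best), ("median", median), ("worst", worst)):
            save_descriptor(out_dir / f"descriptor_{name}.json", result, de_cfg, cv_cfg)
    return Stage1Result(runs=runs, summary=summary, best=best, median=median, worst=worst)


def run_stage2(train_samples: Sequence[LabeledSample],
               test_samples: Sequence[LabeledSample], bank: GaborBank,
               cv_cfg: CVConfig) -> MetricsReport:
    """Full-train fit, held-out-test evaluation with a given descriptor."""
    train_table = build_feature_table(train_samples, bank)
    test_table = build_feature_table(test_samples, bank)
    y_true, y_pred = fit_final_svm(train_table, test_table, cv_cfg)
    return evaluate_predictions(y_true, y_pred)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_descriptor(path: str | Path, result: OptimizationResult,
                    de_cfg: DEConfig, cv_cfg: CVConfig) -> None:
    """Serialize an optimized bank with its provenance (seed, fitness, config
    echo and hash)."""
    config_echo = {"de": asdict(de_cfg), "cv": asdict(cv_cfg)}
    payload = {
        "bank": {"filters": [p.to_dict() for p in result.best_bank]},
        "seed": result.seed,
        "final_fitness": result.best_fitness,
        "termination_reason": result.termination_reason,
        "config": config_echo,
        "config_hash": _config_hash(config_echo),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_descriptor(path: str | Path) -> tuple[GaborBank, dict]:
    """Load a descriptor file; the bank revalidates its parameter domains."""
    payload = json.loads(Path(path).read_text())
    bank = GaborBank.from_json(json.dumps(payload["bank"]))
    return bank, payload
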