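"""End-to-end orchestration: simulate -> extract -> select -> tune -> train -> evaluate.

Feature extraction runs once and is shared by the three binary problems
(valence, arousal, liking); feature selection, optional hyperparameter
tuning, training and evaluation run per dimension on the dimension's own
labels.  All randomness flows from one global seed through named
substreams, and every artifact is written with a JSON sidecar recording the
seed and configuration so a finished run directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .bgwo import BGWOConfig, FeatureMask, select_features
from .bilstm import FittedBiLSTM, TrainConfig, predict, train
from .de_tuning import DEConfig, tune_bilstm
from .evaluation import EvaluationReport, evaluate
from .features import FeatureConfig, FeatureMatrix, extract_matrix
from .io_deap import (
    CLASSIFIED_DIMENSIONS,
    BinaryLabelSet,
    EEGTrialSet,
    TrialSplit,
    binarize,
    split_trials,
)
from .synthetic import SynthesisConfig, generate_dataset

log = logging.getLogger("eegaffect")


def _substream(seed: int, name: str) -> int:
    """Stable named substream seed below 2**31."""
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return (seed * 1000003 + h) % (2**31 - 1)


@dataclass
class PipelineConfig:
    dimensions: tuple[str, ...] = CLASSIFIED_DIMENSIONS
    seed: int = 7
    out_dir: str = "run"
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    bgwo: BGWOConfig = field(default_factory=BGWOConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    tune: bool = False
    de: DEConfig = field(default_factory=lambda: DEConfig(population_size=6, generations=3))
    fraction_train: float = 0.70
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("at least one label dimension required")
        for d in self.dimensions:
            if d not in CLASSIFIED_DIMENSIONS:
                raise ValueError(f"unknown dimension {d!r}")


def _sidecar(path: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["version"] = __version__
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(payload, indent=2, default=str)
    )


@dataclass
class PipelineResult:
    reports: dict[str, EvaluationReport]
    masks: dict[str, FeatureMask]
    models: dict[str, FittedBiLSTM]
    features: FeatureMatrix
    split: TrialSplit
    errors: dict[str, str] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig,
                 dataset: Optional[Sequence[EEGTrialSet]] = None) -> PipelineResult:
    """Execute all stages; a stage failure aborts only that dimension."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if dataset is None:
        syn = dataclasses.replace(cfg.synthesis, seed=_substream(cfg.seed, "simulate"))
        log.info("generating synthetic dataset: %d participants", syn.n_participants)
        dataset = generate_dataset(syn)
    ratings = np.vstack([ts.ratings for ts in dataset])

    log.info("extracting features from %d trials", sum(ts.n_trials for ts in dataset))
    fm = extract_matrix(dataset, cfg.features)
    fm.to_csv(out / "features.csv")
    _sidecar(out / "features.csv", {"seed": cfg.seed, "config": asdict(cfg.features),
                                    "n_trials": fm.n_trials, "n_features": fm.n_features})

    split = split_trials(fm.n_trials, cfg.fraction_train, _substream(cfg.seed, "split"))
    np.savetxt(out / "split_train.txt", split.train_indices, fmt="%d")
    np.savetxt(out / "split_test.txt", split.test_indices, fmt="%d")

    reports: dict[str, EvaluationReport] = {}
    masks: dict[str, FeatureMask] = {}
    models: dict[str, FittedBiLSTM] = {}
    errors: dict[str, str] = {}
    dim_index = {"valence": 0, "arousal": 1, "dominance": 2, "liking": 3}
    for dim in cfg.dimensions:
        try:
            y = binarize(ratings[:, dim_index[dim]], dimension=dim)
            tr, te = split.train_indices, split.test_indices
            bg = dataclasses.replace(cfg.bgwo, seed=_substream(cfg.seed, f"bgwo:{dim}"))
            log.info("[%s] BGWO feature selection (%d wolves, %d iterations)",
                     dim, bg.n_wolves, bg.max_iter)
            mask = select_features(
                FeatureMatrix(fm.values[tr], fm.column_names, fm.config),
                BinaryLabelSet(dim, y.labels[tr]), bg)
            masks[dim] = mask
            mask.to_frame().to_csv(out / f"mask_{dim}.csv", index=False)
            _sidecar(out / f"mask_{dim}.csv",
                     {"seed": bg.seed, "fitness": mask.fitness,
                      "n_selected": mask.n_selected,
                      "trace": list(map(float, mask.trace))})

            train_cfg = dataclasses.replace(
                cfg.training, seed=_substream(cfg.seed, f"train:{dim}"))
            sel = mask.bits.astype(bool)
            Xsel = FeatureMatrix(fm.values[:, sel],
                                 [c for c, b in zip(fm.column_names, sel) if b],
                                 fm.config)
            if cfg.tune:
                de_cfg = dataclasses.replace(cfg.de, seed=_substream(cfg.seed, f"tune:{dim}"))
                log.info("[%s] DE hyperparameter tuning (NP=%d, g=%d)",
                         dim, de_cfg.population_size, de_cfg.generations)
                train_cfg, de_result = tune_bilstm(
                    Xsel, y, split, cfg=de_cfg, base_config=train_cfg)
                de_result.history.to_csv(out / f"leaderboard_{dim}.csv", index=False)
            log.info("[%s] training Bi-LSTM on %d trials x %d features",
                     dim, tr.size, mask.n_selected)
            model = train(FeatureMatrix(Xsel.values[tr], Xsel.column_names, Xsel.config),
                          BinaryLabelSet(dim, y.labels[tr]), train_cfg)
            models[dim] = model
            model.save(out / f"model_{dim}.npz")
            _sidecar(out / f"model_{dim}.npz",
                     {"seed": train_cfg.seed, "config": asdict(train_cfg),
                      "final_train_accuracy": model.accuracy_trace[-1]})

            y_pred, probs = predict(model, Xsel.values[te])
            report = evaluate(dim, y.labels[te], y_pred, probs)
            reports[dim] = report
            report.to_json(out / f"report_{dim}.json")
            log.info("[%s] test accuracy %.4f%% (AUC %.4f)", dim, report.accuracy, report.auc)
        except Exception as exc:  # keep the other dimensions running
            log.error("[%s] stage failed: %s", dim, exc)
            errors[dim] = f"{type(exc).__name__}: {exc}"
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return PipelineResult(reports, masks, models, fm, split, errors)
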