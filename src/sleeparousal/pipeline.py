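"""End-to-end orchestration: synthesis -> subbands -> windows -> spectrograms
-> CNN features -> GWO-tuned RBF-SVM -> stratified k-fold evaluation.

The default configuration is a desk-scale study: a few minutes of synthetic
single-lead EEG yielding roughly 400 one-second windows, the tiny backbone
scale, and a reduced Grey-Wolf search budget.  Every stage is a pure
function of the configuration (seeds included), so a rerun writes
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass

import numpy as np

from ._exceptions import ConfigurationError, ValidationError
from .backbone import BackboneConfig, TrainConfig, build_extractor, extract_features, finetune
from .classifier import (
    KernelParams,
    TuneResult,
    fit_svm,
    predict,
    save_model,
    tune_hyperparameters,
)
from .evaluation import ROCResult, confusion_metrics, roc_curve, stratified_kfold
from .gwo import GWOConfig
from .preprocess import dwt_subbands, window_signal
from .signal_model import EEGRecord, SynthConfig, generate_record
from .spectro import STFTConfig, render, stft_power

logger = logging.getLogger("sleeparousal")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    # --- synthetic study ------------------------------------------------
    n_records: int = 4
    record_duration_s: float = 52.0
    fs: float = 200.0
    n_arousal_events: int = 2
    arousal_dur_range_s: tuple[float, float] = (5.0, 15.0)
    noise_snr_db: float | None = None
    # --- preprocessing --------------------------------------------------
    wavelet: str = "db3"
    level: int = 5
    win_s: float = 1.0
    overlap: float = 0.5
    #: "raw" or "subband:<name>" — which signal the spectrograms are
    #: computed on
    spectro_source: str = "raw"
    # --- spectrogram ----------------------------------------------------
    seg_len: int = 64
    hop: int = 8
    n_freq: int = 64
    log_power: bool = True
    # --- backbone -------------------------------------------------------
    backbone_scale: str = "tiny"
    finetune_epochs: int = 30
    finetune_optimizer: str = "rmsprop"
    finetune_lr: float = 0.001
    # --- tuning ---------------------------------------------------------
    tune_folds: int = 5
    c_range: tuple[float, float] = (1.0, 50.0)
    g_range: tuple[float, float] = (1.0, 30.0)
    gwo_pop: int = 10
    gwo_iters: int = 20
    tune_repetitions: int = 2
    #: skip the GWO search and use these (C, gamma) directly when set
    fixed_params: tuple[float, float] | None = None
    # --- evaluation -----------------------------------------------------
    eval_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if int(round(self.win_s * self.fs)) < self.seg_len:
            raise ConfigurationError(
                f"a {self.win_s}s window at {self.fs} Hz is shorter than "
                f"seg_len={self.seg_len} STFT samples"
            )
        if self.spectro_source != "raw" and not self.spectro_source.startswith("subband:"):
            raise ConfigurationError(
                "spectro_source must be 'raw' or 'subband:<name>'"
            )


@dataclass
class PipelineReport:
    config: PipelineConfig
    fold_metrics: list[dict]
    accuracy: float
    sensitivity: float
    specificity: float
    az: float
    roc: ROCResult
    tune_result: TuneResult | None
    params: KernelParams
    n_windows: int
    n_excluded: int
    runtime_s: float

    def summary(self) -> str:
        lines = [
            "sleep-arousal detection report",
            "==============================",
            f"windows evaluated : {self.n_windows} "
            f"({self.n_excluded} undefined windows excluded)",
            f"(C, gamma)        : ({self.params.C:.3f}, {self.params.gamma:.3f})",
            f"held-out accuracy : {self.accuracy:.4f}",
            f"sensitivity       : {self.sensitivity:.4f}",
            f"specificity       : {self.specificity:.4f}",
            f"A_z (AUROC)       : {self.az:.4f}",
            "",
            "fold\tn_test\taccuracy\tsensitivity\tspecificity",
        ]
        for m in self.fold_metrics:
            lines.append(
                f"{m['fold']}\t{m['n_test']}\t{m['accuracy']:.4f}"
                f"\t{m['sensitivity']:.4f}\t{m['specificity']:.4f}"
            )
        return "\n".join(lines)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "metrics.tsv"), "w") as fh:
            fh.write("metric\tvalue\tfold\n")
            for name in ("accuracy", "sensitivity", "specificity", "az"):
                fh.write(f"{name}\t{getattr(self, name)!r}\tall\n")
            for m in self.fold_metrics:
                for name in ("accuracy", "sensitivity", "specificity"):
                    fh.write(f"{name}\t{m[name]!r}\t{m['fold']}\n")
        self.roc.write_tsv(os.path.join(outdir, "roc.tsv"))
        if self.tune_result is not None:
            best = self.tune_result.repetitions[0]
            best.write_trace(os.path.join(outdir, "gwo_trace.tsv"))
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, default=str)


def _source_signal(record: EEGRecord, cfg: PipelineConfig) -> np.ndarray:
    if cfg.spectro_source == "raw":
        return record.samples
    band = cfg.spectro_source.split(":", 1)[1]
    subbands = dwt_subbands(record, wavelet=cfg.wavelet, level=cfg.level)
    if band not in subbands.bands:
        raise ConfigurationError(f"unknown subband {band!r}")
    return subbands.bands[band]


def build_dataset(
    cfg: PipelineConfig,
) -> tuple[list, np.ndarray, int]:
    """Generate records and return (windows, labels in {-1,+1}, n_excluded)."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_records)
    windows = []
    n_excluded = 0
    for i, rec_seed in enumerate(seeds):
        synth = SynthConfig(
            duration_s=cfg.record_duration_s,
            fs=cfg.fs,
            n_arousal_events=cfg.n_arousal_events,
            arousal_dur_range_s=cfg.arousal_dur_range_s,
            noise_snr_db=cfg.noise_snr_db,
            seed=int(rec_seed % 2**31),
            record_id=f"synth-{i:03d}",
        )
        record, annotation = generate_record(synth)
        signal = _source_signal(record, cfg)
        for win in window_signal(
            record, annotation, win_s=cfg.win_s, overlap=cfg.overlap,
            samples=signal,
            band=None if cfg.spectro_source == "raw" else cfg.spectro_source,
        ):
            if win.label == -1:
                n_excluded += 1
            else:
                windows.append(win)
    labels = np.array([1 if w.label == 1 else -1 for w in windows])
    return windows, labels, n_excluded


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None) -> PipelineReport:
    """Execute the whole detection pipeline and evaluate it by stratified
    k-fold cross-validation.

    Hyperparameters (C, gamma) are tuned once by the Grey Wolf Optimizer
    against inner-CV classification error on the extracted features, then a
    fresh classifier is fitted and scored on each outer fold; decision
    values are pooled across folds for the ROC / A_z.
    """
    t0 = time.time()
    logger.info("stage 1/5: synthesising %d records", cfg.n_records)
    windows, y, n_excluded = build_dataset(cfg)
    if n_excluded:
        logger.info("excluded %d undefined (-1) windows", n_excluded)
    if np.unique(y).size < 2:
        raise ValidationError("dataset contains a single class; adjust the generator")

    logger.info("stage 2/5: spectrograms for %d windows", len(windows))
    backbone_cfg = BackboneConfig(scale=cfg.backbone_scale, seed=cfg.seed)
    stft_cfg = STFTConfig(seg_len=cfg.seg_len, hop=cfg.hop, n_freq=cfg.n_freq)
    images = [
        render(
            stft_power(w, stft_cfg, fs=cfg.fs),
            height=backbone_cfg.input_hw,
            width=backbone_cfg.input_hw,
            log_power=cfg.log_power,
        )
        for w in windows
    ]

    logger.info("stage 3/5: %s-scale feature extraction", cfg.backbone_scale)
    fx = build_extractor(backbone_cfg)
    if cfg.finetune_epochs > 0:
        finetune(
            fx, images, (y > 0).astype(int),
            TrainConfig(
                lr=cfg.finetune_lr, optimizer=cfg.finetune_optimizer,
                epochs=cfg.finetune_epochs, seed=cfg.seed,
            ),
        )
    fx.calibrate(images)
    X = extract_features(fx, images)

    if cfg.fixed_params is not None:
        tune_result = None
        params = KernelParams(C=cfg.fixed_params[0], gamma=cfg.fixed_params[1])
        logger.info("stage 4/5: using fixed (C, gamma) = (%g, %g)", params.C, params.gamma)
    else:
        logger.info(
            "stage 4/5: GWO tuning (pop %d, %d iters, %d repetitions)",
            cfg.gwo_pop, cfg.gwo_iters, cfg.tune_repetitions,
        )
        tune_result = tune_hyperparameters(
            X, y,
            folds=cfg.tune_folds,
            c_range=cfg.c_range,
            g_range=cfg.g_range,
            gwo_cfg=GWOConfig(
                bounds=(cfg.c_range, cfg.g_range),
                pop_size=cfg.gwo_pop,
                n_iters=cfg.gwo_iters,
                n_restarts=1,
                seed=cfg.seed,
            ),
            repetitions=cfg.tune_repetitions,
            seed=cfg.seed,
        )
        params = tune_result.best_params

    logger.info("stage 5/5: %d-fold evaluation", cfg.eval_folds)
    assignment = stratified_kfold(y, k=cfg.eval_folds, seed=cfg.seed)
    fold_metrics = []
    pooled_pred = np.empty_like(y)
    pooled_decision = np.empty(y.shape[0])
    for fold in range(cfg.eval_folds):
        test = assignment == fold
        model = fit_svm(X[~test], y[~test], params)
        pred, decision = predict(model, X[test])
        pooled_pred[test] = pred
        pooled_decision[test] = decision
        cm, acc, sens, spec = confusion_metrics(y[test], pred)
        fold_metrics.append(
            {
                "fold": fold,
                "n_test": int(test.sum()),
                "accuracy": acc,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    _, accuracy, sensitivity, specificity = confusion_metrics(y, pooled_pred)
    roc = roc_curve(y, pooled_decision)
    report = PipelineReport(
        config=cfg,
        fold_metrics=fold_metrics,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        az=roc.az,
        roc=roc,
        tune_result=tune_result,
        params=params,
        n_windows=int(y.size),
        n_excluded=n_excluded,
        runtime_s=time.time() - t0,
    )
    if outdir is not None:
        report.write(outdir)
        final_model = fit_svm(X, y, params)
        save_model(final_model, os.path.join(outdir, "model"))
    logger.info("pipeline finished in %.1f s", report.runtime_s)
    return report
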