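"""End-to-end predictor training and leave-one-recording-out evaluation.

Each patient is evaluated in N rounds (N = number of records). Per round
one record is held out; on the remaining N − 1:

1. preictal training epochs are collected from the preictal windows of
   non-excluded seizures, interictal training epochs only from seizure-free
   records;
2. the run-length threshold α is selected by splitting the N − 1 training
   records into up to 5 inner folds: CSP + LDA fitted on the other folds
   score each fold's records, and α maximizing pooled inner alarm
   sensitivity (ties: lowest false rate, then largest α) wins;
3. CSP and LDA are refit on all N − 1 records, parameters frozen, and the
   held-out record is scored: epoch features -> LDA decisions at 1 Hz ->
   seventh-order median smoothing -> run-length alarms -> horizon metrics.

The held-out record contributes specificity/FPR always, and sensitivity /
prediction time only if it contains an evaluable seizure. Averages are the
arithmetic mean of per-round values, skipping not-applicable entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import alarms as alarm_logic
from . import csp as csp_mod
from . import lda as lda_mod
from . import metrics as metrics_mod
from .io import GlobalSeizure, Recording, RecordSet
from .lda import BinarySeries
from .segmentation import (INTERICTAL, PREICTAL, SegmentationConfig,
                           label_epochs, sliding_epochs)

log = logging.getLogger("preictal")


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one predictor run (times in seconds)."""

    window_s: float = 3.0
    step_s: float = 1.0
    preictal_len_s: float = 180.0
    preictal_offset_s: float = 0.0
    postictal_s: float = 600.0
    gap_margin_s: float = 600.0
    horizon_s: float = 3600.0
    alpha: int | None = None  # fixed threshold; None = select on training data
    alpha_grid: tuple[int, ...] = alarm_logic.DEFAULT_ALPHA_GRID
    shrinkage: float = 1e-3
    median_order: int = 7
    inner_folds: int = 5
    seed: int = 0

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            window_s=self.window_s, step_s=self.step_s,
            preictal_len_s=self.preictal_len_s,
            preictal_offset_s=self.preictal_offset_s,
            postictal_s=self.postictal_s, gap_margin_s=self.gap_margin_s,
        )


@dataclass
class PredictorModel:
    """A frozen, fitted predictor: spatial filters, discriminant, threshold."""

    csp: csp_mod.CSPModel
    lda: lda_mod.LDAModel
    alpha: int
    config: RunConfig


@dataclass
class RoundResult:
    held_out: str
    alpha: int
    result: metrics_mod.EvaluationResult
    n_preictal_train: int
    n_interictal_train: int
    train_record_ids: list[str] = field(default_factory=list)


@dataclass
class CrossValReport:
    patient_id: str
    rounds: list[RoundResult]
    skipped: list[tuple[str, str]]  # (record_id, reason)
    config: RunConfig

    def average(self) -> dict[str, float]:
        """NaN-skipping arithmetic mean of per-round metrics."""
        keys = ("sensitivity", "specificity", "fpr_per_h",
                "mean_prediction_time_min")
        out = {}
        for key in keys:
            vals = [getattr(r.result, key) for r in self.rounds]
            vals = [v for v in vals if not np.isnan(v)]
            out[key] = float(np.mean(vals)) if vals else float("nan")
        return out


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

def collect_training_epochs(record_set: RecordSet,
                            recordings: Sequence[Recording],
                            config: RunConfig):
    """Preictal and interictal training epochs from the given records.

    Interictal epochs are drawn only from seizure-free records; preictal
    epochs come from the labelled preictal windows of non-excluded seizures.
    """
    seg = config.segmentation()
    seizures = record_set.seizures_global()
    gaps = record_set.gaps()
    coverage = record_set.coverage()
    seizure_free = record_set.seizure_free_record_ids()
    pre, inter = [], []
    for rec in recordings:
        epochs = sliding_epochs(rec, seg)
        labeling = label_epochs(epochs, seizures, seg, gaps=gaps,
                                coverage=coverage)
        for ep, lab in zip(epochs, labeling.labels):
            if lab == PREICTAL:
                pre.append(ep)
            elif lab == INTERICTAL and rec.record_id in seizure_free:
                inter.append(ep)
    return pre, inter


def fit_predictor(record_set: RecordSet,
                  recordings: Sequence[Recording],
                  config: RunConfig,
                  alpha: int,
                  seed: int) -> PredictorModel:
    """Fit CSP + LDA on the given training records with a fixed α."""
    pre, inter = collect_training_epochs(record_set, recordings, config)
    if not pre:
        raise ValueError("no preictal training epochs available")
    if not inter:
        raise ValueError("no interictal training epochs (need seizure-free records)")
    c1 = csp_mod.class_mean_covariance(
        [csp_mod.normalized_covariance(ep) for ep in pre]
    )
    c2 = csp_mod.class_mean_covariance(
        [csp_mod.normalized_covariance(ep) for ep in inter]
    )
    model = csp_mod.fit_csp(c1, c2)
    feats = np.vstack([
        csp_mod.epoch_features(pre, model),
        csp_mod.epoch_features(inter, model),
    ])
    labels = np.concatenate([
        np.ones(len(pre), dtype=int), np.zeros(len(inter), dtype=int)
    ])
    feats, labels = lda_mod.undersample(feats, labels, seed=seed)
    clf = lda_mod.fit_lda(feats, labels, shrinkage=config.shrinkage)
    return PredictorModel(csp=model, lda=clf, alpha=alpha, config=config)


def predict_on_recording(model: PredictorModel,
                         recording: Recording) -> BinarySeries:
    """Smoothed 1 Hz preictal/interictal decision series for one record."""
    seg = model.config.segmentation()
    epochs = sliding_epochs(recording, seg)
    if not epochs:
        return BinarySeries(values=np.zeros(0, np.uint8),
                            start_time=recording.start_time,
                            step_s=seg.step_s)
    feats = csp_mod.epoch_features(epochs, model.csp)
    series = lda_mod.predict_series(
        model.lda, feats, start_time=epochs[0].start_time, step_s=seg.step_s
    )
    return lda_mod.median_smooth(series, order=model.config.median_order)


# ---------------------------------------------------------------------------
# Inner α selection
# ---------------------------------------------------------------------------

def _select_alpha_inner(record_set: RecordSet,
                        train_recs: list[Recording],
                        config: RunConfig,
                        seed: int) -> int:
    """Select α by up-to-5-fold cross-validation within the training records."""
    n_folds = min(config.inner_folds, len(train_recs))
    if n_folds < 2:
        log.warning("too few training records for inner folds; "
                    "selecting alpha on resubstitution")
        folds = [train_recs]
        fit_sets = [train_recs]
    else:
        idx_folds = np.array_split(np.arange(len(train_recs)), n_folds)
        folds = [[train_recs[i] for i in idx] for idx in idx_folds]
        fit_sets = [
            [r for r in train_recs if not any(r is f for f in fold)]
            for fold in folds
        ]
    seizures = record_set.seizures_global()
    runs = []
    for k, (fold, fit_recs) in enumerate(zip(folds, fit_sets)):
        try:
            model = fit_predictor(record_set, fit_recs, config, alpha=1,
                                  seed=seed + 7 * k + 1)
        except ValueError as exc:
            log.info("inner fold %d skipped: %s", k, exc)
            continue
        for rec in fold:
            series = predict_on_recording(model, rec)
            if len(series):
                runs.append((series, seizures))
    if not runs:
        log.warning("no usable inner folds; using largest grid alpha")
        return int(max(config.alpha_grid))
    return alarm_logic.select_alpha(
        runs, config.horizon_s, alpha_grid=config.alpha_grid,
        gaps=record_set.gaps(), postictal_s=config.postictal_s,
    )


# ---------------------------------------------------------------------------
# Leave-one-recording-out
# ---------------------------------------------------------------------------

def loocv_run(record_set: RecordSet, config: RunConfig) -> CrossValReport:
    """Leave-one-recording-out evaluation of the full predictor."""
    recs = record_set.recordings
    if len(recs) < 2:
        raise ValueError("leave-one-out needs at least 2 recordings")
    seizures = record_set.seizures_global()
    if not any(not sz.excluded for sz in seizures):
        raise ValueError("record set has no evaluable (non-excluded) seizure")
    gaps = record_set.gaps()

    rounds: list[RoundResult] = []
    skipped: list[tuple[str, str]] = []
    for r, held_out in enumerate(recs):
        train_recs = [rec for rec in recs if rec is not held_out]
        round_seed = config.seed * 1009 + r
        try:
            if config.alpha is not None:
                alpha = config.alpha
            else:
                alpha = _select_alpha_inner(record_set, train_recs, config,
                                            seed=round_seed)
            model = fit_predictor(record_set, train_recs, config, alpha,
                                  seed=round_seed)
        except ValueError as exc:
            log.warning("round %d (held-out %r) skipped: %s",
                        r, held_out.record_id, exc)
            skipped.append((held_out.record_id, str(exc)))
            continue
        pre, inter = collect_training_epochs(record_set, train_recs, config)
        series = predict_on_recording(model, held_out)
        alarm_times = alarm_logic.raise_alarms(series, model.alpha)
        result = metrics_mod.evaluate(
            alarm_times, seizures, config.horizon_s,
            coverage=[(held_out.start_time, held_out.end_time)],
            postictal_s=config.postictal_s, gaps=gaps,
            gap_margin_s=config.gap_margin_s,
        )
        rounds.append(
            RoundResult(
                held_out=held_out.record_id,
                alpha=model.alpha,
                result=result,
                n_preictal_train=len(pre),
                n_interictal_train=len(inter),
                train_record_ids=[rec.record_id for rec in train_recs],
            )
        )
    return CrossValReport(patient_id=record_set.patient_id, rounds=rounds,
                          skipped=skipped, config=config)


def evaluate_baseline(record_set: RecordSet, spec: metrics_mod.BaselineSpec,
                      config: RunConfig) -> metrics_mod.EvaluationResult:
    """Score a periodic/Poisson baseline over the whole record set."""
    coverage = record_set.coverage()
    alarm_times = metrics_mod.baseline_alarms(spec, coverage)
    return metrics_mod.evaluate(
        alarm_times, record_set.seizures_global(), config.horizon_s,
        coverage=coverage, postictal_s=config.postictal_s,
        gaps=record_set.gaps(), gap_margin_s=config.gap_margin_s,
    )


def mean_interictal_interval_h(record_set: RecordSet) -> float:
    """Average seizure-free stretch (hours): total coverage / (n seizures + 1)."""
    total_h = sum(e - s for s, e in record_set.coverage()) / 3600.0
    n = sum(1 for sz in record_set.seizures_global() if not sz.excluded)
    return total_h / max(n + 1, 1)
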