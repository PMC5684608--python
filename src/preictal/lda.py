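"""Closed-form two-class linear discriminant on CSP features.

The classifier is the textbook pooled-covariance LDA with equal priors
(training sets are balanced by random undersampling first):
``w ∝ S⁻¹ (μ_pre − μ_inter)`` with the boundary at the midpoint of the
projected class means. The pooled covariance is shrunk toward its diagonal
by a small coefficient because 23-dimensional features estimated from a few
minutes of preictal data can be ill-conditioned.

Epoch decisions form a 1 Hz binary series (1 = preictal) which is smoothed
with a seventh-order median filter before alarm logic sees it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("preictal")

PREICTAL_LABEL = 1
INTERICTAL_LABEL = 0


@dataclass
class LDAModel:
    w: np.ndarray
    b: float
    mean_pre: np.ndarray
    mean_inter: np.ndarray
    pooled_cov: np.ndarray
    shrinkage: float

    def decision(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, float) @ self.w + self.b


@dataclass
class BinarySeries:
    """Uniformly stepped 0/1 classifier output, one value per epoch."""

    values: np.ndarray
    start_time: float = 0.0
    step_s: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("series values must be 0 or 1")
        self.values = v.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.values)

    def time_of(self, index: int) -> float:
        return self.start_time + index * self.step_s


def undersample(features: np.ndarray, labels: np.ndarray,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomly reduce the majority class to the minority count.

    Sampling is uniform without replacement and deterministic given
    ``seed``; surviving rows keep their original order. A class with zero
    members is an error.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    idx_pre = np.flatnonzero(labels == PREICTAL_LABEL)
    idx_int = np.flatnonzero(labels == INTERICTAL_LABEL)
    if idx_pre.size == 0 or idx_int.size == 0:
        raise ValueError("undersampling requires both classes present")
    rng = np.random.default_rng(seed)
    if idx_pre.size > idx_int.size:
        idx_pre = np.sort(rng.choice(idx_pre, idx_int.size, replace=False))
    elif idx_int.size > idx_pre.size:
        idx_int = np.sort(rng.choice(idx_int, idx_pre.size, replace=False))
    keep = np.sort(np.concatenate([idx_pre, idx_int]))
    return features[keep], labels[keep]


def fit_lda(features: np.ndarray, labels: np.ndarray,
            shrinkage: float = 1e-3) -> LDAModel:
    """Fit equal-prior LDA in closed form.

    The pooled within-class covariance is ``(1 − γ) S + γ diag(S)`` with
    shrinkage coefficient γ. At γ = 0 a singular S raises with advice to
    enable shrinkage.
    """
    x = np.asarray(features, float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be n_samples x n_features matching labels")
    xp = x[y == PREICTAL_LABEL]
    xi = x[y == INTERICTAL_LABEL]
    if len(xp) == 0 or len(xi) == 0:
        raise ValueError("both classes required to fit LDA")
    mu_p, mu_i = xp.mean(axis=0), xi.mean(axis=0)
    n = len(xp) + len(xi)
    scatter = (xp - mu_p).T @ (xp - mu_p) + (xi - mu_i).T @ (xi - mu_i)
    pooled = scatter / max(n - 2, 1)
    pooled = (1 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))
    delta = mu_p - mu_i
    try:
        w = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance singular; refit with shrinkage > 0"
        ) from exc
    if np.linalg.norm(delta) < 1e-12:
        log.warning("identical class means: degenerate discriminant (w ~ 0)")
    b = -float(w @ (mu_p + mu_i) / 2)
    return LDAModel(w=w, b=b, mean_pre=mu_p, mean_inter=mu_i,
                    pooled_cov=pooled, shrinkage=shrinkage)


def predict_series(model: LDAModel, features: np.ndarray,
                   start_time: float = 0.0,
                   step_s: float = 1.0) -> BinarySeries:
    """Classify ordered epochs: 1 iff ``w·x + b > 0`` (ties are interictal)."""
    x = np.asarray(features, float)
    if x.size == 0:
        return BinarySeries(values=np.zeros(0, np.uint8),
                            start_time=start_time, step_s=step_s)
    if not np.isfinite(x).all():
        bad = np.flatnonzero(~np.isfinite(x).all(axis=1))
        raise ValueError(f"non-finite features at epoch index(es) {bad.tolist()}")
    out = (model.decision(x) > 0).astype(np.uint8)
    return BinarySeries(values=out, start_time=start_time, step_s=step_s)


def median_smooth(series: BinarySeries, order: int = 7) -> BinarySeries:
    """Sliding median of odd length ``order``, edges handled by reflection."""
    if order % 2 == 0 or order < 1:
        raise ValueError(f"median order must be odd and >= 1, got {order}")
    v = series.values
    if order == 1 or len(v) == 0:
        return BinarySeries(values=v.copy(), start_time=series.start_time,
                            step_s=series.step_s)
    half = order // 2
    if len(v) == 1:
        padded = np.repeat(v, order)
    else:
        padded = np.pad(v, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, order)
    out = (windows.sum(axis=1) > half).astype(np.uint8)  # binary median
    return BinarySeries(values=out, start_time=series.start_time,
                        step_s=series.step_s)
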