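"""Common spatial patterns (CSP) and log-variance features.

CSP finds a projection matrix ``W`` whose rows (spatial filters) extremize
the variance ratio between two signal classes — here preictal (class 1) and
interictal (class 2) scalp-EEG epochs. The derivation, kept explicit so all
intermediates are inspectable:

1. per-epoch normalized covariance ``C = D Dᵀ / trace(D Dᵀ)`` for a
   channels x samples segment ``D``;
2. class averages ``C1``, ``C2`` and the composite ``Cc = C1 + C2``;
3. eigendecomposition ``Cc = Fc ψ Fcᵀ``;
4. square-root whitening ``P = ψ^(−1/2) Fcᵀ`` so that ``P Cc Pᵀ = I``;
5. the whitened class matrices ``S1 = P C1 Pᵀ`` and ``S2 = P C2 Pᵀ`` share
   eigenvectors ``U`` with eigenvalue pairs summing to one
   (``Λ1 + Λ2 = I``); sorting Λ1 descending and setting ``W = Uᵀ P`` puts
   the most preictal-variance-selective filters first.

Features are the natural log of the sample variance of each spatially
filtered row, giving one value per channel (a 23-element vector for a
23-channel montage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .segmentation import Epoch

log = logging.getLogger("preictal")

#: Condition-number threshold beyond which a small ridge is added to Cc.
_COND_LIMIT = 1e12
_RIDGE_SCALE = 1e-10


class DegenerateInputError(ValueError):
    """Raised for inputs CSP cannot process (zero segments, flat rows)."""


@dataclass
class Covariance:
    """A symmetric covariance estimate and how many epochs produced it."""

    matrix: np.ndarray
    n_epochs: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance must be symmetric (atol 1e-10)")
        self.matrix = (m + m.T) / 2

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CSPModel:
    """All intermediates of one CSP fit (see module docstring)."""

    C1: Covariance
    C2: Covariance
    Fc: np.ndarray
    psi: np.ndarray       # eigenvalues of Cc, descending
    P: np.ndarray         # whitening transform
    U: np.ndarray         # common eigenvectors of the whitened classes
    lambda1: np.ndarray   # paired eigenvalues, class 1, descending
    lambda2: np.ndarray   # paired eigenvalues, class 2 (= 1 - lambda1)
    W: np.ndarray         # projection matrix, filters in rows

    @property
    def dim(self) -> int:
        return self.W.shape[0]


def _epoch_data(epoch: Epoch | np.ndarray) -> np.ndarray:
    data = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, float)
    if data.ndim != 2:
        raise ValueError("epoch data must be channels x samples")
    return data


def normalized_covariance(epoch: Epoch | np.ndarray) -> Covariance:
    """Per-segment covariance ``D Dᵀ / trace(D Dᵀ)`` (unit trace, no mean removal)."""
    d = _epoch_data(epoch)
    if d.shape[1] < 2:
        raise DegenerateInputError("epoch needs at least 2 samples")
    if np.any(np.ptp(d, axis=1) == 0) and not np.all(d == 0):
        flat = np.flatnonzero(np.ptp(d, axis=1) == 0)
        if np.any(d[flat] != 0):
            raise DegenerateInputError(
                f"all-constant nonzero channel(s) {flat.tolist()} in epoch"
            )
    ddt = d @ d.T
    tr = np.trace(ddt)
    if tr <= 0:
        raise DegenerateInputError("all-zero epoch: trace(DDt) = 0")
    return Covariance(matrix=ddt / tr, n_epochs=1)


def class_mean_covariance(covs: list[Covariance]) -> Covariance:
    """Element-wise arithmetic mean of per-epoch covariances (unit trace kept)."""
    if not covs:
        raise ValueError("cannot average an empty covariance list")
    dim = covs[0].dim
    if any(c.dim != dim for c in covs):
        raise ValueError("covariance dimensions differ")
    mean = np.mean([c.matrix for c in covs], axis=0)
    return Covariance(matrix=mean, n_epochs=sum(c.n_epochs for c in covs))


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Make the first nonzero component of each column positive (reproducible)."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            v[:, j] = -col
    return v


def fit_csp(C1: Covariance, C2: Covariance) -> CSPModel:
    """Fit the CSP projection from two class covariances.

    Class 1 is preictal, class 2 interictal. ``lambda1`` is sorted
    descending, so the leading rows of ``W`` maximize preictal variance.
    Raises if the composite covariance stays near-singular even after a
    small ridge.
    """
    if C1.dim != C2.dim:
        raise ValueError(f"dimension mismatch: {C1.dim} vs {C2.dim}")
    cc = C1.matrix + C2.matrix
    eigvals = np.linalg.eigvalsh(cc)
    if eigvals.min() <= 0 or eigvals.max() / max(eigvals.min(), 1e-300) > _COND_LIMIT:
        ridge = _RIDGE_SCALE * np.trace(cc)
        log.warning(
            "composite covariance ill-conditioned (cond %.2e); adding ridge %.2e",
            eigvals.max() / max(eigvals.min(), 1e-300), ridge,
        )
        cc = cc + ridge * np.eye(C1.dim)
        eigvals = np.linalg.eigvalsh(cc)
        if eigvals.min() <= 0:
            raise np.linalg.LinAlgError(
                "composite covariance singular beyond regularization; "
                "provide more epochs or a larger ridge"
            )

    psi, fc = scipy.linalg.eigh(cc)
    order = np.argsort(psi)[::-1]
    psi, fc = psi[order], _sign_fix(fc[:, order])

    p = np.diag(psi ** -0.5) @ fc.T
    s1 = p @ C1.matrix @ p.T
    s2 = p @ C2.matrix @ p.T
    s1, s2 = (s1 + s1.T) / 2, (s2 + s2.T) / 2

    lam1, u = scipy.linalg.eigh(s1)
    order = np.argsort(lam1)[::-1]
    lam1, u = lam1[order], _sign_fix(u[:, order])
    lam2 = np.diag(u.T @ s2 @ u).copy()

    return CSPModel(
        C1=C1, C2=C2, Fc=fc, psi=psi, P=p, U=u,
        lambda1=lam1, lambda2=lam2, W=u.T @ p,
    )


def project(epoch: Epoch | np.ndarray, model: CSPModel | np.ndarray) -> np.ndarray:
    """Apply the spatial filters: ``W @ X`` for a channels x samples epoch.

    One filtered time series per row; equivalent to the column-wise form
    ``XᵀWᵀ`` up to transposition.
    """
    w = model.W if isinstance(model, CSPModel) else np.asarray(model, float)
    d = _epoch_data(epoch)
    if d.shape[0] != w.shape[1]:
        raise ValueError(
            f"epoch has {d.shape[0]} channels but the model expects {w.shape[1]}"
        )
    return w @ d


def log_variance_features(projected: np.ndarray) -> np.ndarray:
    """Natural log of each filtered row's sample variance (length-N vector)."""
    p = np.asarray(projected, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("projected matrix needs >= 2 samples per row")
    var = p.var(axis=1, ddof=1)
    if np.any(var <= 0):
        raise DegenerateInputError(
            f"zero-variance projected row(s) {np.flatnonzero(var <= 0).tolist()}"
        )
    return np.log(var)


def epoch_features(epochs, model: CSPModel) -> np.ndarray:
    """Feature matrix (n_epochs x n_channels) for a sequence of epochs."""
    return np.array(
        [log_variance_features(project(ep, model)) for ep in epochs]
    )
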