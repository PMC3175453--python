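"""Second-order blind source separation (TDSEP).

The decomposition chain is: mean removal -> PCA to k dimensions -> whitening
(so the zero-lag covariance is the identity) -> joint diagonalization of a
set of symmetrized time-lagged cross-covariance matrices by Jacobi rotation
sweeps.  Because mutually independent sources have diagonal lagged
cross-covariances, the orthogonal matrix that jointly diagonalizes the
whitened lagged covariances recovers the sources up to permutation, sign and
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import Decomposition, EEGRecording, IcacleanError

DEFAULT_N_COMPONENTS = 30
DEFAULT_LAGS = tuple(range(1, 100))
JACOBI_TOL = 1e-8          # radians; rotations smaller than this are skipped
JACOBI_MAX_SWEEPS = 100


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class LaggedCovarianceSet:
    """Symmetrized lag-tau cross-covariances of whitened data."""

    lags: tuple[int, ...]
    matrices: np.ndarray     # n_lags x k x k

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be n_lags x k x k")
        if not np.allclose(self.matrices, np.transpose(self.matrices, (0, 2, 1)),
                           atol=1e-10):
            raise ValueError("lagged covariance matrices must be symmetric")
        for lag, mat in zip(self.lags, self.matrices):
            if lag == 0 and not np.allclose(mat, np.eye(mat.shape[0]), atol=1e-8):
                raise ValueError("the lag-0 matrix of whitened data must be I")


# ---------------------------------------------------------------------------
# PCA and whitening
# ---------------------------------------------------------------------------

def pca_reduce(rec: EEGRecording, k: int = DEFAULT_N_COMPONENTS
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-``k`` principal component scores of the mean-centered recording.

    Returns ``(basis, reduced, eigenvalues)`` where ``basis`` is channels x k
    (orthonormal columns, for back-projection), ``reduced`` is k x samples and
    the eigenvalues are sorted descending.
    """
    if k > rec.n_channels:
        raise ValueError(f"k={k} exceeds channel count {rec.n_channels}")
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / (rec.n_samples - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-12)) if evals[0] > 0 else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    basis = evecs[:, :k]
    return basis, basis.T @ x, evals[:k]


def whiten(reduced: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decorrelate and rescale so the sample covariance becomes the identity.

    Returns ``(whitened, whitening, dewhitening)`` with
    ``whitening @ dewhitening = I``.
    """
    reduced = np.asarray(reduced, dtype=float)
    x = reduced - reduced.mean(axis=1, keepdims=True)
    n = x.shape[1]
    cov = (x @ x.T) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) < np.max(evals) * 1e-12:
        raise IcacleanError(
            "covariance is singular after reduction; use a smaller k"
        )
    whitening = (evecs / np.sqrt(evals)) @ evecs.T      # symmetric (ZCA) form
    dewhitening = (evecs * np.sqrt(evals)) @ evecs.T
    return whitening @ x, whitening, dewhitening


def lagged_cross_covariances(whitened: np.ndarray,
                             lags: tuple[int, ...] = DEFAULT_LAGS
                             ) -> LaggedCovarianceSet:
    """Symmetrized cross-covariances (C(tau) + C(tau)^T)/2 over the overlap."""
    x = np.asarray(whitened, dtype=float)
    n = x.shape[1]
    mats = []
    for lag in lags:
        if lag >= n:
            raise ValueError(f"lag {lag} >= number of samples {n}")
        if lag == 0:
            c = (x @ x.T) / (n - 1)
        else:
            c = (x[:, :-lag] @ x[:, lag:].T) / (n - lag - 1)
        mats.append(0.5 * (c + c.T))
    return LaggedCovarianceSet(lags=tuple(lags), matrices=np.array(mats))


# ---------------------------------------------------------------------------
# Joint diagonalization
# ---------------------------------------------------------------------------

def offdiagonal_cost(matrices: np.ndarray, V: np.ndarray | None = None) -> float:
    """Sum of squared off-diagonal entries of V^T M V over the set."""
    mats = np.asarray(matrices, dtype=float)
    if V is not None:
        mats = np.einsum("ip,kij,jq->kpq", V, mats, V)
    k = mats.shape[1]
    mask = ~np.eye(k, dtype=bool)
    return float(np.sum(mats[:, mask] ** 2))


def joint_diagonalize(cov_set: LaggedCovarianceSet,
                      tol: float = JACOBI_TOL,
                      max_sweeps: int = JACOBI_MAX_SWEEPS) -> np.ndarray:
    """Orthogonal V minimizing the joint off-diagonal cost (Jacobi sweeps).

    Each sweep visits every index pair (p, q) and applies the closed-form
    optimal plane rotation for that pair; the off-diagonal cost is
    non-increasing per rotation.  Iteration stops once every rotation angle
    in a sweep is below ``tol`` radians or after ``max_sweeps`` sweeps.
    """
    mats = np.array(cov_set.matrices, dtype=float, copy=True)
    if not np.allclose(mats, np.transpose(mats, (0, 2, 1)), atol=1e-10):
        raise ValueError("joint_diagonalize requires symmetric matrices")
    k = mats.shape[1]
    V = np.eye(k)
    if k < 2:
        return V
    for _ in range(max_sweeps):
        max_angle = 0.0
        for p in range(k - 1):
            for q in range(p + 1, k):
                # Optimal Jacobi angle for symmetric joint diagonalization:
                # principal eigenvector of the 2x2 Gram matrix of
                # h = (M_pp - M_qq, 2 M_pq) over the set.
                hp = mats[:, p, p] - mats[:, q, q]
                hq = 2.0 * mats[:, p, q]
                g11 = float(hp @ hp)
                g22 = float(hq @ hq)
                g12 = float(hp @ hq)
                # principal eigenvector (x, y) of [[g11,g12],[g12,g22]]
                diff = g11 - g22
                r = np.hypot(diff, 2.0 * g12)
                x = diff + r
                y = 2.0 * g12
                norm = np.hypot(x, y)
                if norm < 1e-300:
                    continue
                x, y = x / norm, y / norm
                # ensure x >= 0 so the rotation is the small-angle one
                if x < 0:
                    x, y = -x, -y
                rr = np.hypot(x, y)
                c = np.sqrt((x + rr) / (2.0 * rr))
                s = y / np.sqrt(2.0 * rr * (x + rr))
                theta = np.arctan2(s, c)
                if abs(theta) <= tol:
                    continue
                max_angle = max(max_angle, abs(theta))
                rot_p = c * mats[:, :, p] + s * mats[:, :, q]
                rot_q = -s * mats[:, :, p] + c * mats[:, :, q]
                mats[:, :, p], mats[:, :, q] = rot_p, rot_q
                rot_p = c * mats[:, p, :] + s * mats[:, q, :]
                rot_q = -s * mats[:, p, :] + c * mats[:, q, :]
                mats[:, p, :], mats[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if max_angle <= tol:
            break
    else:
        warnings.warn(
            f"joint diagonalization did not converge in {max_sweeps} sweeps; "
            f"final off-diagonal cost {offdiagonal_cost(mats):.3e}",
            ConvergenceWarning,
        )
    return V


# ---------------------------------------------------------------------------
# Full decomposition
# ---------------------------------------------------------------------------

def tdsep(rec: EEGRecording, k: int = DEFAULT_N_COMPONENTS,
          lags: tuple[int, ...] = DEFAULT_LAGS) -> Decomposition:
    """Decompose a recording into ``k`` temporally decorrelated sources.

    Composes PCA reduction, whitening, lagged covariance estimation and joint
    diagonalization.  Components are ordered by descending impact on the
    recording, measured as Var(std(pattern) * source).
    """
    k = min(k, rec.n_channels)
    basis, reduced, _ = pca_reduce(rec, k)
    whitened, whitening, _ = whiten(reduced)
    cov_set = lagged_cross_covariances(whitened, lags)
    V = joint_diagonalize(cov_set)

    W = V.T @ whitening                   # PCA space -> sources
    A = np.linalg.inv(W)
    sources = W @ (reduced - reduced.mean(axis=1, keepdims=True))
    patterns = basis @ A                  # sensor-space patterns (columns)
    filters = W @ basis.T                 # sensor-space filters (rows)

    impact = np.std(patterns, axis=0) ** 2 * np.var(sources, axis=1)
    order = np.argsort(impact)[::-1]
    # fix signs so the largest-magnitude pattern entry is positive
    signs = np.sign(patterns[np.argmax(np.abs(patterns), axis=0),
                             np.arange(k)])
    signs[signs == 0] = 1.0

    W = (W[order, :].T / signs[order]).T
    A = A[:, order] * signs[order]
    return Decomposition(
        n_components=k,
        pca_basis=basis,
        mean=rec.data.mean(axis=1),
        W=W, A=A,
        patterns=patterns[:, order] * signs[order],
        filters=(filters[order, :].T / signs[order]).T,
        sources=sources[order, :] / signs[order][:, None],
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )
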