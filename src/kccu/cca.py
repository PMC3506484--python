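"""Classical canonical correlation analysis between two SNP-set matrices.

Finds weight vectors nu, omega maximizing corr(X nu, Y omega) under the
unit-norm constraints nu' X'X nu = omega' Y'Y omega = 1 on column-centred
matrices.  Solved by singular value decomposition of the whitened
cross-product matrix, with pseudo-inverse whitening so SNP sets with
collinear columns (perfect LD) do not crash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["CanonicalResult", "center_columns", "cca_first"]

# relative singular-value cutoff for pseudo-inverse whitening
_RCOND = 1e-10


@dataclass
class CanonicalResult:
    """First canonical pair: correlation, weight vectors and score variates.

    ``r`` is the maximum canonical coefficient in [0, 1]; ``left_vector``
    (length p) and ``right_vector`` (length q) are scaled so the variates
    ``a = X @ left_vector`` and ``b = Y @ right_vector`` have unit norm.
    ``correlations`` carries the full spectrum for diagnostics; only the
    first feeds the co-association statistic.
    """

    r: float
    left_vector: np.ndarray
    right_vector: np.ndarray
    a: np.ndarray
    b: np.ndarray
    correlations: np.ndarray


def center_columns(M: np.ndarray) -> np.ndarray:
    """Subtract each column's mean; shape is preserved."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    return M - M.mean(axis=0, keepdims=True)


def _invsqrt_psd(S: np.ndarray, rcond: float = _RCOND) -> np.ndarray:
    """Pseudo-inverse square root of a symmetric PSD matrix."""
    w, V = linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    cut = w.max(initial=0.0) * rcond
    inv = np.where(w > cut, 1.0 / np.sqrt(np.where(w > cut, w, 1.0)), 0.0)
    return (V * inv) @ V.T


def cca_first(X: np.ndarray, Y: np.ndarray) -> CanonicalResult:
    """First canonical correlation and vectors between centred X and Y.

    Raises on a row-count mismatch or a zero-variance column (QC is expected
    to have removed those).  The sign convention makes r >= 0 and the first
    nonzero entry of the left vector positive.
    """
    X = center_columns(X)
    Y = center_columns(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    for name, M in (("X", X), ("Y", Y)):
        if (np.ptp(M, axis=0) == 0).any():
            raise ValueError(f"{name} has a zero-variance column")

    Sxx = X.T @ X
    Syy = Y.T @ Y
    Sxy = X.T @ Y
    Wx = _invsqrt_psd(Sxx)
    Wy = _invsqrt_psd(Syy)
    U, s, Vt = linalg.svd(Wx @ Sxy @ Wy)
    s = np.clip(s, 0.0, 1.0)
    nu = Wx @ U[:, 0]
    om = Wy @ Vt[0]

    nz = np.flatnonzero(np.abs(nu) > 1e-12)
    if nz.size and nu[nz[0]] < 0:
        nu, om = -nu, -om
    a = X @ nu
    b = Y @ om
    return CanonicalResult(float(s[0]), nu, om, a, b, s)
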