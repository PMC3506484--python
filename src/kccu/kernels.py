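"""Kernel Gram matrices and regularized kernel canonical correlation.

Kernel CCA maps each individual's genotype vector for a gene into a
feature space and runs CCA on the feature images, using only the m x m
Gram matrices K_x, K_y.  Without regularization the optimum is degenerate
(a correlation of exactly 1 whenever the Gram matrices are invertible),
so the constraints are penalized quadratically: maximize a' K_x K_y b
subject to a'(K_x + eta I)^2 a = b'(K_y + eta I)^2 b = 1.  In the linear-
kernel, small-eta limit this reproduces classical CCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .genotype_data import GenotypeMatrix

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "compute_gram",
    "center_gram",
    "kcca_max_correlation",
    "default_eta",
]

_FAMILIES = ("linear", "polynomial", "rbf", "sigmoid", "ibs", "weighted_ibs")

# relative eigenvalue cutoff for the low-rank reduction of a Gram matrix
_RANK_TOL = 1e-6


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family with its parameters.

    ``sigma`` is the RBF bandwidth multiplier, k(u, v) = exp(-sigma ||u-v||^2),
    parameterized so a sweep over sigma in {0.05, 0.5, 5, 50} is direct.
    ``eta`` is the KCCA regularization; ``None`` selects the data-driven
    default ``0.1 * m * mean(diag K)`` at solve time.
    """

    family: str = "rbf"
    sigma: float = 0.5
    degree: int = 2
    offset: float = 1.0
    scale: float = 1.0
    eta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unsupported kernel family {self.family!r}")
        if self.family == "rbf" and self.sigma <= 0:
            raise ValueError("rbf kernel needs sigma > 0")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.eta is not None and self.eta < 0:
            raise ValueError("regularization eta must be >= 0")


@dataclass
class GramMatrix:
    """Symmetric PSD kernel matrix over individuals, with its spec."""

    values: np.ndarray
    spec: KernelSpec
    centred: bool = False
    snp_mafs: np.ndarray | None = field(default=None, repr=False)
    #: mean of the uncentred kernel diagonal, kept through centering so the
    #: default regularization does not depend on when it is computed
    mean_diag: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.shape != (m, m):
            raise ValueError("Gram matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("Gram matrix must be symmetric")

    @property
    def m(self) -> int:
        return self.values.shape[0]


def kernel_function(U: np.ndarray, V: np.ndarray, spec: KernelSpec,
                    mafs: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the kernel between every row of U and every row of V."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    fam = spec.family
    if fam == "linear":
        return U @ V.T
    if fam == "polynomial":
        return (U @ V.T + spec.offset) ** spec.degree
    if fam == "rbf":
        d2 = (
            np.sum(U * U, axis=1)[:, None]
            + np.sum(V * V, axis=1)[None, :]
            - 2.0 * (U @ V.T)
        )
        return np.exp(-spec.sigma * np.maximum(d2, 0.0))
    if fam == "sigmoid":
        return np.tanh(spec.scale * (U @ V.T) + spec.offset)
    if fam in ("ibs", "weighted_ibs"):
        # allele-sharing similarity: per SNP (2 - |u - v|) / 2
        share = 2.0 - np.abs(U[:, None, :] - V[None, :, :])
        if fam == "weighted_ibs":
            if mafs is None:
                raise ValueError("weighted_ibs kernel needs per-SNP MAFs")
            w = 1.0 / np.sqrt(np.asarray(mafs, dtype=float))
            return (share * w).sum(axis=2) / (2.0 * w.sum())
        return share.sum(axis=2) / (2.0 * U.shape[1])
    raise ValueError(f"unsupported kernel family {fam!r}")


def compute_gram(G: GenotypeMatrix, spec: KernelSpec) -> GramMatrix:
    """Kernel Gram matrix between all individuals of a (post-QC) gene matrix."""
    if not np.isfinite(G.values).all():
        raise ValueError("genotype matrix contains missing values; run qc_filter")
    mafs = np.array([s.minor_allele_freq for s in G.snps])
    K = kernel_function(G.values, G.values, spec, mafs)
    return GramMatrix(
        K, spec, centred=False, snp_mafs=mafs, mean_diag=float(K.diagonal().mean())
    )


def center_gram(K: GramMatrix) -> GramMatrix:
    """Doubly centre a Gram matrix (K <- HKH, H = I - 11'/m).

    Equivalent to centering the feature images so KCCA sees mean-zero
    features, as CCA assumes for its inputs.  Idempotent.
    """
    Kv = K.values
    rm = Kv.mean(axis=0, keepdims=True)
    Kc = Kv - rm - rm.T + rm.mean()
    return replace(K, values=Kc, centred=True)


def default_eta(m: int, mean_diag: float) -> float:
    """Default KCCA regularization, 0.1 * m * (mean Gram diagonal)."""
    return 0.1 * m * mean_diag


def _reduce_gram(Kc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a centred Gram, keeping eigenvalues above tolerance."""
    lam, Q = linalg.eigh(Kc)
    keep = lam > max(lam.max(initial=0.0), 0.0) * _RANK_TOL
    return lam[keep], Q[:, keep]


def kcca_max_correlation(
    K_x: GramMatrix, K_y: GramMatrix, eta: float | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximum kernel canonical coefficient with expansion coefficients.

    Both Gram matrices must already be centred and of equal size.  Returns
    ``(kr, alpha, beta)`` where kr in [0, 1] is the largest eigenvalue of the
    regularized problem and alpha, beta satisfy the penalized unit
    constraints a'(K + eta I)^2 a = 1.

    With eta = 0 and numerically full-rank Gram matrices the problem is
    degenerate (kr ~ 1); a warning is emitted in that case.
    """
    if not (K_x.centred and K_y.centred):
        raise ValueError("Gram matrices must be centred (center_gram) first")
    if K_x.m != K_y.m:
        raise ValueError("Gram matrices differ in size")
    m = K_x.m
    if eta is None:
        eta = K_x.spec.eta
    if eta is None:
        mdx = K_x.mean_diag if K_x.mean_diag is not None else float(np.trace(K_x.values)) / m
        mdy = K_y.mean_diag if K_y.mean_diag is not None else float(np.trace(K_y.values)) / m
        eta_x, eta_y = default_eta(m, mdx), default_eta(m, mdy)
    else:
        eta_x = eta_y = float(eta)

    lx, Qx = _reduce_gram(K_x.values)
    ly, Qy = _reduce_gram(K_y.values)
    if eta_x == 0.0 and eta_y == 0.0 and min(lx.size, ly.size) >= m - 1:
        warnings.warn(
            "eta = 0 with full-rank Gram matrices: kernel CCA is degenerate "
            "(correlation ~ 1)"
        )

    dx = lx / (lx + eta_x)
    dy = ly / (ly + eta_y)
    C = (dx[:, None] * (Qx.T @ Qy)) * dy[None, :]
    U, s, Vt = linalg.svd(C)
    kr = float(np.clip(s[0], 0.0, 1.0))
    alpha = Qx @ (U[:, 0] / (lx + eta_x))
    beta = Qy @ (Vt[0] / (ly + eta_y))
    return kr, alpha, beta
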