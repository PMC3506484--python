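"""Pattern-compressed (kernel) canonical-correlation evaluator.

Genotype rows over a gene take few distinct values (bounded by the number of
haplotype pairs in the source population), so the m x m Gram matrix of a
stratum is fully determined by the kernel on the unique genotype patterns and
the pattern counts.  This module exploits that: a stratum is summarized once
into unique patterns per gene plus joint-pattern counts, after which each
(kernel) canonical-correlation evaluation — including every bootstrap
resample, which is just a multinomial redraw of the joint counts — costs
O(u^3) for u unique patterns instead of O(m^3).

The nonzero spectrum of the weighted centred Gram H_w K H_w equals that of
the small matrix  diag(sqrt c) Mc diag(sqrt c)  with Mc the weighted-centred
pattern kernel, and the cross term Q_x' Q_y reduces to the count-normalized
joint-pattern table.  This path is exact (same rank tolerance as the dense
solver), not an approximation; agreement is enforced by tests.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .cca import _invsqrt_psd
from .kernels import KernelSpec, default_eta, kernel_function

_RANK_TOL = 1e-6


class StratumEngine:
    """Repeated-evaluation engine for one stratum's two gene matrices.

    Parameters
    ----------
    A, B : arrays (m x p, m x q)
        Complete dosage matrices, rows aligned on the same individuals.
    engine : {"cca", "kcca"}
        Classical first canonical correlation, or the regularized kernel one.
    spec : KernelSpec
        Kernel family/parameters (kcca only).
    """

    def __init__(
        self,
        A: np.ndarray,
        B: np.ndarray,
        engine: str = "kcca",
        spec: KernelSpec | None = None,
        mafs_A: np.ndarray | None = None,
        mafs_B: np.ndarray | None = None,
    ) -> None:
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        if A.shape[0] != B.shape[0]:
            raise ValueError("A and B must cover the same individuals")
        if engine not in ("cca", "kcca"):
            raise ValueError(f"unknown engine {engine!r}")
        self.engine = engine
        self.spec = spec if spec is not None else KernelSpec()
        self.m = A.shape[0]

        self.UA, iA = np.unique(A, axis=0, return_inverse=True)
        self.UB, iB = np.unique(B, axis=0, return_inverse=True)
        self.uA, self.uB = len(self.UA), len(self.UB)
        code = iA.astype(np.int64) * self.uB + iB.astype(np.int64)
        ucode, counts = np.unique(code, return_counts=True)
        self.ja = (ucode // self.uB).astype(np.intp)
        self.jb = (ucode % self.uB).astype(np.intp)
        self.flat = (self.ja * self.uB + self.jb).astype(np.intp)
        self.base_counts = counts.astype(float)

        if engine == "kcca":
            self.KuA = kernel_function(self.UA, self.UA, self.spec, mafs_A)
            self.KuB = kernel_function(self.UB, self.UB, self.spec, mafs_B)

    def joint_probs(self) -> np.ndarray:
        return self.base_counts / self.m

    def _gene_counts(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cA = np.bincount(self.ja, weights=counts, minlength=self.uA)
        cB = np.bincount(self.jb, weights=counts, minlength=self.uB)
        return cA, cB

    def degenerate(self, counts: np.ndarray) -> bool:
        """True if either gene has an all-constant column under these counts."""
        cA, cB = self._gene_counts(counts)
        for U, c in ((self.UA, cA), (self.UB, cB)):
            sub = U[c > 0]
            if (sub.max(axis=0) == sub.min(axis=0)).any():
                return True
        return False

    def corr(self, counts: np.ndarray | None = None) -> float:
        """First (kernel) canonical correlation under the given pattern counts."""
        if counts is None:
            counts = self.base_counts
        m = counts.sum()
        cA, cB = self._gene_counts(counts)
        P = np.bincount(self.flat, weights=counts, minlength=self.uA * self.uB)
        P = P.reshape(self.uA, self.uB)
        if self.engine == "cca":
            return self._corr_cca(m, cA, cB, P)
        return self._corr_kcca(m, cA, cB, P)

    def _corr_cca(self, m, cA, cB, P) -> float:
        wA, wB = cA / m, cB / m
        meanA = wA @ self.UA
        meanB = wB @ self.UB
        SAA = (self.UA * wA[:, None]).T @ self.UA - np.outer(meanA, meanA)
        SBB = (self.UB * wB[:, None]).T @ self.UB - np.outer(meanB, meanB)
        SAB = self.UA.T @ (P / m) @ self.UB - np.outer(meanA, meanB)
        M = _invsqrt_psd(SAA) @ SAB @ _invsqrt_psd(SBB)
        s = linalg.svdvals(M)
        return float(np.clip(s[0], 0.0, 1.0))

    def _side(self, Ku, c, m, eta):
        """Eigenbasis of the weighted centred Gram restricted to active patterns."""
        act = c > 0
        K = Ku[np.ix_(act, act)]
        ca = c[act]
        w = ca / m
        kw = K @ w
        Mc = K - kw[:, None] - kw[None, :] + w @ kw
        s = np.sqrt(ca)
        N = Mc * s[:, None] * s[None, :]
        lam, V = np.linalg.eigh(N)
        keep = lam > max(lam[-1], 0.0) * _RANK_TOL
        lam, V = lam[keep], V[:, keep]
        if eta is None:
            eta = default_eta(m, float(ca @ K.diagonal()) / m)
        d = lam / (lam + eta)
        return act, s, V, d

    def _corr_kcca(self, m, cA, cB, P) -> float:
        eta = self.spec.eta
        actA, sA, VA, dA = self._side(self.KuA, cA, m, eta)
        actB, sB, VB, dB = self._side(self.KuB, cB, m, eta)
        R = P[np.ix_(actA, actB)] / sA[:, None] / sB[None, :]
        C = (dA[:, None] * (VA.T @ R @ VB)) * dB[None, :]
        s = linalg.svdvals(C)
        return float(np.clip(s[0] if s.size else 0.0, 0.0, 1.0))
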