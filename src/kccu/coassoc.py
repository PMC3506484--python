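"""CCU and KCCU gene-gene co-association statistics.

The co-association of two genes is measured by the first (kernel) canonical
correlation between their SNP matrices, computed separately in cases (kr_D)
and controls (kr_C).  Each is Fisher-transformed,
``kz = 1/2 [log(1 + kr) - log(1 - kr)]``, the variance of each transformed
coefficient is estimated by bootstrap over individuals, and the test
statistic is

    U = (kz_D - kz_C) / sqrt(var(kz_D) + var(kz_C)),

approximately standard normal under the null of equal co-association.  A
permutation alternative rebuilds the null by shuffling case/control labels.
A pairwise logistic-regression comparator (minimum interaction-term p value
over SNP pairs) is provided for the single-SNP-based contrast.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._engine import StratumEngine
from .genotype_data import CaseControlSplit, GenotypeMatrix
from .kernels import KernelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CoAssociationResult",
    "MinPResult",
    "fisher_z",
    "bootstrap_var_z",
    "co_association_test",
    "permutation_pvalue",
    "pairwise_logistic_minp",
    "pairwise_minp_permutation",
]

_CLIP = 1.0 - 1e-12


@dataclass
class CoAssociationResult:
    """Full output of a CCU/KCCU test for one gene pair."""

    kr_cases: float
    kr_controls: float
    z_cases: float
    z_controls: float
    var_z_cases: float
    var_z_controls: float
    U: float
    p_value: float
    method: str
    n_bootstrap: int
    kernel: KernelSpec | None = None


@dataclass
class MinPResult:
    """Minimum pairwise logistic interaction p value and the attaining pair."""

    min_p: float
    best_pair: tuple[str, str]
    pair_pvalues: dict[tuple[str, str], float]


def fisher_z(r: float) -> float:
    """Fisher transformation z = 1/2 ln((1+r)/(1-r)) of a correlation in [0, 1).

    Values within 1e-12 of 1 are clipped (with a warning) so the transform
    stays finite; values outside [0, 1] beyond tolerance are an error.
    """
    r = float(r)
    if r < -1e-12 or r > 1.0 + 1e-9:
        raise ValueError(f"correlation {r} outside [0, 1)")
    if r >= _CLIP:
        warnings.warn("correlation at or above 1 - 1e-12; clipping before Fisher z")
        r = _CLIP
    r = max(r, 0.0)
    return float(np.arctanh(r))


def _engine_name(method: str) -> str:
    try:
        return {"ccu": "cca", "kccu": "kcca", "cca": "cca", "kcca": "kcca"}[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; use 'ccu' or 'kccu'") from None


def _mafs(G: GenotypeMatrix) -> np.ndarray:
    return np.array([s.minor_allele_freq for s in G.snps])


def _stratum_seed(seed: int, *matrices: GenotypeMatrix) -> np.random.SeedSequence:
    """Sub-seed derived from the master seed and the stratum's data bytes.

    Keying on content (not on case/control role) makes the bootstrap stream a
    function of the data, so exchanging the two strata reproduces each
    stratum's variance estimate exactly and U changes sign bit-exactly.
    """
    crc = 0
    for G in matrices:
        crc = zlib.crc32(np.ascontiguousarray(G.values).tobytes(), crc)
    return np.random.SeedSequence([int(seed) % 2**31, crc % 2**31])


def bootstrap_var_z(
    G_A: GenotypeMatrix,
    G_B: GenotypeMatrix,
    engine: str = "kcca",
    spec: KernelSpec | None = None,
    B: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Bootstrap variance of the Fisher-transformed canonical coefficient.

    Individuals are resampled with replacement jointly for the two genes
    (equivalently: a multinomial redraw of the joint genotype-pattern
    counts), the first (kernel) canonical correlation is recomputed and
    Fisher-transformed for each of the B resamples, and the sample variance
    of the B values is returned together with the point estimate on the
    original data.  Resamples in which either gene collapses to an
    all-constant column are redrawn; more than 10*B redraws is an error.
    """
    if B < 2:
        raise ValueError("need at least B = 2 bootstrap replicates")
    engine = _engine_name(engine)
    eng = StratumEngine(
        G_A.values, G_B.values, engine, spec, mafs_A=_mafs(G_A), mafs_B=_mafs(G_B)
    )
    z_hat = fisher_z(eng.corr())
    rng = np.random.default_rng(seed)
    probs = eng.joint_probs()
    zs = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            counts = rng.multinomial(eng.m, probs).astype(float)
            if not eng.degenerate(counts):
                break
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError(
                    f"bootstrap exceeded {10 * B} degenerate redraws; "
                    "data too sparse for resampling"
                )
        zs[b] = fisher_z(eng.corr(counts))
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    return float(np.var(zs, ddof=1)), z_hat


def co_association_test(
    split: CaseControlSplit,
    method: str = "kccu",
    spec: KernelSpec | None = None,
    B: int = 200,
    seed: int = 0,
) -> CoAssociationResult:
    """CCU or KCCU test of differential gene-gene co-association.

    Computes the first (kernel) canonical correlation in each stratum,
    Fisher-transforms, estimates each stratum's variance by bootstrap with
    independently derived sub-seeds, and returns the two-sided standard
    normal p value of U.

    Both variants run through the regularized kernel solver: ``kccu`` with
    the supplied kernel (RBF by default), ``ccu`` with the linear kernel —
    the form in which the linear statistic is computed in practice (kernel
    CCA software regularizes even the linear case).  An unregularized
    maximal canonical correlation is a boundary statistic whose bootstrap
    variance is inflated under the null, which makes the unregularized test
    markedly conservative; the regularized linear form does not suffer from
    this and recovers classical CCA as the regularization vanishes.
    """
    method = "ccu" if _engine_name(method) == "cca" else "kccu"
    if method == "ccu":
        spec_used = KernelSpec(
            family="linear", eta=spec.eta if spec is not None else None
        )
    else:
        spec_used = spec if spec is not None else KernelSpec()
    var_D, z_D = bootstrap_var_z(
        split.cases_A, split.cases_B, "kcca", spec_used, B,
        seed=_stratum_seed(seed, split.cases_A, split.cases_B),
    )
    var_C, z_C = bootstrap_var_z(
        split.controls_A, split.controls_B, "kcca", spec_used, B,
        seed=_stratum_seed(seed, split.controls_A, split.controls_B),
    )
    tot = var_D + var_C
    if tot == 0.0:
        raise ValueError(
            "both bootstrap variances are zero (degenerate strata); "
            "p value undefined"
        )
    U = (z_D - z_C) / np.sqrt(tot)
    p = float(min(2.0 * stats.norm.sf(abs(U)), 1.0))
    return CoAssociationResult(
        kr_cases=float(np.tanh(z_D)),
        kr_controls=float(np.tanh(z_C)),
        z_cases=z_D,
        z_controls=z_C,
        var_z_cases=var_D,
        var_z_controls=var_C,
        U=float(U),
        p_value=p,
        method=method,
        n_bootstrap=B,
        kernel=spec if method == "kccu" else None,
    )


def _reassemble(split: CaseControlSplit) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    A = GenotypeMatrix(
        np.vstack([split.cases_A.values, split.controls_A.values]),
        list(split.cases_A.snps),
        list(split.cases_A.sample_ids) + list(split.controls_A.sample_ids),
    )
    B = GenotypeMatrix(
        np.vstack([split.cases_B.values, split.controls_B.values]),
        list(split.cases_B.snps),
        list(split.cases_B.sample_ids) + list(split.controls_B.sample_ids),
    )
    return A, B


def permutation_pvalue(
    split: CaseControlSplit,
    method: str = "kccu",
    spec: KernelSpec | None = None,
    B: int = 200,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Permutation p value for |U| under case/control label shuffling.

    Stratum sizes are preserved; the add-one estimator
    (1 + #{|U_perm| >= |U_obs|}) / (1 + n_valid) never returns zero.
    Permutations whose test fails are dropped and logged.
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    obs = abs(co_association_test(split, method, spec, B, seed).U)
    G_A, G_B = _reassemble(split)
    m, n_cases = G_A.n_samples, split.n_cases
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x9E37]))
    exceed = 0
    n_valid = 0
    for _ in range(n_perm):
        order = rng.permutation(m)
        case_idx, ctrl_idx = order[:n_cases], order[n_cases:]
        perm_split = CaseControlSplit(
            G_A.take_samples(case_idx),
            G_B.take_samples(case_idx),
            G_A.take_samples(ctrl_idx),
            G_B.take_samples(ctrl_idx),
        )
        try:
            u = abs(co_association_test(perm_split, method, spec, B, seed).U)
        except (ValueError, RuntimeError) as exc:
            logger.info("dropped failed permutation: %s", exc)
            continue
        n_valid += 1
        if u >= obs:
            exceed += 1
    if n_valid == 0:
        raise RuntimeError("all permutations failed")
    return (1 + exceed) / (1 + n_valid)


def _interaction_pvalue(a: np.ndarray, b: np.ndarray, y: np.ndarray) -> float:
    """Wald p value for the product term in logit(P) = b0 + b1 A + b2 B + g AB."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(a), a, b, a * b])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("no convergence")
        p = float(fit.pvalues[3])
        if not np.isfinite(p):
            raise RuntimeError("non-finite p")
        return p
    except Exception as exc:  # separation, singular Hessian, ...
        logger.info("logistic pair fit failed (%s); p set to 1", exc)
        return 1.0


def pairwise_logistic_minp(
    G_A: GenotypeMatrix, G_B: GenotypeMatrix, phenotype: np.ndarray
) -> MinPResult:
    """Minimum interaction p value over all cross-gene SNP pairs.

    For every pair (one SNP per gene) a logistic model with a product term
    is fit and the Wald p value of the product coefficient recorded; the
    smallest p and the attaining pair are returned.  Non-converging pairs
    score p = 1.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != G_A.n_samples or y.shape[0] != G_B.n_samples:
        raise ValueError("phenotype length does not match genotype matrices")
    pvals: dict[tuple[str, str], float] = {}
    for i, sa in enumerate(G_A.snps):
        for j, sb in enumerate(G_B.snps):
            pvals[(sa.id, sb.id)] = _interaction_pvalue(
                G_A.values[:, i], G_B.values[:, j], y
            )
    best = min(pvals, key=pvals.get)
    return MinPResult(pvals[best], best, pvals)


def pairwise_minp_permutation(
    G_A: GenotypeMatrix,
    G_B: GenotypeMatrix,
    phenotype: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Permutation p value of the pairwise min-p statistic (add-one estimator)."""
    y = np.asarray(phenotype, dtype=int)
    obs = pairwise_logistic_minp(G_A, G_B, y).min_p
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x51]))
    exceed = 0
    for _ in range(n_perm):
        perm = pairwise_logistic_minp(G_A, G_B, rng.permutation(y)).min_p
        if perm <= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
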