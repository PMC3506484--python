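"""Two-locus case-control genotype simulator.

Emulates the classic study design for gene-based interaction testing: two
unlinked gene regions are represented by weighted haplotype pools with
realistic minor-allele frequencies and adjacent-SNP linkage disequilibrium;
individuals are formed by random union of two haplotypes per region; disease
status follows a two-locus multiplicative penetrance model

    P(disease | x1, x2) = f0 * r1^x1 * r2^x2 * theta^(x1 * x2)

with x1, x2 the dosages at one causal SNP per region and theta the
interaction odds ratio (theta = 1 is the null of no interaction).  The
causal SNPs are removed from the output, so any case-control difference in
the remaining SNPs arises only through linkage disequilibrium with the
causal pair — the signal a gene-based co-association test must detect.

The synthetic haplotype pool is built from a first-order binary Markov
chain over alleles, which gives exact analytic control of per-SNP MAF and
adjacent-pair r^2; realized values are verified against targets after the
pool is truncated to its most frequent haplotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_data import CaseControlSplit, GenotypeMatrix, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "SimulatedDataset",
    "build_pool",
    "write_pool",
    "draw_genotypes",
    "simulate_case_control",
    "default_pools",
    "DEFAULT_MODEL",
]

MAF_TOL = 0.02
R2_TOL = 0.10


@dataclass
class HaplotypePool:
    """Weighted pool of phased haplotypes for one gene region."""

    haplotypes: np.ndarray  # H x p, 0/1 minor-allele indicators
    frequencies: np.ndarray  # length H, sums to 1
    snps: list[SnpRecord]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        H, p = self.haplotypes.shape
        if H < 2:
            raise ValueError("a haplotype pool needs at least 2 haplotypes")
        if len(self.frequencies) != H or len(self.snps) != p:
            raise ValueError("inconsistent pool dimensions")
        if (self.frequencies < 0).any() or abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype weights must be nonnegative and sum to 1")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        return self.frequencies @ self.haplotypes

    def r2(self, i: int, j: int) -> float:
        """Haplotype-frequency r^2 between SNPs i and j."""
        pa = float(self.frequencies @ self.haplotypes[:, i])
        pb = float(self.frequencies @ self.haplotypes[:, j])
        pab = float(self.frequencies @ (self.haplotypes[:, i] * self.haplotypes[:, j]))
        denom = pa * (1 - pa) * pb * (1 - pb)
        if denom == 0:
            return float("nan")
        return (pab - pa * pb) ** 2 / denom

    def genotype_catalog(self) -> tuple[np.ndarray, np.ndarray]:
        """All attainable dosage patterns with their random-union probabilities."""
        H = len(self.frequencies)
        ii, jj = np.meshgrid(np.arange(H), np.arange(H), indexing="ij")
        dosages = self.haplotypes[ii.ravel()] + self.haplotypes[jj.ravel()]
        probs = np.outer(self.frequencies, self.frequencies).ravel()
        patterns, inv = np.unique(dosages, axis=0, return_inverse=True)
        agg = np.bincount(inv, weights=probs, minlength=len(patterns))
        return patterns.astype(np.int8), agg

    def drop_snp(self, index: int) -> "HaplotypePool":
        keep = [j for j in range(self.n_snps) if j != index]
        return HaplotypePool(
            self.haplotypes[:, keep],
            self.frequencies,
            [self.snps[j] for j in keep],
        )


@dataclass(frozen=True)
class DiseaseModel:
    """Two-locus multiplicative penetrance model.

    ``f0`` is the baseline penetrance, ``r1``/``r2`` the per-minor-allele
    multiplicative effects at the causal SNPs, ``theta`` the interaction
    odds ratio (1 = no interaction), and the causal indices are 0-based
    column positions within each region.
    """

    f0: float = 0.01
    r1: float = 1.2
    r2: float = 1.2
    theta: float = 1.0
    causal_index_region1: int = 1
    causal_index_region2: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("baseline penetrance f0 must be in (0, 1)")
        if min(self.r1, self.r2, self.theta) <= 0:
            raise ValueError("effect parameters must be positive")

    def penetrance(self, x1, x2) -> np.ndarray:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        f = self.f0 * self.r1**x1 * self.r2**x2 * self.theta ** (x1 * x2)
        return np.minimum(f, 1.0)


DEFAULT_MODEL = DiseaseModel()


@dataclass
class SimulatedDataset:
    """Simulated case-control data for two regions, causal SNPs removed.

    ``causal_cases`` / ``causal_controls`` keep the causal-pair dosages
    (n x 2) for generating-parameter diagnostics; they are not part of the
    matrices handed to the tests.
    """

    cases_A: GenotypeMatrix
    cases_B: GenotypeMatrix
    controls_A: GenotypeMatrix
    controls_B: GenotypeMatrix
    model: DiseaseModel
    seed: int
    causal_cases: np.ndarray = field(default=None, repr=False)  # type: ignore
    causal_controls: np.ndarray = field(default=None, repr=False)  # type: ignore

    def to_split(self) -> CaseControlSplit:
        return CaseControlSplit(
            self.cases_A, self.cases_B, self.controls_A, self.controls_B
        )


def _chain_distribution(maf: np.ndarray, adjacent_r2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact haplotype distribution of a first-order allele chain.

    Adjacent-pair correlations are sqrt(target r^2), clamped to the
    Frechet-feasible range for the two margins.
    """
    p = len(maf)
    haps = ((np.arange(2**p)[:, None] >> np.arange(p)[None, :]) & 1).astype(np.int8)
    probs = np.where(haps[:, 0] == 1, maf[0], 1 - maf[0]).astype(float)
    for j in range(p - 1):
        p1, p2 = maf[j], maf[j + 1]
        rho = np.sqrt(adjacent_r2[j])
        p11 = p1 * p2 + rho * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
        p11 = float(np.clip(p11, lo + 1e-9, hi - 1e-9))
        t1 = p11 / p1  # P(next=1 | this=1)
        t0 = (p2 - p11) / (1 - p1)  # P(next=1 | this=0)
        cond = np.where(haps[:, j] == 1, t1, t0)
        probs *= np.where(haps[:, j + 1] == 1, cond, 1 - cond)
    return haps, probs


def build_pool(
    mode: str = "synthetic",
    *,
    n_snps: int | None = None,
    maf=None,
    adjacent_r2=None,
    max_haplotypes: int = 16,
    region_label: str = "region",
    path: str | Path | None = None,
) -> HaplotypePool:
    """Construct a haplotype pool synthetically or from a phased-text file.

    Synthetic mode enumerates a first-order allele chain matching the target
    MAF vector and adjacent-pair r^2 vector, truncates to the most frequent
    haplotypes, and verifies realized MAFs within 0.02 and adjacent r^2
    within 0.1 of the targets, enlarging the pool if truncation drifted.
    """
    if mode == "from_file":
        if path is None:
            raise ValueError("from_file mode needs a path")
        return _read_pool(path)
    if mode != "synthetic":
        raise ValueError(f"unknown pool mode {mode!r}")

    maf = np.asarray(maf, dtype=float)
    if n_snps is None:
        n_snps = len(maf)
    if len(maf) != n_snps:
        raise ValueError("maf vector length must equal n_snps")
    if n_snps > 16:
        raise ValueError("synthetic pools support at most 16 SNPs")
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("target MAFs must be in (0, 0.5]")
    if n_snps == 1:
        haps = np.array([[0], [1]], dtype=np.int8)
        freqs = np.array([1 - maf[0], maf[0]])
        snps = [SnpRecord(f"{region_label}_snp1", region_label, float(maf[0]))]
        return HaplotypePool(haps, freqs, snps)
    adjacent_r2 = np.asarray(adjacent_r2, dtype=float)
    if len(adjacent_r2) != n_snps - 1:
        raise ValueError("need one adjacent r2 target per SNP pair")

    haps_all, probs_all = _chain_distribution(maf, adjacent_r2)
    order = np.argsort(probs_all)[::-1]
    target_r2 = adjacent_r2

    H = min(max_haplotypes, len(order))
    best_summary = ""
    while True:
        idx = order[:H]
        freqs = probs_all[idx]
        keep = freqs > 0
        idx, freqs = idx[keep], freqs[keep]
        freqs = freqs / freqs.sum()
        pool = HaplotypePool(
            haps_all[idx], freqs,
            [SnpRecord(f"{region_label}_snp{j + 1}", region_label, 0.25)
             for j in range(n_snps)],
        )
        got_maf = pool.allele_freqs()
        got_r2 = np.array([pool.r2(j, j + 1) for j in range(n_snps - 1)])
        maf_ok = np.all(np.abs(got_maf - maf) <= MAF_TOL)
        r2_ok = np.all(np.abs(got_r2 - target_r2) <= R2_TOL)
        best_summary = (
            f"H={len(freqs)} realized MAF={np.round(got_maf, 3)} "
            f"adjacent r2={np.round(got_r2, 3)} (targets {np.round(maf, 3)} / "
            f"{np.round(target_r2, 3)})"
        )
        if maf_ok and r2_ok:
            break
        if H >= len(order):
            raise ValueError(f"infeasible MAF/r2 targets for pool: {best_summary}")
        H = min(2 * H, len(order))
    logger.info("built synthetic pool %s: %s", region_label, best_summary)
    snps = [
        SnpRecord(f"{region_label}_snp{j + 1}", region_label,
                  float(min(got_maf[j], 0.5)))
        for j in range(n_snps)
    ]
    return HaplotypePool(pool.haplotypes, pool.frequencies, snps)


def write_pool(pool: HaplotypePool, path: str | Path) -> None:
    """Plain-text pool: header of SNP ids, then one '<bits> <weight>' per line."""
    with open(path, "w") as fh:
        fh.write("#snps\t" + "\t".join(s.id for s in pool.snps) + "\n")
        fh.write("#region\t" + pool.snps[0].region_label + "\n")
        for h, w in zip(pool.haplotypes, pool.frequencies):
            fh.write("".join(str(int(b)) for b in h) + f"\t{float(w)!r}\n")


def _read_pool(path: str | Path) -> HaplotypePool:
    ids: list[str] = []
    region = "region"
    haps, freqs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#snps"):
                ids = line.split("\t")[1:]
            elif line.startswith("#region"):
                region = line.split("\t")[1]
            elif not line.startswith("#"):
                bits, w = line.split()
                haps.append([int(b) for b in bits])
                freqs.append(float(w))
    haps_arr = np.asarray(haps, dtype=np.int8)
    freqs_arr = np.asarray(freqs, dtype=float)
    freqs_arr = freqs_arr / freqs_arr.sum()
    if not ids:
        ids = [f"{region}_snp{j + 1}" for j in range(haps_arr.shape[1])]
    mafs = freqs_arr @ haps_arr
    snps = [
        SnpRecord(ids[j], region, float(np.clip(mafs[j], 1e-9, 0.5)))
        for j in range(haps_arr.shape[1])
    ]
    return HaplotypePool(haps_arr, freqs_arr, snps)


def draw_genotypes(pool: HaplotypePool, n: int, seed: int = 0) -> GenotypeMatrix:
    """Random-union genotypes: each individual sums two weighted haplotype draws."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool.frequencies), size=(n, 2), p=pool.frequencies)
    dosages = pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]
    return GenotypeMatrix(
        dosages.astype(float),
        list(pool.snps),
        [f"sim_{i + 1}" for i in range(n)],
    )


def default_pools() -> tuple[HaplotypePool, HaplotypePool]:
    """The package's two study regions: 6 and 7 SNPs with gene-region LD."""
    pool1 = build_pool(
        maf=[0.35, 0.28, 0.22, 0.41, 0.17, 0.30],
        adjacent_r2=[0.55, 0.45, 0.35, 0.30, 0.50],
        region_label="region1",
    )
    pool2 = build_pool(
        maf=[0.24, 0.33, 0.19, 0.38, 0.27, 0.45, 0.21],
        adjacent_r2=[0.50, 0.40, 0.35, 0.45, 0.30, 0.40],
        region_label="region2",
    )
    return pool1, pool2


def simulate_case_control(
    pool1: HaplotypePool,
    pool2: HaplotypePool,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    drop_causal: bool = True,
    max_draws: int = 100_000_000,
) -> SimulatedDataset:
    """Rejection-sample a case-control dataset under the penetrance model.

    Individuals are drawn independently from the two (unlinked) region
    pools; disease status is Bernoulli with the two-locus penetrance at the
    causal dosages; sampling continues until both strata are filled.  The
    causal columns are then deleted (unless ``drop_causal=False``, e.g. for
    planted-signal benchmarks of SNP-pair methods).
    """
    c1, c2 = model.causal_index_region1, model.causal_index_region2
    if not (0 <= c1 < pool1.n_snps and 0 <= c2 < pool2.n_snps):
        raise ValueError("causal index outside its region")

    pat1, pr1 = pool1.genotype_catalog()
    pat2, pr2 = pool2.genotype_catalog()
    x1v = pat1[:, c1].astype(float)
    x2v = pat2[:, c2].astype(float)

    f0 = model.f0
    grid = f0 * model.r1 ** np.arange(3)[:, None] * model.r2 ** np.arange(3)[None, :]
    grid = grid * model.theta ** np.outer(np.arange(3), np.arange(3))
    if grid.max() > 1.0:
        f0 = model.f0 / grid.max()
        warnings.warn(
            f"penetrance exceeds 1 for some genotype; rescaling f0 to {f0:.4g}"
        )

    pen = np.minimum(
        f0 * np.outer(model.r1**x1v, model.r2**x2v)
        * model.theta ** np.outer(x1v, x2v),
        1.0,
    )
    prev = min(max(float(pr1 @ pen @ pr2), 1e-6), 1.0)

    rng = np.random.default_rng(seed)
    need_c, need_u = n_cases, n_controls
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    drawn = 0
    while need_c > 0 or need_u > 0:
        batch = int(min(
            max(20_000, 1.5 * (need_c / prev + need_u / max(1 - prev, 1e-6))),
            5_000_000,
        ))
        if drawn + batch > max_draws:
            raise RuntimeError(
                f"exceeded {max_draws} draws with {need_c} cases still missing; "
                "baseline penetrance too small for the requested sample"
            )
        i1 = rng.choice(len(pr1), size=batch, p=pr1)
        i2 = rng.choice(len(pr2), size=batch, p=pr2)
        f = f0 * model.r1 ** x1v[i1] * model.r2 ** x2v[i2]
        f = np.minimum(f * model.theta ** (x1v[i1] * x2v[i2]), 1.0)
        is_case = rng.random(batch) < f
        drawn += batch
        if need_c > 0:
            sel = np.flatnonzero(is_case)[:need_c]
            case_rows.append(np.column_stack([i1[sel], i2[sel]]))
            need_c -= len(sel)
        if need_u > 0:
            sel = np.flatnonzero(~is_case)[:need_u]
            ctrl_rows.append(np.column_stack([i1[sel], i2[sel]]))
            need_u -= len(sel)

    cases = np.vstack(case_rows)
    ctrls = np.vstack(ctrl_rows)

    def matrices(rows: np.ndarray, prefix: str):
        g1 = pat1[rows[:, 0]].astype(float)
        g2 = pat2[rows[:, 1]].astype(float)
        ids = [f"{prefix}_{i + 1}" for i in range(len(rows))]
        causal = np.column_stack([g1[:, c1], g2[:, c2]])
        if drop_causal:
            g1 = np.delete(g1, c1, axis=1)
            g2 = np.delete(g2, c2, axis=1)
            snps1 = [s for j, s in enumerate(pool1.snps) if j != c1]
            snps2 = [s for j, s in enumerate(pool2.snps) if j != c2]
        else:
            snps1, snps2 = list(pool1.snps), list(pool2.snps)
        return (
            GenotypeMatrix(g1, snps1, ids),
            GenotypeMatrix(g2, snps2, ids),
            causal,
        )

    cA, cB, causal_cases = matrices(cases, "case")
    uA, uB, causal_controls = matrices(ctrls, "control")
    return SimulatedDataset(
        cA, cB, uA, uB, model, seed,
        causal_cases=causal_cases, causal_controls=causal_controls,
    )
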