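"""Genotype containers and I/O for two-gene co-association testing.

Genotypes are held as additive minor-allele dosages (0/1/2) in an
individuals x SNPs matrix with per-SNP metadata, and are partitioned by
case/control status before testing.  Three input formats are supported:
VCF (biallelic SNPs), PLINK-style additive-dosage text, and a plain
delimited numeric matrix accompanied by a SNP-to-gene map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "CaseControlSplit",
    "load_genotypes",
    "read_region_map",
    "qc_filter",
    "split_by_phenotype",
    "write_delimited",
]


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for a single biallelic SNP.

    ``minor_allele_freq`` is the frequency of the counted (minor) allele and
    must lie in (0, 0.5].  ``position`` is 1-based and informational only.
    """

    id: str
    region_label: str
    minor_allele_freq: float
    position: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.minor_allele_freq <= 0.5):
            raise ValueError(
                f"SNP {self.id}: minor allele frequency {self.minor_allele_freq} "
                "outside (0, 0.5]"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of additive minor-allele dosages.

    Entries are 0, 1 or 2; ``nan`` marks missing genotypes before QC.
    """

    values: np.ndarray
    snps: list[SnpRecord]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if self.values.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.snps)} SNP records"
            )
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            list(self.snps),
            [self.sample_ids[i] for i in idx],
        )

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            [self.snps[i] for i in idx],
            list(self.sample_ids),
        )


@dataclass
class CaseControlSplit:
    """Case and control strata of two gene matrices, rows aligned per stratum."""

    cases_A: GenotypeMatrix
    cases_B: GenotypeMatrix
    controls_A: GenotypeMatrix
    controls_B: GenotypeMatrix
    phenotype: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cases_A.n_samples != self.cases_B.n_samples:
            raise ValueError("case strata of gene A and gene B differ in size")
        if self.controls_A.n_samples != self.controls_B.n_samples:
            raise ValueError("control strata of gene A and gene B differ in size")
        if self.phenotype is None:
            self.phenotype = np.r_[
                np.ones(self.cases_A.n_samples, dtype=int),
                np.zeros(self.controls_A.n_samples, dtype=int),
            ]

    @property
    def n_cases(self) -> int:
        return self.cases_A.n_samples

    @property
    def n_controls(self) -> int:
        return self.controls_A.n_samples

    def swapped(self) -> "CaseControlSplit":
        """Exchange the case and control strata (label inversion)."""
        return CaseControlSplit(
            self.controls_A, self.controls_B, self.cases_A, self.cases_B
        )


def read_region_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (SNP id, gene label) map file; any whitespace/comma delimiter."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"region map {path} needs two columns (snp id, gene)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _maf_from_column(col: np.ndarray) -> float:
    ok = np.isfinite(col)
    if not ok.any():
        return 0.0
    return float(np.mean(col[ok]) / 2.0)


def _orient_minor(values: np.ndarray) -> np.ndarray:
    """Flip any column whose counted-allele frequency exceeds 0.5."""
    out = values.copy()
    for j in range(out.shape[1]):
        if _maf_from_column(out[:, j]) > 0.5:
            ok = np.isfinite(out[:, j])
            out[ok, j] = 2.0 - out[ok, j]
    return out


def _records_from_data(
    values: np.ndarray,
    ids: Sequence[str],
    region_map: Mapping[str, str],
    positions: Sequence[int | None] | None = None,
) -> list[SnpRecord]:
    recs = []
    for j, sid in enumerate(ids):
        maf = _maf_from_column(values[:, j])
        # monomorphic columns get a placeholder frequency; QC removes them
        maf = min(max(maf, 1e-9), 0.5)
        pos = positions[j] if positions is not None else None
        recs.append(SnpRecord(str(sid), region_map[str(sid)], maf, pos))
    return recs


def _load_vcf(path: str | Path, region_map: Mapping[str, str]):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, positions = [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dosage_of = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1 or var.is_indel:
            warnings.warn(f"excluding non-biallelic-SNP site {vid}")
            continue
        if vid not in region_map:
            warnings.warn(f"SNP {vid} absent from region map; excluded")
            continue
        d = dosage_of[np.asarray(var.gt_types)]
        cols.append(d)
        ids.append(vid)
        positions.append(var.POS)
    if not cols:
        raise ValueError(f"no usable biallelic SNPs in {path}")
    values = _orient_minor(np.column_stack(cols))
    return values, ids, samples, positions


def _load_table(path: str | Path, region_map: Mapping[str, str], plink: bool):
    sep = r"\s+" if plink else None
    df = pd.read_csv(path, sep=sep, engine="python", na_values=["NA", "-9", "."])
    drop = [c for c in df.columns if str(c).upper() in ("FID", "IID", "PHENOTYPE")]
    df = df.drop(columns=drop)
    if "sample_id" in df.columns:
        samples = df.pop("sample_id").astype(str).tolist()
    else:
        samples = [f"S{i + 1}" for i in range(len(df))]
    keep, skipped = [], []
    for c in df.columns:
        (keep if str(c) in region_map else skipped).append(str(c))
    for c in skipped:
        warnings.warn(f"SNP {c} absent from region map; excluded")
    values = _orient_minor(df[keep].to_numpy(dtype=float))
    return values, keep, samples, None


def load_genotypes(
    path: str | Path,
    format: str,
    region_map: Mapping[str, str] | str | Path,
) -> GenotypeMatrix:
    """Load a genotype file into a minor-allele dosage matrix.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``vcf``, ``plink_additive`` (whitespace table with a SNP-id
        header; FID/IID/PHENOTYPE columns tolerated and dropped) or
        ``delimited`` (our own dosage matrix format).
    region_map
        SNP id -> gene label mapping, or path to a two-column map file.
        SNPs absent from the map are excluded with a warning.
    """
    if not isinstance(region_map, Mapping):
        region_map = read_region_map(region_map)
    if format == "vcf":
        values, ids, samples, positions = _load_vcf(path, region_map)
    elif format in ("plink_additive", "delimited"):
        values, ids, samples, positions = _load_table(
            path, region_map, plink=(format == "plink_additive")
        )
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    snps = _records_from_data(values, ids, region_map, positions)
    return GenotypeMatrix(values, snps, samples)


def write_delimited(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a tab-separated dosage matrix with a ``sample_id`` column."""
    df = pd.DataFrame(G.values, columns=G.snp_ids)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def qc_filter(G: GenotypeMatrix, max_missing_rate: float = 0.05) -> GenotypeMatrix:
    """Drop high-missingness and monomorphic SNPs; mean-impute the rest.

    Columns with missingness above ``max_missing_rate`` are removed; remaining
    missing entries are imputed to the rounded column mean; columns that are
    constant after imputation are removed.  Raises if nothing survives.
    """
    vals = G.values.copy()
    miss = np.mean(~np.isfinite(vals), axis=0)
    keep = miss <= max_missing_rate
    dropped_missing = [s.id for s, k in zip(G.snps, keep) if not k]
    vals = vals[:, keep]
    snps = [s for s, k in zip(G.snps, keep) if k]

    for j in range(vals.shape[1]):
        m = ~np.isfinite(vals[:, j])
        if m.any():
            vals[m, j] = np.clip(round(float(np.nanmean(vals[:, j]))), 0, 2)

    poly = np.array([len(np.unique(vals[:, j])) > 1 for j in range(vals.shape[1])])
    dropped_const = [s.id for s, k in zip(snps, poly) if not k]
    vals = vals[:, poly]
    snps = [s for s, k in zip(snps, poly) if k]

    if dropped_missing or dropped_const:
        logger.info(
            "qc_filter removed %d high-missingness (%s) and %d monomorphic (%s) SNPs",
            len(dropped_missing), ",".join(dropped_missing),
            len(dropped_const), ",".join(dropped_const),
        )
    if vals.shape[1] == 0:
        raise ValueError(
            "QC removed every SNP "
            f"(missingness>{max_missing_rate}: {dropped_missing}; monomorphic: {dropped_const})"
        )
    snps = [replace(s, minor_allele_freq=min(_maf_from_column(vals[:, j]), 0.5))
            for j, s in enumerate(snps)]
    return GenotypeMatrix(vals, snps, list(G.sample_ids))


def split_by_phenotype(
    G_A: GenotypeMatrix, G_B: GenotypeMatrix, phenotype: Sequence[int] | np.ndarray
) -> CaseControlSplit:
    """Partition paired gene matrices into case (1) and control (0) strata.

    Row order is preserved within each stratum; both classes must be
    non-empty and the phenotype length must match the matrices.
    """
    y = np.asarray(phenotype, dtype=int)
    if y.shape[0] != G_A.n_samples or y.shape[0] != G_B.n_samples:
        raise ValueError("phenotype length does not match genotype matrices")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be coded 0 (control) / 1 (case)")
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError("both phenotype classes must be non-empty")
    return CaseControlSplit(
        G_A.take_samples(case_idx),
        G_B.take_samples(case_idx),
        G_A.take_samples(ctrl_idx),
        G_B.take_samples(ctrl_idx),
        phenotype=y,
    )
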