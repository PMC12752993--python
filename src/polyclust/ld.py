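"""Genotype-quality filtering and within-cluster linkage-disequilibrium pruning.

LD is computed as the squared product-moment correlation of allele dosages over
pairwise-complete samples of a reference panel (composite LD), which needs no
phasing and behaves sensibly for imputed real-valued dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.3
DEFAULT_MAX_MISSING = 0.10


@dataclass
class DosageMatrix:
    """Individuals x SNPs allele dosages in [0, 2], NaN where missing.

    ``dose``: DataFrame indexed by sample_id with one column per snp_id.
    ``counted_allele``: Series snp_id -> the allele whose dose is counted.
    """

    dose: pd.DataFrame
    counted_allele: pd.Series

    def __post_init__(self) -> None:
        vals = self.dose.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 2:
                raise DataError("dosages must lie in [0, 2]")
        missing = set(self.dose.columns) - set(self.counted_allele.index)
        if missing:
            raise DataError(f"counted_allele undefined for {len(missing)} SNPs")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dose.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dose.columns)

    def missing_fraction(self) -> pd.Series:
        """Per-SNP missing fraction across samples."""
        return self.dose.isna().mean(axis=0)


@dataclass
class LDMatrix:
    snp_ids: list[str]
    r2: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    def lookup(self, a: str, b: str) -> float:
        i, j = self.snp_ids.index(a), self.snp_ids.index(b)
        return float(self.r2[i, j])


def genotype_filters(
    cluster_snps: list[str],
    panel: DosageMatrix,
    variant_meta: pd.DataFrame,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> list[str]:
    """Keep biallelic cluster SNPs with missing fraction <= max_missing.

    ``variant_meta`` is indexed by snp_id with a boolean ``multiallelic``
    column.  A SNP absent from the panel counts as fully missing.  Exactly
    max_missing is retained (only strictly-greater missingness is removed).
    """
    miss = panel.missing_fraction()
    kept = []
    n_multi = n_miss = n_absent = 0
    for sid in cluster_snps:
        if sid in variant_meta.index and bool(variant_meta.loc[sid, "multiallelic"]):
            n_multi += 1
            continue
        if sid not in miss.index:
            n_absent += 1
            continue
        if miss[sid] > max_missing:
            n_miss += 1
            continue
        kept.append(sid)
    if n_multi or n_miss or n_absent:
        log.info(
            "genotype filters removed %d multiallelic, %d high-missingness, %d absent SNPs",
            n_multi,
            n_miss,
            n_absent,
        )
    return kept


def pairwise_r2(panel: DosageMatrix, snps: list[str]) -> LDMatrix:
    """Squared dosage correlation over pairwise-complete samples.

    Pairs with fewer than 3 complete samples or a monomorphic member get
    r2 = 0 (logged) so pruning can proceed.
    """
    if len(snps) < 2:
        raise DataError("pairwise r2 needs at least two SNPs")
    sub = panel.dose[snps]
    r = sub.corr(min_periods=3)  # pairwise-complete by construction
    r2 = (r**2).to_numpy()
    n_absent = int(np.isnan(r2).sum() - np.isnan(np.diag(r2)).sum())
    if n_absent:
        log.warning("%d SNP pairs with undefined r2 treated as 0", n_absent // 2)
    r2 = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(snp_ids=list(snps), r2=np.clip(r2, 0.0, 1.0))


def greedy_prune(
    snps: list[str],
    priority: pd.Series,
    ld: LDMatrix,
    threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[str]:
    """Greedy LD pruning: visit SNPs by decreasing priority (row-max |z|; ties
    by id) and keep each SNP iff its r2 with every kept SNP is <= threshold.

    The kept set is maximal: no excluded SNP can be added back without
    violating the threshold.
    """
    missing = [s for s in snps if s not in priority.index]
    if missing:
        raise DataError(f"priority missing for {len(missing)} SNPs, e.g. {missing[0]!r}")
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    order = sorted(snps, key=lambda s: (-float(priority[s]), s))
    kept: list[str] = []
    kept_idx: list[int] = []
    for s in order:
        i = idx[s]
        if all(ld.r2[i, j] <= threshold for j in kept_idx):
            kept.append(s)
            kept_idx.append(i)
    return kept
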