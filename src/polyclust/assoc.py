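"""Covariate-adjusted group tests with FDR control.

"One-way ANOVA controlling for covariates" is realised as the partial F-test
for the group factor in a linear model that always contains the covariates
(ANCOVA): F compares the covariate-only fit against the full fit.  Burden
ratings are treated as a categorical factor, matching the per-level pairwise
follow-up structure, not as a linear trend.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ConfigurationError, DataError

log = logging.getLogger(__name__)

DEFAULT_FDR_ALPHA = 0.05


@dataclass
class AssocResult:
    """One group F-test: F(df1, df2), p, BH-adjusted p, and sample count."""

    test_label: str
    F: float
    df1: int
    df2: int
    p: float
    p_adj: float | None = None
    n_used: int = 0

    def to_dict(self) -> dict:
        return {
            "test_label": self.test_label,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "p_adj": self.p_adj,
            "n_used": self.n_used,
        }


@dataclass
class PairwiseResult:
    """Two-sample pooled-variance t-test between two group levels."""

    test_label: str
    group_a: str
    group_b: str
    t: float
    df: int
    p: float
    p_adj: float | None = None
    n_a: int = 0
    n_b: int = 0


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(
    df: pd.DataFrame, factor: str, covariates: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Full and reduced (covariate-only) design matrices, dummy-coded."""

    def dummies(cols: list[str]) -> np.ndarray:
        parts = [np.ones((len(df), 1))]
        for c in cols:
            s = df[c]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                d = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
                parts.append(d.to_numpy())
            else:
                parts.append(s.to_numpy(dtype=float)[:, None])
        return np.hstack(parts)

    x_red = dummies(covariates)
    x_full = np.hstack([x_red, _factor_dummies(df[factor])])
    df1 = x_full.shape[1] - x_red.shape[1]
    return x_full, x_red, df1


def _factor_dummies(s: pd.Series) -> np.ndarray:
    return pd.get_dummies(s.astype(str), drop_first=True, dtype=float).to_numpy()


def ancova_f_test(
    outcome: pd.Series,
    group: pd.Series,
    covariates: list[pd.Series] | None = None,
    test_label: str = "group",
) -> AssocResult:
    """Partial F-test for a categorical group factor given covariates.

    Complete cases only (listwise deletion, logged).  Raises on singular
    designs, naming the collinear columns.
    """
    covariates = covariates or []
    data = {"_y": outcome, "_g": group}
    cov_names = []
    for i, c in enumerate(covariates):
        name = c.name if c.name is not None else f"cov{i}"
        data[str(name)] = c
        cov_names.append(str(name))
    df = pd.DataFrame(data)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        log.info("listwise deletion removed %d incomplete cases", n0 - len(df))

    levels = df["_g"].astype(str).value_counts()
    if len(levels) < 2 or (levels < 2).any():
        raise DataError("need >= 2 group levels with >= 2 samples each")

    x_full, x_red, df1 = _design(df, "_g", cov_names)
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        raise ComputationError(
            f"singular design for {test_label!r}: group factor collinear with "
            f"covariates {cov_names}"
        )
    y = df["_y"].to_numpy(dtype=float)
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df2 = int(full.df_resid)
    if df2 < 1:
        raise DataError("no residual degrees of freedom")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0 or full.ssr <= 1e-12 * tss:  # outcome (near-)exactly fitted
        f_stat, p = 0.0, 1.0
        if red.ssr > 1e-12 * max(tss, 1.0):
            f_stat, p = np.inf, 0.0
    else:
        f_stat = ((red.ssr - full.ssr) / df1) / (full.ssr / df2)
        f_stat = max(float(f_stat), 0.0)
        p = float(stats.f.sf(f_stat, df1, df2))
    return AssocResult(
        test_label=test_label,
        F=float(f_stat),
        df1=int(df1),
        df2=df2,
        p=min(max(p, np.nextafter(0, 1)), 1.0),
        n_used=len(df),
    )


def pairwise_adjusted_ttests(
    outcome: pd.Series, group: pd.Series, test_label: str = "group"
) -> list[PairwiseResult]:
    """Pooled-variance two-sided t-tests for every level pair, BH-adjusted
    across the pairs.  Levels with fewer than 2 samples are skipped (logged)."""
    df = pd.DataFrame({"_y": outcome, "_g": group.astype(str)}).dropna()
    levels = sorted(df["_g"].unique())
    if len(levels) < 2:
        raise DataError("need >= 2 group levels")
    results = []
    for a, b in itertools.combinations(levels, 2):
        ya = df.loc[df["_g"] == a, "_y"].to_numpy(dtype=float)
        yb = df.loc[df["_g"] == b, "_y"].to_numpy(dtype=float)
        if len(ya) < 2 or len(yb) < 2:
            log.info("skipping pair (%s, %s): a level has < 2 samples", a, b)
            continue
        t, p = stats.ttest_ind(ya, yb, equal_var=True)
        if np.isnan(t):  # zero pooled variance
            t, p = 0.0, 1.0
        results.append(
            PairwiseResult(
                test_label=test_label,
                group_a=a,
                group_b=b,
                t=float(t),
                df=len(ya) + len(yb) - 2,
                p=float(p),
                n_a=len(ya),
                n_b=len(yb),
            )
        )
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
    return results


def regional_burden_scan(
    delta: pd.Series,
    cohort: pd.DataFrame,
    regions: list[str],
    covariates: list[str] | None = None,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
) -> tuple[list[AssocResult], dict[str, list[PairwiseResult]]]:
    """Per-region ANCOVA of the score difference against ordinal burden level.

    Burden enters as the categorical factor; BH adjustment runs across all
    scanned regions; regions passing FDR get pairwise follow-ups between
    burden levels (BH within each region's family).  Regions with fewer than
    two observed burden levels are skipped (logged).
    """
    covariates = covariates or []
    cohort = cohort.set_index("sample_id") if "sample_id" in cohort.columns else cohort
    results: list[AssocResult] = []
    usable: list[str] = []
    for region in regions:
        col = f"burden_{region}" if f"burden_{region}" in cohort.columns else region
        if col not in cohort.columns:
            raise ConfigurationError(f"region column {col!r} not in cohort table")
        burden = cohort[col].reindex(delta.index)
        n_levels = burden.dropna().nunique()
        if n_levels < 2:
            log.info("region %r has %d observed burden level(s); skipped", region, n_levels)
            continue
        res = ancova_f_test(
            delta,
            burden,
            [cohort[c].reindex(delta.index) for c in covariates],
            test_label=region,
        )
        results.append(res)
        usable.append(region)
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
    followups: dict[str, list[PairwiseResult]] = {}
    for region, res in zip(usable, results):
        if res.p_adj is not None and res.p_adj < fdr_alpha:
            col = f"burden_{region}" if f"burden_{region}" in cohort.columns else region
            followups[region] = pairwise_adjusted_ttests(
                delta, cohort[col].reindex(delta.index), test_label=region
            )
    return results, followups


def results_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Tidy results table (test_label, F, df1, df2, p, p_adj, n_used)."""
    return pd.DataFrame([r.to_dict() for r in results])
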