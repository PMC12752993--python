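"""Cluster-specific polygenic risk scores.

A cluster's score for individual i is the frequency-centred, per-SNP-averaged
weighted allele sum

    PRS_i = (1/M) * sum_j w_j * (g_ij - 2 f_j)

with w_j the signed z-score weight for the effect allele, g_ij the effect-
allele dosage, f_j the effect-allele frequency in a reference population, and
M the number of weight SNPs.  Missing dosages are replaced by 2 f_j and hence
contribute exactly zero; individuals missing more than 10% of a score's SNPs
are excluded from that score.  "Mean scaled" is realised as division by M,
which makes scores comparable across clusters of different sizes — a
prerequisite for the relative (difference) score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .ld import DosageMatrix
from .sumstats import StudyStats

log = logging.getLogger(__name__)

DEFAULT_MAX_MISSING = 0.10


@dataclass
class WeightTable:
    """Per-SNP signed weights defining one cluster's score.

    ``table``: DataFrame indexed by snp_id with columns effect_allele,
    other_allele, weight (signed z), ref_freq (effect-allele frequency in the
    reference population, in (0, 1)).
    """

    cluster_label: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise DataError("duplicate snp_ids in weight table")
        f = self.table["ref_freq"]
        if ((f <= 0) | (f >= 1)).any():
            raise DataError("ref_freq must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PRSResult:
    """Per-sample scores with missingness bookkeeping.

    ``table``: DataFrame indexed by sample_id with columns score (NaN where
    excluded), missing_frac, excluded.
    """

    cluster_label: int
    table: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def load_freq_table(path) -> pd.DataFrame:
    """Read an allele-frequency table: either (snp_id, allele, freq) with one
    row per allele, or (snp_id, freq) giving the effect-allele frequency
    directly (dialect detected from the column count)."""
    raw = pd.read_csv(path, sep=None, engine="python", comment="#")
    if raw.shape[1] == 3:
        raw.columns = ["snp_id", "allele", "freq"]
    elif raw.shape[1] == 2:
        raw.columns = ["snp_id", "freq"]
    else:
        raise ConfigurationError(f"frequency table must have 2 or 3 columns, got {raw.shape[1]}")
    return raw


def _freq_lookup(freqs: pd.DataFrame):
    """Return freq(snp, allele) -> float | None from either table dialect."""
    if "allele" in freqs.columns:
        table = {(r.snp_id, r.allele): float(r.freq) for r in freqs.itertuples()}

        def lookup(snp: str, allele: str):
            return table.get((snp, allele))

    else:
        table2 = {r.snp_id: float(r.freq) for r in freqs.itertuples()}

        def lookup(snp: str, allele: str):  # allele assumed = stated effect allele
            return table2.get(snp)

    return lookup


def build_weight_table(
    cluster_snps: list[str],
    study: StudyStats,
    freqs: pd.DataFrame,
    minor_allele_rule: bool = False,
    cluster_label: int = 0,
) -> WeightTable:
    """Signed z weights for a cluster's SNPs from one study's effect estimates.

    Requires a study with direction of effect (beta and se): a study reporting
    only p-values cannot define signed weights, which is why no score can be
    built for a direction-less phenotype.  With ``minor_allele_rule`` the
    effect allele is reassigned to the allele with reference frequency < 0.5
    (the weight flips sign when that swaps the stated alleles; frequency ties
    pick the alphabetically first allele, logged).  SNPs without reference
    frequency are dropped with a logged count.
    """
    if not study.signed:
        raise DataError(
            f"study {study.study_label!r} lacks direction of effect: cannot build weights"
        )
    t = study.table.set_index("variant_id")
    lookup = _freq_lookup(freqs)
    rows = []
    n_nofreq = 0
    n_absent = 0
    for sid in cluster_snps:
        if sid not in t.index:
            n_absent += 1
            continue
        rec = t.loc[sid]
        eff, oth = rec["effect_allele"], rec["other_allele"]
        w = float(rec["beta"]) / float(rec["se"])
        f = lookup(sid, eff)
        if f is None:
            n_nofreq += 1
            continue
        if minor_allele_rule:
            if f > 0.5 or (f == 0.5 and min(eff, oth) != eff):
                eff, oth = oth, eff
                w, f = -w, 1.0 - f
                if f == 0.5:
                    log.info("frequency tie at %s: effect allele set alphabetically", sid)
        rows.append((sid, eff, oth, w, f))
    if n_nofreq:
        log.warning("dropped %d SNPs without reference allele frequency", n_nofreq)
    if n_absent:
        log.warning("%d cluster SNPs absent from study %r", n_absent, study.study_label)
    table = pd.DataFrame(
        rows, columns=["snp_id", "effect_allele", "other_allele", "weight", "ref_freq"]
    ).set_index("snp_id")
    return WeightTable(cluster_label=cluster_label, table=table)


def align_alleles(weights: WeightTable, genotypes: DosageMatrix) -> WeightTable:
    """Orient weights to the allele counted in the genotype data.

    When the counted allele is the non-effect allele the weight is negated and
    ref_freq becomes 1 - ref_freq (dose of the effect allele is 2 minus the
    provided dose, an affine flip the scoring formula absorbs).  SNPs whose
    counted allele matches neither stated allele are dropped (logged).
    """
    rows = []
    n_dropped = 0
    n_missing = 0
    for sid, rec in weights.table.iterrows():
        if sid not in genotypes.counted_allele.index or sid not in genotypes.dose.columns:
            n_missing += 1
            continue
        counted = genotypes.counted_allele[sid]
        if counted == rec["effect_allele"]:
            rows.append((sid, rec["effect_allele"], rec["other_allele"], rec["weight"], rec["ref_freq"]))
        elif counted == rec["other_allele"]:
            rows.append(
                (sid, rec["other_allele"], rec["effect_allele"], -rec["weight"], 1.0 - rec["ref_freq"])
            )
        else:
            n_dropped += 1
    if n_dropped:
        log.warning("dropped %d SNPs whose counted allele matches neither stated allele", n_dropped)
    if n_missing:
        log.warning("%d weight SNPs absent from genotype data", n_missing)
    table = pd.DataFrame(
        rows, columns=["snp_id", "effect_allele", "other_allele", "weight", "ref_freq"]
    ).set_index("snp_id")
    return WeightTable(cluster_label=weights.cluster_label, table=table)


def score_individuals(
    weights: WeightTable,
    genotypes: DosageMatrix,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> PRSResult:
    """Frequency-centred, per-SNP-averaged weighted allele sum per individual."""
    if len(weights) == 0:
        raise DataError("empty weight table after alignment")
    snps = [s for s in weights.table.index if s in genotypes.dose.columns]
    if len(snps) < len(weights.table):
        raise DataError("weight SNPs missing from genotype matrix; align first")
    g = genotypes.dose[snps].to_numpy(dtype=float)
    w = weights.table.loc[snps, "weight"].to_numpy(dtype=float)
    f = weights.table.loc[snps, "ref_freq"].to_numpy(dtype=float)
    m = len(snps)
    missing = np.isnan(g)
    missing_frac = missing.mean(axis=1)
    centred = np.where(missing, 0.0, g - 2.0 * f)  # imputing 2f == zero contribution
    score = centred @ w / m
    excluded = missing_frac > max_missing
    score = np.where(excluded, np.nan, score)
    table = pd.DataFrame(
        {"score": score, "missing_frac": missing_frac, "excluded": excluded},
        index=genotypes.dose.index,
    )
    return PRSResult(cluster_label=weights.cluster_label, table=table)


def relative_score(prs_a: PRSResult, prs_b: PRSResult) -> pd.Series:
    """Difference score a - b over samples scored (not excluded) in both."""
    a = prs_a.table.loc[~prs_a.table["excluded"], "score"]
    b = prs_b.table.loc[~prs_b.table["excluded"], "score"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise DataError("no samples scored in both inputs")
    delta = (a.loc[shared] - b.loc[shared]).rename("delta")
    return delta
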