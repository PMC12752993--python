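"""Cluster stability under repeated SNP subsampling.

The full-sample clustering is re-run on many random subsamples (default: 100
draws of 80% of the SNPs, without replacement); each resample's cluster labels
are matched back to the full-sample clusters by greedy maximum overlap, and
per-cluster consistency is the pooled percentage of SNP-resample observations
assigned to their full-sample cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sumstats import HarmonizedZMatrix
from .wcna import ClusterAssignment, cluster_snps

log = logging.getLogger(__name__)

DEFAULT_N_RESAMPLES = 100
DEFAULT_FRAC = 0.8


@dataclass
class ResampleReport:
    n_resamples: int
    frac: float
    seed: int
    per_cluster_consistency: dict[int, float]
    #: SNPs x resamples matched labels; NaN where the SNP was not drawn
    assignment_table: pd.DataFrame
    reference: ClusterAssignment


def match_cluster_labels(
    reference: ClusterAssignment, candidate: ClusterAssignment
) -> dict[int, int]:
    """Map candidate cluster labels onto reference labels by greedy maximum overlap.

    Repeatedly pairs the (reference, candidate) clusters sharing the most SNPs
    among still-unpaired clusters; candidate clusters left unpaired get fresh
    labels beyond the reference's K (a resample can split a cluster in two).
    Label 0 (unassigned) always maps to 0.
    """
    ref = pd.Series(reference.labels, index=reference.snp_ids)
    cand = pd.Series(candidate.labels, index=candidate.snp_ids)
    shared = ref.index.intersection(cand.index)
    ref, cand = ref.loc[shared], cand.loc[shared]

    ref_labels = sorted({int(l) for l in reference.labels if l != 0})
    cand_labels = sorted({int(l) for l in candidate.labels if l != 0})
    overlaps = []
    for c in cand_labels:
        for r in ref_labels:
            n = int(((cand == c) & (ref == r)).sum())
            overlaps.append((n, r, c))
    # largest overlap first; ties by (reference label, candidate label)
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {0: 0}
    used_ref: set[int] = set()
    for n, r, c in overlaps:
        if n == 0 or c in mapping or r in used_ref:
            continue
        mapping[c] = r
        used_ref.add(r)
    fresh = max(ref_labels, default=0)
    for c in cand_labels:
        if c not in mapping:
            fresh += 1
            mapping[c] = fresh
    return mapping


def resample_assignments(
    matrix: HarmonizedZMatrix,
    params: dict | None = None,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    frac: float = DEFAULT_FRAC,
    seed: int = 0,
    reference: ClusterAssignment | None = None,
) -> ResampleReport:
    """Cluster ``n_resamples`` random subsamples of round(frac*n) SNPs each.

    One root seed spawns per-resample generators, so the report is
    reproducible and any single resample can be re-run in isolation.  A
    clustering failure inside a resample yields an all-absent column (logged),
    not an error.
    """
    if not 0 < frac <= 1:
        raise ConfigurationError(f"frac must be in (0, 1], got {frac}")
    params = params or {}
    if reference is None:
        reference = cluster_snps(matrix, **params)
    n = matrix.n_snps
    k = round(frac * n)
    snp_index = pd.Index(matrix.snp_ids)
    table = pd.DataFrame(
        np.nan, index=snp_index, columns=[f"resample_{i:03d}" for i in range(n_resamples)]
    )
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_resamples)):
        rng = np.random.default_rng(child)
        take = np.sort(rng.choice(n, size=k, replace=False))
        sub_ids = [matrix.snp_ids[j] for j in take]
        sub = HarmonizedZMatrix(
            absz=matrix.absz.loc[sub_ids],
            signed_z=matrix.signed_z.loc[sub_ids]
            if len(matrix.signed_z.columns)
            else matrix.signed_z,
        )
        try:
            cand = cluster_snps(sub, **params)
        except Exception:  # noqa: BLE001 - a failed resample is data, not a crash
            log.warning("clustering failed in resample %d; column left absent", i, exc_info=True)
            continue
        mapping = match_cluster_labels(reference, cand)
        matched = np.array([mapping[int(l)] for l in cand.labels], dtype=float)
        table.iloc[[snp_index.get_loc(s) for s in sub_ids], i] = matched
    report = ResampleReport(
        n_resamples=n_resamples,
        frac=frac,
        seed=seed,
        per_cluster_consistency={},
        assignment_table=table,
        reference=reference,
    )
    report.per_cluster_consistency = consistency_summary(report, reference)
    return report


def consistency_summary(
    report: ResampleReport, reference: ClusterAssignment
) -> dict[int, float]:
    """Pooled per-cluster consistency percentages.

    consistency(c) = 100 * (# SNP-resample observations where the matched
    label equals c) / (# observations of SNPs whose full-sample label is c).
    """
    ref = pd.Series(reference.labels, index=reference.snp_ids)
    out: dict[int, float] = {}
    for c in reference.cluster_labels:
        rows = report.assignment_table.loc[ref.index[ref == c]]
        observed = rows.notna().to_numpy()
        n_obs = int(observed.sum())
        if n_obs == 0:
            log.warning("cluster %d never observed in any resample", c)
            continue
        n_match = int((rows.to_numpy() == c).sum())
        out[c] = 100.0 * n_match / n_obs
    return out
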