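"""Weighted correlation clustering of SNP association profiles.

SNPs are clustered from the pairwise similarity of their |z| profiles across
phenotypes: a soft-thresholded unsigned adjacency |cor|^power is denoised into
a topological overlap similarity, converted to a distance, and cut from an
average-linkage dendrogram with a minimum branch size.  Clusters whose
eigenprofiles (first principal axis of member profiles) are closer than a
dissimilarity threshold are merged.

Note the profile correlation here runs across only a handful of phenotype
columns (three in the motivating design), which is statistically coarse; the
topological overlap step is what makes the resulting clusters stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ComputationError, ConfigurationError, DataError
from .sumstats import HarmonizedZMatrix

log = logging.getLogger(__name__)

DEFAULT_POWER = 12.0
DEFAULT_MIN_SIZE = 30
DEFAULT_MERGE_DISSIM = 0.25
DEFAULT_CUT_HEIGHT_FRAC = 0.65
DEFAULT_SIGNED = True


@dataclass
class AdjacencyMatrix:
    snp_ids: list[str]
    a: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]
    power: float
    signed: bool = False


@dataclass
class TOMMatrix:
    snp_ids: list[str]
    t: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]


@dataclass
class ClusterAssignment:
    """Per-SNP integer labels: 1..K by decreasing cluster size, 0 = unassigned."""

    snp_ids: list[str]
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.snp_ids, self.labels) if l == label]

    @property
    def cluster_labels(self) -> list[int]:
        return sorted({int(l) for l in self.labels if l != 0})

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "label": self.labels.astype(int)})


@dataclass
class Eigenprofile:
    cluster_label: int
    vector: np.ndarray  # unit norm, length n_phenotypes


def soft_adjacency(
    matrix: HarmonizedZMatrix,
    power: float = DEFAULT_POWER,
    signed: bool = DEFAULT_SIGNED,
) -> AdjacencyMatrix:
    """Soft-threshold adjacency from profile correlations.

    Unsigned: a_ij = |cor(profile_i, profile_j)|^power.  Signed (default):
    a_ij = ((1 + cor)/2)^power, which keeps anti-correlated profiles apart.
    With few phenotype columns the signed form matters: a centred profile high
    in one phenotype is exactly anti-proportional to the complementary profile
    high in the other two, so the unsigned form cannot distinguish them.

    Profiles with zero variance across phenotypes cannot be correlated; their
    off-diagonal adjacencies are set to 0 (logged).
    """
    if power <= 0:
        raise ConfigurationError(f"power must be positive, got {power}")
    if len(matrix.phenotypes) < 2:
        raise ConfigurationError("adjacency needs at least two phenotype columns")
    x = matrix.absz.to_numpy(dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d SNPs with zero profile variance get zero adjacency", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c[np.isnan(c)] = 0.0
    c = np.clip(c, -1.0, 1.0)
    a = ((1.0 + c) / 2.0) ** power if signed else np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    a[degenerate, :] = 0.0
    a[:, degenerate] = 0.0
    a[np.diag_indices_from(a)] = 1.0
    return AdjacencyMatrix(snp_ids=matrix.snp_ids, a=a, power=power, signed=signed)


def tom_similarity(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: direct adjacency reinforced by shared neighbours.

    t_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; t_ii = 1.
    """
    b = adj.a.copy()
    np.fill_diagonal(b, 0.0)
    k = b.sum(axis=1)
    shared = b @ b  # (b@b)_ij = sum over all u != i,j since diag(b)=0
    numer = shared + b
    denom = np.minimum.outer(k, k) + 1.0 - b
    t = numer / denom
    np.fill_diagonal(t, 1.0)
    return TOMMatrix(snp_ids=list(adj.snp_ids), t=np.clip(t, 0.0, 1.0))


def hierarchical_clusters(
    tom: TOMMatrix,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height_frac: float = DEFAULT_CUT_HEIGHT_FRAC,
) -> ClusterAssignment:
    """Average-linkage dendrogram on d = 1 - TOM, cut at a fraction of its top merge.

    Branches below the cut with at least ``min_size`` leaves become clusters,
    numbered 1..K by decreasing size; everything else is labelled 0.
    """
    if min_size < 2:
        raise ConfigurationError(f"min_size must be >= 2, got {min_size}")
    n = len(tom.snp_ids)
    if n < min_size:
        raise DataError(f"only {n} SNPs: fewer than min_size={min_size}")
    d = 1.0 - tom.t
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(np.clip(d, 0.0, None), checks=False), method="average")
    cut = cut_height_frac * float(z[:, 2].max())
    flat = fcluster(z, t=cut, criterion="distance")
    labels = _filter_and_rank(flat, min_size)
    return ClusterAssignment(
        snp_ids=list(tom.snp_ids),
        labels=labels,
        params={"min_size": min_size, "cut_height_frac": cut_height_frac},
    )


def _filter_and_rank(flat: np.ndarray, min_size: int) -> np.ndarray:
    """Drop branches below min_size, renumber the rest 1..K by decreasing size.

    Size ties are broken by the smallest member position, so labels are
    deterministic for a fixed SNP order.
    """
    labels = np.zeros(len(flat), dtype=int)
    uniq, counts = np.unique(flat, return_counts=True)
    keep = [(int(c), int(u)) for u, c in zip(uniq, counts) if c >= min_size]
    first_pos = {u: int(np.flatnonzero(flat == u)[0]) for _, u in keep}
    keep.sort(key=lambda cu: (-cu[0], first_pos[cu[1]]))
    for new, (_, old) in enumerate(keep, start=1):
        labels[flat == old] = new
    return labels


def cluster_eigenprofile(matrix: HarmonizedZMatrix, members: list[str]) -> Eigenprofile:
    """First principal axis (in phenotype space) of a cluster's member profiles.

    Each member's profile is standardized across phenotypes (the module-
    eigengene construct: correlation-similar profiles share a centred shape,
    so the standardized matrix is near rank one and its leading right singular
    vector is the cluster's shape direction).  Returned with unit norm,
    sign-oriented so its correlation with the cluster's mean raw profile is
    non-negative.  If all member profiles have zero variance the shape is
    undefined and a ComputationError is raised; individual flat profiles are
    dropped from the decomposition.
    """
    if len(members) < 2:
        raise DataError("eigenprofile needs at least two members")
    x = matrix.absz.loc[members].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=1)
    ok = sd > 0
    if not ok.any():
        raise ComputationError("zero-variance submatrix: eigenprofile undefined")
    xs = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    v = vt[0]
    v = v / np.linalg.norm(v)
    if _orientation_sign(v, mu) < 0:
        v = -v
    return Eigenprofile(cluster_label=-1, vector=v)


def _orientation_sign(v: np.ndarray, mean_profile: np.ndarray) -> float:
    if np.std(mean_profile) > 0 and np.std(v) > 0:
        c = np.corrcoef(v, mean_profile)[0, 1]
        if not np.isnan(c) and c != 0:
            return float(np.sign(c))
    s = float(v.sum())
    return 1.0 if s >= 0 else -1.0


def _profile_cor(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def merge_close_clusters(
    assign: ClusterAssignment,
    matrix: HarmonizedZMatrix,
    merge_dissim: float = DEFAULT_MERGE_DISSIM,
) -> ClusterAssignment:
    """Iteratively merge the closest cluster pair while their eigenprofile
    dissimilarity 1 - cor is below ``merge_dissim``; relabel by size at the end."""
    if assign.n_clusters == 0:
        raise DataError("no clusters to merge")
    labels = assign.labels.copy()
    while True:
        active = sorted({int(l) for l in labels if l != 0})
        if len(active) < 2:
            break
        eig = {
            l: cluster_eigenprofile(matrix, [s for s, li in zip(assign.snp_ids, labels) if li == l]).vector
            for l in active
        }
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                dis = 1.0 - _profile_cor(eig[a], eig[b])
                if best is None or dis < best[0] - 1e-12:
                    best = (dis, a, b)
        assert best is not None
        if best[0] >= merge_dissim:
            break
        _, a, b = best
        labels[labels == b] = a
    labels = _renumber_by_size(labels)
    params = dict(assign.params)
    params["merge_dissim"] = merge_dissim
    return ClusterAssignment(snp_ids=list(assign.snp_ids), labels=labels, params=params)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(labels[labels != 0], return_counts=True)
    first_pos = {int(u): int(np.flatnonzero(labels == u)[0]) for u in uniq}
    order = sorted(zip(uniq, counts), key=lambda uc: (-uc[1], first_pos[int(uc[0])]))
    out = np.zeros_like(labels)
    for new, (old, _) in enumerate(order, start=1):
        out[labels == old] = new
    return out


def cluster_snps(
    matrix: HarmonizedZMatrix,
    power: float = DEFAULT_POWER,
    min_size: int = DEFAULT_MIN_SIZE,
    merge_dissim: float = DEFAULT_MERGE_DISSIM,
    cut_height_frac: float = DEFAULT_CUT_HEIGHT_FRAC,
    signed: bool = DEFAULT_SIGNED,
) -> ClusterAssignment:
    """Full clustering stage: adjacency -> TOM -> dendrogram cut -> merge."""
    adj = soft_adjacency(matrix, power=power, signed=signed)
    tom = tom_similarity(adj)
    assign = hierarchical_clusters(tom, min_size=min_size, cut_height_frac=cut_height_frac)
    if assign.n_clusters == 0:
        log.warning("no branch reached min_size=%d; all SNPs unassigned", min_size)
        assign.params.update(power=power, signed=signed, merge_dissim=merge_dissim)
        return assign
    merged = merge_close_clusters(assign, matrix, merge_dissim=merge_dissim)
    merged.params.update(power=power, signed=signed)
    return merged
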