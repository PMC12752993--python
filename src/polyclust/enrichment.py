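"""Gene-set overrepresentation for cluster SNPs.

Cluster SNPs are mapped to genes through a user-supplied table (offline and
deterministic — no live annotation service), and each gene-set term is tested
with the upper-tail hypergeometric probability P(X >= overlap) of drawing the
query from the background, with fold enrichment observed/expected and BH FDR
across terms.  Results on real annotation snapshots are version-dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, DataError
from .assoc import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Background gene universe plus term_id -> {name, members} gene sets."""

    background: set[str]
    terms: dict[str, dict]

    def __post_init__(self) -> None:
        if not self.background:
            raise ConfigurationError("empty background gene list")
        for tid, t in self.terms.items():
            if not t["members"]:
                raise ConfigurationError(f"term {tid!r} has no members")
            extra = t["members"] - self.background
            if extra:
                raise ConfigurationError(f"term {tid!r} has members outside the background")


@dataclass
class EnrichResult:
    term_id: str
    name: str
    n_query: int
    n_term: int
    n_overlap: int
    expected: float
    fold: float
    p: float
    p_adj: float | None = None


def read_gmt(path) -> GeneSetCollection:
    """GMT gene sets: term, description, members...; background = union of members."""
    terms: dict[str, dict] = {}
    background: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = {g for g in parts[2:] if g}
            terms[parts[0]] = {"name": parts[1], "members": members}
            background |= members
    if not terms:
        raise DataError(f"no terms parsed from {path}")
    return GeneSetCollection(background=background, terms=terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, t in sorted(collection.terms.items()):
            fh.write("\t".join([tid, t["name"], *sorted(t["members"])]) + "\n")


def read_snp_gene_mapping(path) -> pd.DataFrame:
    """Delimited snp_id -> gene table, one pair per row (a SNP may repeat)."""
    m = pd.read_csv(path, sep=None, engine="python", comment="#")
    m.columns = ["snp_id", "gene"] + list(m.columns[2:])
    return m[["snp_id", "gene"]]


def snp_to_gene(snps: list[str], mapping: pd.DataFrame) -> set[str]:
    """Union of genes mapped by the given SNPs; duplicates collapse, unmapped
    SNPs are counted and logged."""
    sub = mapping[mapping["snp_id"].isin(set(snps))]
    mapped_snps = set(sub["snp_id"])
    n_unmapped = len(set(snps) - mapped_snps)
    if n_unmapped:
        log.info("%d of %d SNPs had no gene mapping", n_unmapped, len(snps))
    genes = set(sub["gene"])
    if not genes:
        raise DataError("no genes mapped for this SNP list")
    return genes


def overrepresentation_test(
    query: set[str], collection: GeneSetCollection
) -> list[EnrichResult]:
    """Hypergeometric overrepresentation of the query in every term.

    expected = n_query * n_term / |background|; fold = overlap / expected;
    p = P(X >= overlap) for X hypergeometric(|background|, n_term, n_query).
    Query genes outside the background are dropped with a warning.  Results
    are sorted by adjusted p then decreasing fold.
    """
    if not query:
        raise DataError("empty query gene set")
    outside = query - collection.background
    if outside:
        log.warning("%d query genes outside the background were dropped", len(outside))
    q = query & collection.background
    if not q:
        raise DataError("no query genes inside the background")
    n_bg = len(collection.background)
    n_query = len(q)
    results = []
    for tid, t in collection.terms.items():
        n_term = len(t["members"])
        k = len(q & t["members"])
        expected = n_query * n_term / n_bg
        fold = k / expected if expected > 0 else float("nan")
        p = float(hypergeom.sf(k - 1, n_bg, n_term, n_query))
        results.append(
            EnrichResult(
                term_id=tid,
                name=t["name"],
                n_query=n_query,
                n_term=n_term,
                n_overlap=k,
                expected=expected,
                fold=fold,
                p=min(max(p, 0.0), 1.0) or 1e-300,
            )
        )
    adj = bh_adjust([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    results.sort(key=lambda r: (r.p_adj, -r.fold, r.term_id))
    return results


def enrichment_frame(results: list[EnrichResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "n_query": r.n_query,
                "n_term": r.n_term,
                "n_overlap": r.n_overlap,
                "expected": r.expected,
                "fold": r.fold,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in results
        ]
    )
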