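"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the study conditions of a three-
phenotype (ALS / FTLD-TDP / HS-Aging-like) summary-statistic integration:

* |z| profiles containing five planted association-profile groups — three
  single-phenotype groups an order of magnitude larger than two phenotype-pair
  groups — plus an incoherent null background;
* an LD-blocked diploid reference panel at Hardy-Weinberg equilibrium with a
  matching allele-frequency table;
* a cohort whose clinical group and regional TDP-43-like burden depend on the
  latent difference between two cluster risk scores;
* a SNP-to-gene mapping and a GMT gene-set collection with one spiked term.

|z| profiles are simulated directly rather than via genotype-level GWAS: the
clustering consumes nothing but |z|, so this is the minimal faithful structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .errors import ConfigurationError
from . import prs as prs_mod
from .ld import DosageMatrix
from .sumstats import StudyStats

PHENOTYPES = ("ALS", "FTLD", "HS")

#: clinical group labels in fixed order (low latent -> high latent)
CLINICAL_GROUPS = ("MND-only", "Cog+MND", "Cog-only")

#: brain regions whose burden tracks the latent FTLD-vs-ALS score difference
FTLD_REGIONS = ("cingulate", "angular", "midfrontal", "temporal")
#: regions whose burden is independent of the score difference
ALS_REGIONS = ("motor_cortex", "spinal_cord")

#: marginal distribution of the 5-level ordinal burden scale {0, 0.5, 1, 2, 3}
BURDEN_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)
_BURDEN_MARGINAL = (0.20, 0.20, 0.25, 0.20, 0.15)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    size: int
    mean_absz_profile: tuple[float, float, float]
    noise_sd: float = 0.3


#: five planted groups: single-phenotype groups are an order of magnitude
#: larger than phenotype-pair groups (1910/1450/1042 vs 144/121)
DEFAULT_GROUPS = (
    GroupSpec("ALS", 1910, (4.5, 0.8, 0.8)),
    GroupSpec("FTLD", 1450, (0.8, 4.5, 0.8)),
    GroupSpec("HS", 1042, (0.8, 0.8, 4.5)),
    GroupSpec("ALS-FTLD", 144, (3.2, 3.2, 0.8)),
    GroupSpec("FTLD-HS", 121, (0.8, 3.2, 3.2)),
)

SINGLE_PHENOTYPE_GROUPS = ("ALS", "FTLD", "HS")


@dataclass(frozen=True)
class SimConfig:
    """Defaults mirror the study conditions: ~5k selected SNPs in five profile
    groups plus null background, and a 260-individual cohort."""

    n_snps: int = 4945
    group_spec: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    n_null: int = 278
    null_mean_absz: float = 2.2
    null_noise_sd: float = 0.9
    n_ref: int = 200
    ld_block_size: int = 10
    ld_rho: float = 0.8
    panel_missing_rate: float = 0.02
    multiallelic_rate: float = 0.01
    n_cohort: int = 260
    group_effect: float = 1.0
    burden_effect: float = 0.8
    burden_missing_rate: float = 0.33
    cohort_missing_rate: float = 0.02
    seed: int = 13

    def __post_init__(self) -> None:
        total = sum(g.size for g in self.group_spec) + self.n_null
        if total != self.n_snps:
            raise ConfigurationError(
                f"group sizes ({total - self.n_null}) + n_null ({self.n_null}) "
                f"!= n_snps ({self.n_snps})"
            )
        if any(g.size <= 0 for g in self.group_spec) or self.n_null < 0:
            raise ConfigurationError("group sizes must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must be in [0, 1)")


def scaled_config(n_snps: int, base: SimConfig | None = None, **overrides) -> SimConfig:
    """Rescale the default five-group structure to a different SNP count,
    preserving group proportions (pair groups stay ~an order of magnitude
    smaller than single-phenotype groups)."""
    base = base or SimConfig()
    factor = n_snps / base.n_snps
    groups = []
    for g in base.group_spec:
        groups.append(replace(g, size=max(2, round(g.size * factor))))
    n_null = n_snps - sum(g.size for g in groups)
    if n_null < 0:
        raise ConfigurationError(f"n_snps={n_snps} too small for the five-group structure")
    return replace(base, n_snps=n_snps, group_spec=tuple(groups), n_null=n_null, **overrides)


def _snp_id(i: int) -> str:
    return f"snp{i:06d}"


def _truncnorm0(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (|z| cannot be negative)."""
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=mean.shape, random_state=rng)


def simulate_summary_stats(config: SimConfig) -> tuple[list[StudyStats], pd.Series]:
    """Three studies over the same variants, plus planted truth labels.

    The ALS-like study reports signed beta/se (se = 1, random signs), the
    FTLD-like study reports beta/se and the matching two-sided p, and the
    HS-like study reports p only — so direction of effect is available for the
    first two but not the third.  Truth labels (group name, or "null") are for
    evaluation only and are not an input to any pipeline stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_snps
    means = np.empty((n, 3))
    truth = np.empty(n, dtype=object)
    sds = np.empty(n)
    pos = 0
    for g in config.group_spec:
        means[pos : pos + g.size] = np.asarray(g.mean_absz_profile)
        sds[pos : pos + g.size] = g.noise_sd
        truth[pos : pos + g.size] = g.name
        pos += g.size
    means[pos:] = config.null_mean_absz
    sds[pos:] = config.null_noise_sd
    truth[pos:] = "null"

    absz = np.empty((n, 3))
    for j in range(3):
        absz[:, j] = truncnorm.rvs(
            (0.0 - means[:, j]) / sds, np.inf, loc=means[:, j], scale=sds, random_state=rng
        )

    snp_ids = [_snp_id(i) for i in range(n)]
    bases = np.array(list("ACGT"))
    eff_idx = rng.integers(0, 4, size=n)
    oth_idx = (eff_idx + rng.integers(1, 4, size=n)) % 4
    base_cols = {
        "variant_id": snp_ids,
        "chrom": ["1"] * n,
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": bases[eff_idx],
        "other_allele": bases[oth_idx],
    }
    signs = rng.choice([-1.0, 1.0], size=(n, 2))
    two_sided_p = 2.0 * ndtr(-absz)  # 2*(1 - Phi(|z|))

    studies = [
        StudyStats(
            "ALS",
            pd.DataFrame(
                {**base_cols, "beta": signs[:, 0] * absz[:, 0], "se": 1.0, "p": np.nan}
            ),
        ),
        StudyStats(
            "FTLD",
            pd.DataFrame(
                {
                    **base_cols,
                    "beta": signs[:, 1] * absz[:, 1],
                    "se": 1.0,
                    "p": np.clip(two_sided_p[:, 1], 1e-300, 1.0),
                }
            ),
        ),
        StudyStats(
            "HS",
            pd.DataFrame(
                {
                    **base_cols,
                    "beta": np.nan,
                    "se": np.nan,
                    "p": np.clip(two_sided_p[:, 2], 1e-300, 1.0),
                }
            ),
        ),
    ]
    truth_s = pd.Series(truth, index=pd.Index(snp_ids, name="snp_id"), name="group")
    return studies, truth_s


def variant_table(studies: list[StudyStats], config: SimConfig) -> pd.DataFrame:
    """Variant metadata (alleles + multiallelic flag) shared by the studies."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    t = studies[0].table[["variant_id", "effect_allele", "other_allele"]].copy()
    t["multiallelic"] = rng.random(len(t)) < config.multiallelic_rate
    return t.set_index("variant_id")


def simulate_reference_panel(
    config: SimConfig, variants: pd.DataFrame
) -> tuple[DosageMatrix, pd.DataFrame]:
    """LD-blocked diploid panel at HWE plus a realized allele-frequency table.

    Haplotypes come from a latent first-order Gaussian chain with neighbour
    correlation ``ld_rho`` inside blocks of ``ld_block_size`` consecutive SNPs
    (fresh at each block start), thresholded at each SNP's drawn frequency; a
    diploid dosage is the sum of two independent haplotypes, counted on the
    effect allele.
    """
    if config.n_ref < 50:
        raise ConfigurationError("n_ref must be >= 50")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    snp_ids = list(variants.index)
    n_snp = len(snp_ids)
    freqs = rng.uniform(0.05, 0.95, size=n_snp)

    def haplotypes() -> np.ndarray:
        x = np.empty((config.n_ref, n_snp))
        rho = config.ld_rho
        innov = rng.standard_normal((config.n_ref, n_snp))
        for j in range(n_snp):
            if j % config.ld_block_size == 0:
                x[:, j] = innov[:, j]
            else:
                x[:, j] = rho * x[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j]
        return (x < ndtri(freqs)).astype(float)

    dose = haplotypes() + haplotypes()
    miss = rng.random(dose.shape) < config.panel_missing_rate
    dose[miss] = np.nan

    sample_ids = [f"ref{i:04d}" for i in range(config.n_ref)]
    dose_df = pd.DataFrame(dose, index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids)
    realized = np.nanmean(dose, axis=0) / 2.0
    freq_rows = []
    for sid, f in zip(snp_ids, realized):
        freq_rows.append((sid, variants.loc[sid, "effect_allele"], f))
        freq_rows.append((sid, variants.loc[sid, "other_allele"], 1.0 - f))
    freq_table = pd.DataFrame(freq_rows, columns=["snp_id", "allele", "freq"])
    panel = DosageMatrix(dose=dose_df, counted_allele=variants["effect_allele"].copy())
    return panel, freq_table


def simulate_cohort(
    config: SimConfig,
    weight_tables: list[prs_mod.WeightTable],
    delta_pair: tuple[int, int] | None = None,
    variants: pd.DataFrame | None = None,
    freq_table: pd.DataFrame | None = None,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Cohort genotypes at HWE plus a trait table driven by latent risk scores.

    True cluster scores are computed with the scoring formula itself; the
    latent variable is the standardized difference between the first two weight
    tables' scores (``delta_pair`` selects which, defaulting to tables 0 and 1,
    read as FTLD-like minus ALS-like).  Clinical group comes from a multinomial
    whose logits shift by ``group_effect`` times the latent score; burden in
    FTLD-characteristic regions shifts by ``burden_effect`` times the latent
    score, while ALS-characteristic regions are independent of it.  Covariates
    match the cohort marginals: age ~ N(64.5, 9.9), P(male) = 0.57, prior-GWAS
    inclusion (none/ALS/FTLD) = (0.62, 0.28, 0.10).
    """
    if len(weight_tables) < 2:
        raise ConfigurationError("simulate_cohort needs two weight tables")
    ia, ib = delta_pair if delta_pair is not None else (0, 1)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    all_snps: list[str] = []
    eff: dict[str, str] = {}
    oth: dict[str, str] = {}
    freq: dict[str, float] = {}
    if variants is not None and freq_table is not None:
        # genotype every simulated variant at its reference frequency
        flookup = {
            (r.snp_id, r.allele): float(r.freq)
            for r in freq_table.itertuples()
            if "allele" in freq_table.columns
        }
        for sid, row in variants.iterrows():
            e, o = row["effect_allele"], row["other_allele"]
            f_e = flookup.get((sid, e))
            if f_e is None or not 0 < f_e < 1:
                continue
            all_snps.append(sid)
            eff[sid], oth[sid], freq[sid] = e, o, f_e
    for wt in weight_tables:
        for sid, row in wt.table.iterrows():
            if sid not in freq:
                all_snps.append(sid)
                freq[sid] = float(row["ref_freq"])
                eff[sid] = row["effect_allele"]
                oth[sid] = row["other_allele"]
    f = np.array([freq[s] for s in all_snps])

    n = config.n_cohort
    g_eff = (rng.random((n, len(all_snps))) < f).astype(float) + (
        rng.random((n, len(all_snps))) < f
    ).astype(float)
    # count a random allele per SNP so downstream alignment has to flip some
    count_effect = rng.random(len(all_snps)) < 0.5
    dose = np.where(count_effect, g_eff, 2.0 - g_eff)
    counted = pd.Series(
        np.where(count_effect, [eff[s] for s in all_snps], [oth[s] for s in all_snps]),
        index=pd.Index(all_snps, name="snp_id"),
    )
    sample_ids = [f"ind{i:04d}" for i in range(n)]
    dose_df = pd.DataFrame(dose, index=pd.Index(sample_ids, name="sample_id"), columns=all_snps)
    genotypes = DosageMatrix(dose=dose_df, counted_allele=counted)

    scores = []
    for wt in weight_tables:
        aligned = prs_mod.align_alleles(wt, genotypes)
        scores.append(prs_mod.score_individuals(aligned, genotypes).table["score"])
    delta = scores[ia] - scores[ib]
    zd = ((delta - delta.mean()) / delta.std()).to_numpy()

    base = np.log(np.array([125, 31, 104]) / 260.0)
    slope = np.array([-1.0, 0.0, 1.0]) * config.group_effect
    logits = base[None, :] + slope[None, :] * zd[:, None]
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = probs.cumsum(axis=1)
    group_idx = (u[:, None] > cum).sum(axis=1)
    clinical_group = np.array(CLINICAL_GROUPS, dtype=object)[group_idx]

    cuts = ndtri(np.cumsum(_BURDEN_MARGINAL))[:-1]
    burden_cols = {}
    for region in FTLD_REGIONS:
        latent = config.burden_effect * zd + rng.standard_normal(n)
        burden_cols[f"burden_{region}"] = _ordinalize(latent / np.sqrt(1 + config.burden_effect**2), cuts)
    for region in ALS_REGIONS:
        latent = rng.standard_normal(n)
        burden_cols[f"burden_{region}"] = _ordinalize(latent, cuts)

    cohort = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "clinical_group": clinical_group,
            "age": rng.normal(64.5, 9.9, size=n),
            "sex": (rng.random(n) < 0.57).astype(int),
            "prior_gwas": rng.choice(["none", "ALS", "FTLD"], size=n, p=[0.62, 0.28, 0.10]),
            "mutation": rng.choice(
                ["none", "C9orf72", "GRN", "TARDBP", "TBK1", "VCP"],
                size=n,
                p=[0.481, 0.435, 0.064, 0.004, 0.008, 0.008],
            ),
            **burden_cols,
        }
    )
    no_path = rng.random(n) < config.burden_missing_rate
    for region in FTLD_REGIONS + ALS_REGIONS:
        cohort.loc[no_path, f"burden_{region}"] = np.nan

    miss = rng.random(dose_df.shape) < config.cohort_missing_rate
    dose_df.values[miss] = np.nan
    return genotypes, cohort


def truth_weight_tables(
    config: SimConfig,
    studies: list[StudyStats],
    truth: pd.Series,
    freq_table: pd.DataFrame,
) -> list[prs_mod.WeightTable]:
    """Generative-truth weight tables for the ALS-like and FTLD-like groups.

    Built from the planted group memberships (not recovered clusters): the
    cohort's latent risk must not depend on the analysis being run on it.
    Returned in (FTLD-like, ALS-like) order so the default latent difference
    reads FTLD-minus-ALS.
    """
    by_label = {s.study_label: s for s in studies}
    als_snps = sorted(truth.index[truth == "ALS"])
    ftld_snps = sorted(truth.index[truth == "FTLD"])
    wt_als = prs_mod.build_weight_table(als_snps, by_label["ALS"], freq_table, cluster_label=1)
    wt_ftld = prs_mod.build_weight_table(
        ftld_snps, by_label["FTLD"], freq_table, minor_allele_rule=True, cluster_label=2
    )
    return [wt_ftld, wt_als]


def _ordinalize(latent: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(cuts, latent)
    return np.asarray(BURDEN_LEVELS, dtype=float)[idx]


def make_annotation_fixture(
    snp_ids: list[str],
    n_genes: int = 400,
    n_terms: int = 40,
    seed: int = 0,
    spiked_snps: list[str] | None = None,
):
    """SNP->gene mapping (position order) and a GMT-style collection with one
    term spiked with genes of ``spiked_snps`` (enriched by construction)."""
    from .enrichment import GeneSetCollection

    if n_genes < 1 or n_terms < 1:
        raise ConfigurationError("n_genes and n_terms must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    n = len(snp_ids)
    mapping = pd.DataFrame(
        {"snp_id": snp_ids, "gene": [genes[i * n_genes // n] for i in range(n)]}
    )
    background = set(genes)
    terms = {}
    for t in range(n_terms - 1):
        size = int(rng.integers(10, 51))
        members = set(rng.choice(genes, size=size, replace=False))
        terms[f"TERM{t:04d}"] = {"name": f"random term {t}", "members": members}
    if spiked_snps:
        spiked_genes = sorted(set(mapping.set_index("snp_id").loc[
            [s for s in spiked_snps if s in set(snp_ids)], "gene"
        ]))
        pick = min(len(spiked_genes), 30)
        members = set(rng.choice(spiked_genes, size=pick, replace=False)) if pick else set()
    else:
        members = set(rng.choice(genes, size=20, replace=False))
    terms["TERM_SPIKED"] = {"name": "spiked term", "members": members}
    return mapping, GeneSetCollection(background=background, terms=terms)
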