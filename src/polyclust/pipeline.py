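"""Stage orchestration: validated config, dependency-ordered execution,
provenance-stamped plain-text artifacts, byte-identical reruns."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, enrichment, io, ld, prs, robustness, simulate, sumstats, wcna
from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

STAGES = ("simulate", "harmonize", "cluster", "robustness", "prune", "score", "associate", "enrich")

#: column-role schema of the summary-statistics files the simulate stage writes
SIM_SCHEMA = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "p": "p",
}


@dataclass
class PipelineConfig:
    outdir: str = "polyclust_out"
    seed: int = 13
    #: top-|z| selection fraction; None when the input already is the selected set
    q: float | None = None
    power: float = wcna.DEFAULT_POWER
    signed: bool = wcna.DEFAULT_SIGNED
    min_size: int = wcna.DEFAULT_MIN_SIZE
    merge_dissim: float = wcna.DEFAULT_MERGE_DISSIM
    cut_height_frac: float = wcna.DEFAULT_CUT_HEIGHT_FRAC
    n_resamples: int = robustness.DEFAULT_N_RESAMPLES
    frac: float = robustness.DEFAULT_FRAC
    r2_threshold: float = ld.DEFAULT_R2_THRESHOLD
    max_missing: float = ld.DEFAULT_MAX_MISSING
    fdr_alpha: float = assoc.DEFAULT_FDR_ALPHA
    #: studies whose effect allele is reassigned to the reference minor allele
    minor_allele_studies: tuple = ("FTLD",)
    sim: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (self.q is None or 0 < self.q < 1, "q must be in (0,1) or null"),
            (self.power > 0, "power must be positive"),
            (self.min_size >= 2, "min_size must be >= 2"),
            (0 <= self.merge_dissim <= 1, "merge_dissim must be in [0,1]"),
            (0 < self.cut_height_frac <= 1, "cut_height_frac must be in (0,1]"),
            (self.n_resamples >= 1, "n_resamples must be >= 1"),
            (0 < self.frac <= 1, "frac must be in (0,1]"),
            (0 <= self.r2_threshold <= 1, "r2_threshold must be in [0,1]"),
            (0 <= self.max_missing < 1, "max_missing must be in [0,1)"),
            (0 < self.fdr_alpha < 1, "fdr_alpha must be in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)
        self.minor_allele_studies = tuple(self.minor_allele_studies)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["minor_allele_studies"] = list(self.minor_allele_studies)
        return d

    def meta(self, stage: str) -> dict:
        return {
            "config": io.config_hash(self.to_dict()),
            "seed": self.seed,
            "stage": stage,
            "polyclust": __version__,
        }


def _p(config: PipelineConfig, name: str) -> Path:
    return Path(config.outdir) / name


def _require(config: PipelineConfig, name: str, produced_by: str) -> Path:
    path = Path(config.paths.get(name.split(".")[0], _p(config, name)))
    if not path.exists():
        raise DataError(
            f"missing input {path}: run the {produced_by!r} stage first or set paths.{name.split('.')[0]}"
        )
    return path


def _sim_config(config: PipelineConfig) -> simulate.SimConfig:
    kwargs = dict(config.sim)
    groups = kwargs.pop("group_spec", None)
    if groups is not None:
        kwargs["group_spec"] = tuple(simulate.GroupSpec(**g) for g in groups)
    kwargs.setdefault("seed", config.seed)
    return simulate.SimConfig(**kwargs)


def stage_simulate(config: PipelineConfig) -> None:
    sc = _sim_config(config)
    meta = config.meta("simulate")
    studies, truth = simulate.simulate_summary_stats(sc)
    for s in studies:
        io.write_table(s.table, _p(config, f"sumstats_{s.study_label}.tsv"), meta)
    io.write_table(truth.reset_index(), _p(config, "truth.tsv"), meta)

    variants = simulate.variant_table(studies, sc)
    io.write_table(variants.reset_index(), _p(config, "variants.tsv"), meta)
    panel, freq_table = simulate.simulate_reference_panel(sc, variants)
    io.write_dosage_tsv(panel, _p(config, "panel.tsv"), meta)
    io.write_table(freq_table, _p(config, "freqs.tsv"), meta)

    wts = simulate.truth_weight_tables(sc, studies, truth, freq_table)
    genotypes, cohort = simulate.simulate_cohort(
        sc, wts, variants=variants, freq_table=freq_table
    )
    io.write_dosage_tsv(genotypes, _p(config, "cohort_genotypes.tsv"), meta)
    io.write_table(cohort, _p(config, "cohort.tsv"), meta)

    spiked = sorted(truth.index[truth == "ALS"])
    mapping, collection = simulate.make_annotation_fixture(
        list(truth.index), seed=sc.seed, spiked_snps=spiked
    )
    io.write_table(mapping, _p(config, "mapping.tsv"), meta)
    enrichment.write_gmt(collection, _p(config, "genesets.gmt"))


def _read_studies(config: PipelineConfig) -> list[sumstats.StudyStats]:
    spec = config.paths.get("sumstats")
    if spec:
        return [
            sumstats.read_sumstats(entry["path"], entry.get("schema", SIM_SCHEMA), label)
            for label, entry in spec.items()
        ]
    studies = []
    for label in [p.name[len("sumstats_") : -len(".tsv")] for p in sorted(Path(config.outdir).glob("sumstats_*.tsv"))]:
        path = _require(config, f"sumstats_{label}.tsv", "simulate")
        studies.append(sumstats.read_sumstats(path, SIM_SCHEMA, label))
    if len(studies) < 2:
        raise DataError("found fewer than two summary-statistics files; run 'simulate' or set paths.sumstats")
    return studies


def stage_harmonize(config: PipelineConfig) -> None:
    studies = _read_studies(config)
    matrix = sumstats.harmonize_studies(studies)
    if config.q is not None:
        matrix = sumstats.select_top_fraction(matrix, config.q)
    meta = config.meta("harmonize")
    io.write_table(matrix.absz.reset_index(), _p(config, "harmonized.tsv"), meta)
    io.write_table(matrix.signed_z.reset_index(), _p(config, "signed_z.tsv"), meta)


def _read_harmonized(config: PipelineConfig) -> sumstats.HarmonizedZMatrix:
    absz = io.read_table(_require(config, "harmonized.tsv", "harmonize"), index_col=0)
    signed_path = _p(config, "signed_z.tsv")
    signed = (
        io.read_table(signed_path, index_col=0) if signed_path.exists() else pd.DataFrame(index=absz.index)
    )
    return sumstats.HarmonizedZMatrix(absz=absz, signed_z=signed)


def _cluster_params(config: PipelineConfig) -> dict:
    return {
        "power": config.power,
        "signed": config.signed,
        "min_size": config.min_size,
        "merge_dissim": config.merge_dissim,
        "cut_height_frac": config.cut_height_frac,
    }


def stage_cluster(config: PipelineConfig) -> None:
    matrix = _read_harmonized(config)
    assign = wcna.cluster_snps(matrix, **_cluster_params(config))
    io.write_table(assign.to_frame(), _p(config, "clusters.tsv"), config.meta("cluster"))


def _read_clusters(config: PipelineConfig) -> wcna.ClusterAssignment:
    df = io.read_table(_require(config, "clusters.tsv", "cluster"))
    return wcna.ClusterAssignment(
        snp_ids=list(df["snp_id"]), labels=df["label"].to_numpy(dtype=int)
    )


def stage_robustness(config: PipelineConfig) -> None:
    matrix = _read_harmonized(config)
    reference = _read_clusters(config)
    report = robustness.resample_assignments(
        matrix,
        params=_cluster_params(config),
        n_resamples=config.n_resamples,
        frac=config.frac,
        seed=config.seed,
        reference=reference,
    )
    meta = config.meta("robustness")
    cons = pd.DataFrame(
        sorted(report.per_cluster_consistency.items()), columns=["label", "consistency_pct"]
    )
    io.write_table(cons, _p(config, "robustness_consistency.tsv"), meta)
    io.write_table(
        report.assignment_table.reset_index().rename(columns={"index": "snp_id"}),
        _p(config, "robustness_assignments.tsv"),
        meta,
    )


def stage_prune(config: PipelineConfig) -> None:
    assign = _read_clusters(config)
    matrix = _read_harmonized(config)
    panel = io.read_dosage(_require(config, "panel.tsv", "simulate"))
    variants = io.read_table(_require(config, "variants.tsv", "simulate"), index_col=0)
    priority = matrix.row_max()
    rows = []
    for label in assign.cluster_labels:
        members = assign.members(label)
        usable = ld.genotype_filters(members, panel, variants, config.max_missing)
        if len(usable) < 2:
            log.warning("cluster %d: %d usable SNPs; kept as-is", label, len(usable))
            rows += [(s, label) for s in usable]
            continue
        ldm = ld.pairwise_r2(panel, usable)
        kept = ld.greedy_prune(usable, priority, ldm, config.r2_threshold)
        rows += [(s, label) for s in kept]
    io.write_table(
        pd.DataFrame(rows, columns=["snp_id", "label"]),
        _p(config, "pruned.tsv"),
        config.meta("prune"),
    )


def classify_clusters(
    matrix: sumstats.HarmonizedZMatrix, assign: wcna.ClusterAssignment
) -> pd.DataFrame:
    """Label each cluster single-phenotype or phenotype-pair by the ideal
    profile direction its mean |z| profile correlates with most strongly."""
    phenos = matrix.phenotypes
    ideals: list[tuple[str, str, np.ndarray]] = []
    for i, ph in enumerate(phenos):
        v = np.zeros(len(phenos))
        v[i] = 1.0
        ideals.append(("single", ph, v))
    for i, j in itertools.combinations(range(len(phenos)), 2):
        v = np.zeros(len(phenos))
        v[i] = v[j] = 1.0
        ideals.append(("pair", f"{phenos[i]}+{phenos[j]}", v))
    rows = []
    for label in assign.cluster_labels:
        m = matrix.absz.loc[assign.members(label)].mean(axis=0).to_numpy()
        best = max(ideals, key=lambda kv: _cor(m, kv[2]))
        rows.append(
            {
                "label": label,
                "kind": best[0],
                "phenotype": best[1],
                "cor": _cor(m, best[2]),
                "size": len(assign.members(label)),
            }
        )
    return pd.DataFrame(rows)


def _cor(u, v) -> float:
    u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if np.std(u) == 0 or np.std(v) == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def stage_score(config: PipelineConfig) -> None:
    pruned = io.read_table(_require(config, "pruned.tsv", "prune"))
    matrix = _read_harmonized(config)
    assign = wcna.ClusterAssignment(
        snp_ids=list(pruned["snp_id"]), labels=pruned["label"].to_numpy(dtype=int)
    )
    studies = {s.study_label: s for s in _read_studies(config)}
    freq_table = prs.load_freq_table(_require(config, "freqs.tsv", "simulate"))
    genotypes = io.read_dosage(_require(config, "cohort_genotypes.tsv", "simulate"))

    roles = classify_clusters(matrix, assign)
    meta = config.meta("score")
    io.write_table(roles, _p(config, "cluster_roles.tsv"), meta)

    scored: dict[str, prs.PRSResult] = {}
    for row in roles.itertuples():
        if row.kind != "single":
            continue
        study = studies.get(row.phenotype)
        if study is None or not study.signed:
            log.info(
                "cluster %d (%s): no signed study available; score skipped",
                row.label,
                row.phenotype,
            )
            continue
        wt = prs.build_weight_table(
            assign.members(row.label),
            study,
            freq_table,
            minor_allele_rule=row.phenotype in config.minor_allele_studies,
            cluster_label=row.label,
        )
        aligned = prs.align_alleles(wt, genotypes)
        result = prs.score_individuals(aligned, genotypes, config.max_missing)
        io.write_table(
            aligned.table.reset_index(), _p(config, f"weights_c{row.label}_{row.phenotype}.tsv"), meta
        )
        io.write_table(
            result.table.reset_index(), _p(config, f"scores_c{row.label}_{row.phenotype}.tsv"), meta
        )
        scored[row.phenotype] = result

    pair = [ph for ph in ("FTLD", "ALS") if ph in scored]
    if len(pair) == 2:
        delta = prs.relative_score(scored["FTLD"], scored["ALS"])
        io.write_table(delta.reset_index(), _p(config, "delta.tsv"), meta)
    else:
        log.warning("relative score needs both FTLD-like and ALS-like scores; delta skipped")


def stage_associate(config: PipelineConfig) -> None:
    cohort = io.read_table(_require(config, "cohort.tsv", "simulate")).set_index("sample_id")
    delta = io.read_table(_require(config, "delta.tsv", "score"), index_col=0)["delta"]
    meta = config.meta("associate")
    covs = [cohort["age"].reindex(delta.index), cohort["sex"].reindex(delta.index),
            cohort["prior_gwas"].astype(str).reindex(delta.index)]

    clinical = assoc.ancova_f_test(
        delta, cohort["clinical_group"].reindex(delta.index), covs, test_label="delta_vs_clinical_group"
    )
    clinical.p_adj = clinical.p
    io.write_table(assoc.results_frame([clinical]), _p(config, "assoc_clinical.tsv"), meta)
    pairs = assoc.pairwise_adjusted_ttests(
        delta, cohort["clinical_group"].reindex(delta.index), test_label="delta_vs_clinical_group"
    )
    io.write_table(
        pd.DataFrame([vars(r) for r in pairs]), _p(config, "assoc_clinical_pairwise.tsv"), meta
    )

    subset_rows = []
    scores = {}
    for path in sorted(Path(config.outdir).glob("scores_c*_*.tsv")):
        pheno = path.stem.split("_")[-1]
        scores[pheno] = io.read_table(path, index_col=0)["score"]
    carriers = cohort.index[cohort["mutation"].astype(str) != "none"]
    c9 = cohort.index[cohort["mutation"].astype(str) == "C9orf72"]
    group = cohort["clinical_group"].astype(str)
    binary = {
        "ALS": (group.isin(["MND-only", "Cog+MND"])).map({True: "MND", False: "no-MND"}),
        "FTLD": (group.isin(["Cog-only", "Cog+MND"])).map({True: "Cog", False: "no-Cog"}),
    }
    for subset_name, idx in (("carriers", carriers), ("C9orf72", c9)):
        for pheno, score in scores.items():
            if pheno not in binary:
                continue
            sub = score.index.intersection(idx)
            try:
                res = assoc.ancova_f_test(
                    score.loc[sub],
                    binary[pheno].loc[sub],
                    [c.loc[c.index.intersection(sub)] for c in
                     (cohort["age"], cohort["sex"], cohort["prior_gwas"].astype(str))],
                    test_label=f"{subset_name}_{pheno}_score_vs_impairment",
                )
                subset_rows.append(res)
            except DataError as exc:
                log.warning("subset test %s/%s skipped: %s", subset_name, pheno, exc)
    if subset_rows:
        adj = assoc.bh_adjust([r.p for r in subset_rows])
        for r, pa in zip(subset_rows, adj):
            r.p_adj = float(pa)
    io.write_table(assoc.results_frame(subset_rows), _p(config, "assoc_subsets.tsv"), meta)

    regions = list(simulate.FTLD_REGIONS + simulate.ALS_REGIONS)
    burden_results, followups = assoc.regional_burden_scan(
        delta, cohort, regions, covariates=["age", "sex", "prior_gwas"], fdr_alpha=config.fdr_alpha
    )
    io.write_table(assoc.results_frame(burden_results), _p(config, "assoc_burden.tsv"), meta)
    fu_rows = [vars(r) for region, rs in sorted(followups.items()) for r in rs]
    io.write_table(
        pd.DataFrame(
            fu_rows,
            columns=["test_label", "group_a", "group_b", "t", "df", "p", "p_adj", "n_a", "n_b"],
        ),
        _p(config, "assoc_burden_pairwise.tsv"),
        meta,
    )


def stage_enrich(config: PipelineConfig) -> None:
    pruned = io.read_table(_require(config, "pruned.tsv", "prune"))
    mapping = enrichment.read_snp_gene_mapping(_require(config, "mapping.tsv", "simulate"))
    collection = enrichment.read_gmt(_require(config, "genesets.gmt", "simulate"))
    meta = config.meta("enrich")
    for label, grp in pruned.groupby("label"):
        try:
            genes = enrichment.snp_to_gene(list(grp["snp_id"]), mapping)
            results = enrichment.overrepresentation_test(genes, collection)
        except DataError as exc:
            log.warning("enrichment for cluster %d skipped: %s", label, exc)
            continue
        io.write_table(
            enrichment.enrichment_frame(results), _p(config, f"enrich_c{label}.tsv"), meta
        )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "harmonize": stage_harmonize,
    "cluster": stage_cluster,
    "robustness": stage_robustness,
    "prune": stage_prune,
    "score": stage_score,
    "associate": stage_associate,
    "enrich": stage_enrich,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> list[str]:
    """Run the requested stages in canonical dependency order."""
    requested = set(stages or STAGES)
    unknown = requested - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages {sorted(unknown)}; valid: {list(STAGES)}")
    ordered = [s for s in STAGES if s in requested]
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    for name in ordered:
        log.info("running stage %s", name)
        _STAGE_FUNCS[name](config)
    return ordered
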