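"""GWAS summary statistics: reading, z-score transformation, harmonization, top-fraction selection.

Per-SNP association strength is expressed as an absolute z-score so that studies
with very different sample sizes can be compared on a common scale.  For studies
reporting an effect size and standard error the signed z is beta/se; for studies
reporting only a p-value, |z| = |Phi^-1(p/2)| (two-sided convention), with the
sign unavailable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ComputationError, ConfigurationError, DataError, ParseError

log = logging.getLogger(__name__)

#: roles every summary-statistics file must provide
REQUIRED_ROLES = ("variant_id", "chrom", "pos", "effect_allele", "other_allele")
#: at least one of (beta, se) jointly or p must be mapped
VALUE_ROLES = ("beta", "se", "p")


@dataclass
class StudyStats:
    """One study's per-variant association records.

    ``table`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    beta, se, p (beta/se/p may be NaN where absent).  ``signed`` is True when
    every record carries beta and se, i.e. the direction of effect is known.
    """

    study_label: str
    table: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.table["variant_id"].duplicated().any():
            dups = self.table["variant_id"][self.table["variant_id"].duplicated()]
            raise DataError(
                f"study {self.study_label!r}: duplicate variant ids, e.g. {dups.iloc[0]!r}"
            )
        se = self.table["se"]
        if ((se <= 0) & se.notna()).any():
            raise DataError(f"study {self.study_label!r}: non-positive standard errors")

    @property
    def signed(self) -> bool:
        return bool(self.table["beta"].notna().all() and self.table["se"].notna().all())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class HarmonizedZMatrix:
    """SNPs x phenotypes |z| profiles over the variants shared by all studies.

    ``absz``: DataFrame indexed by snp_id, one non-negative column per study
    label.  ``signed_z``: same-indexed DataFrame holding signed z columns for
    the studies whose direction of effect is known (possibly empty).
    """

    absz: pd.DataFrame
    signed_z: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return list(self.absz.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.absz.columns)

    @property
    def n_snps(self) -> int:
        return len(self.absz)

    def row_max(self) -> pd.Series:
        """Strongest association of each SNP to any phenotype."""
        return self.absz.max(axis=1)


def read_sumstats(path, schema: dict[str, str], study_label: str) -> StudyStats:
    """Read delimited summary statistics using a role->column-name schema.

    ``schema`` maps roles (variant_id, chrom, pos, effect_allele, other_allele,
    beta, se, p) to column names in the file.  Rows providing neither (beta, se)
    nor p are dropped and counted in ``n_rejected``.
    """
    for role in REQUIRED_ROLES:
        if role not in schema:
            raise ConfigurationError(f"schema missing required role {role!r}")
    if not ("p" in schema or ("beta" in schema and "se" in schema)):
        raise ConfigurationError("schema must map 'p' or both 'beta' and 'se'")

    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    for role, col in schema.items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"study {study_label!r}: column {col!r} (role {role!r}) not in {path}"
            )

    out = pd.DataFrame(
        {
            "variant_id": raw[schema["variant_id"]].astype(str),
            "chrom": raw[schema["chrom"]].astype(str),
            "effect_allele": raw[schema["effect_allele"]].str.upper(),
            "other_allele": raw[schema["other_allele"]].str.upper(),
        }
    )
    try:
        out["pos"] = raw[schema["pos"]].astype(int)
    except ValueError as exc:
        raise ParseError(f"study {study_label!r}: non-integer position: {exc}") from exc

    for role in VALUE_ROLES:
        if role in schema:
            col = pd.to_numeric(raw[schema[role]], errors="coerce")
            bad = col.isna() & raw[schema[role]].notna() & (raw[schema[role]].str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"study {study_label!r}: non-numeric {role!r} at data row {row}"
                )
            out[role] = col
        else:
            out[role] = np.nan

    has_beta_se = out["beta"].notna() & out["se"].notna()
    has_p = out["p"].notna()
    keep = has_beta_se | has_p
    n_rejected = int((~keep).sum())
    if n_rejected:
        log.warning(
            "study %r: rejected %d rows lacking both (beta,se) and p", study_label, n_rejected
        )
    out = out.loc[keep].reset_index(drop=True)
    return StudyStats(study_label=study_label, table=out, n_rejected=n_rejected)


def compute_abs_z(beta=None, se=None, p=None) -> tuple[float, float | None]:
    """Absolute (and, when available, signed) z for one association record.

    Returns ``(absz, signed_z)``; ``signed_z`` is None when only a p-value is
    available.  beta/se take precedence over p when both are present.
    """
    if beta is not None and se is not None and not (_isnan(beta) or _isnan(se)):
        if se == 0:
            raise ComputationError("se = 0: z undefined")
        z = beta / se
        return abs(z), z
    if p is None or _isnan(p):
        raise ComputationError("record has neither (beta, se) nor p")
    if p <= 0:
        raise ComputationError("p = 0: |z| infinite")
    if p > 1:
        raise ComputationError(f"p = {p} outside (0, 1]")
    return abs(float(ndtri(p / 2.0))), None


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def study_z_table(study: StudyStats) -> pd.DataFrame:
    """Vectorized per-study z table: columns absz, signed_z (NaN when unsigned)."""
    t = study.table
    has_beta_se = t["beta"].notna() & t["se"].notna()
    if (has_beta_se & (t["se"] == 0)).any():
        raise ComputationError(f"study {study.study_label!r}: se = 0 encountered")
    p = t["p"]
    need_p = ~has_beta_se
    if (need_p & (p <= 0)).any():
        raise ComputationError(f"study {study.study_label!r}: p = 0 encountered")
    signed = np.where(has_beta_se, t["beta"] / t["se"], np.nan)
    absz = np.where(has_beta_se, np.abs(signed), np.abs(ndtri(np.where(need_p, p, 0.5) / 2.0)))
    return pd.DataFrame(
        {"absz": absz, "signed_z": signed}, index=pd.Index(t["variant_id"], name="snp_id")
    )


def harmonize_studies(studies: list[StudyStats]) -> HarmonizedZMatrix:
    """Restrict all studies to their shared variant ids and stack |z| columns.

    Variants are matched by id alone; snp_ids come out in sorted order so the
    result is independent of study order.  Allele disagreements between studies
    are logged as warnings, not errors.
    """
    if len(studies) < 2:
        raise ConfigurationError("harmonization needs at least two studies")
    labels = [s.study_label for s in studies]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("study labels must be unique")

    shared: set[str] | None = None
    for s in studies:
        ids = set(s.table["variant_id"])
        shared = ids if shared is None else shared & ids
    assert shared is not None
    if not shared:
        raise DataError("no variants shared across all studies")
    snp_ids = sorted(shared)

    _warn_allele_mismatches(studies, snp_ids)

    absz = {}
    signed = {}
    for s in studies:
        zt = study_z_table(s).loc[snp_ids]
        absz[s.study_label] = zt["absz"]
        if s.signed:
            signed[s.study_label] = zt["signed_z"]
    absz_df = pd.DataFrame(absz, index=pd.Index(snp_ids, name="snp_id"))
    signed_df = pd.DataFrame(signed, index=pd.Index(snp_ids, name="snp_id"))
    return HarmonizedZMatrix(absz=absz_df, signed_z=signed_df)


def _warn_allele_mismatches(studies: list[StudyStats], snp_ids: list[str]) -> None:
    ref = studies[0].table.set_index("variant_id").loc[snp_ids]
    ref_pair = ref["effect_allele"] + "/" + ref["other_allele"]
    for s in studies[1:]:
        t = s.table.set_index("variant_id").loc[snp_ids]
        pair = t["effect_allele"] + "/" + t["other_allele"]
        flipped = t["other_allele"] + "/" + t["effect_allele"]
        mismatch = (pair != ref_pair) & (flipped != ref_pair)
        if mismatch.any():
            log.warning(
                "study %r: %d shared variants with alleles inconsistent with %r",
                s.study_label,
                int(mismatch.sum()),
                studies[0].study_label,
            )


def select_top_fraction(matrix: HarmonizedZMatrix, q: float = 0.01) -> HarmonizedZMatrix:
    """Keep the top ceil(q*n) SNPs ranked by row-maximum |z|.

    Boundary ties are broken by variant-id sort order so the selection is
    deterministic.
    """
    if not 0 < q < 1:
        raise ConfigurationError(f"q must be in (0, 1), got {q}")
    n = matrix.n_snps
    k = math.ceil(q * n)
    if k < 1:
        raise DataError(f"top-fraction selection is empty (n={n}, q={q})")
    order = (
        pd.DataFrame({"rowmax": matrix.row_max()})
        .reset_index()
        .sort_values(["rowmax", "snp_id"], ascending=[False, True], kind="mergesort")
    )
    keep = sorted(order["snp_id"].head(k))
    return HarmonizedZMatrix(
        absz=matrix.absz.loc[keep],
        signed_z=matrix.signed_z.loc[keep] if len(matrix.signed_z.columns) else matrix.signed_z,
    )
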