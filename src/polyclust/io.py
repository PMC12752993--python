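"""Plain-text readers and writers for pipeline artifacts.

All tabular outputs are tab-delimited text with a header, preceded by '#'
provenance comment lines (config hash, seed), so artifacts are greppable,
diffable, and byte-identical across reruns of the same configuration.

Dosage matrices travel either as TSV — first column sample_id, one column per
SNP, a ``#counted`` comment line recording the counted allele per SNP, NA for
missing — or as VCF with a per-genotype dosage field (DS), where the counted
allele is ALT.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .ld import DosageMatrix


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def provenance_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in sorted(meta.items())]


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA", lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kwargs)


def write_dosage_tsv(panel: DosageMatrix, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    snps = panel.snp_ids
    with open(path, "w") as fh:
        for line in provenance_lines(meta or {}):
            fh.write(line + "\n")
        fh.write("sample_id\t" + "\t".join(snps) + "\n")
        fh.write("#counted\t" + "\t".join(panel.counted_allele[s] for s in snps) + "\n")
        panel.dose.to_csv(fh, sep="\t", header=False, na_rep="NA", lineterminator="\n")


def read_dosage_tsv(path) -> DosageMatrix:
    counted = None
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#counted\t"):
                counted = line.rstrip("\n").split("\t")[1:]
            elif line.startswith("#"):
                continue
            elif header is None:
                header = line.rstrip("\n").split("\t")
    if header is None:
        raise DataError(f"no header found in {path}")
    if counted is None:
        raise DataError(f"no '#counted' allele line in {path}")
    snps = header[1:]
    if len(counted) != len(snps):
        raise DataError("counted-allele line does not match SNP columns")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], index_col=0)
    df.index.name = "sample_id"
    return DosageMatrix(
        dose=df.astype(float),
        counted_allele=pd.Series(counted, index=pd.Index(snps, name="snp_id")),
    )


def read_dosage_vcf(path) -> DosageMatrix:
    """VCF with a per-genotype DS (dosage) field; ALT is the counted allele.

    Falls back to counting ALT alleles in GT when DS is absent.  Multiallelic
    records are rejected (split them upstream).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ConfigurationError("reading VCF dosages requires the cyvcf2 extra") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, alleles, cols = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(f"multiallelic record at {var.CHROM}:{var.POS}; split first")
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        alleles.append(var.ALT[0])
        ds = var.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            col = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        col = np.where((col < 0) | (col > 2), np.nan, col)
        cols.append(col)
    if not snp_ids:
        raise DataError(f"no variants in {path}")
    dose = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(samples, name="sample_id"), columns=snp_ids
    )
    return DosageMatrix(
        dose=dose, counted_allele=pd.Series(alleles, index=pd.Index(snp_ids, name="snp_id"))
    )


def read_dosage(path) -> DosageMatrix:
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_dosage_vcf(path)
    return read_dosage_tsv(path)
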