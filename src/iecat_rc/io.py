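"""Readers, writers, QC and run metadata.

Two genotype formats are supported: VCF (biallelic SNVs; the dosage is the
ALT-allele count) and a delimited subjects x variants matrix whose header
row carries variant IDs and whose first column carries sample IDs.
Positions follow VCF 1-based conventions; the in-memory matrices are
position-agnostic. Missing genotypes are mean-imputed per variant after QC
so the calibration and testing layers never see missingness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeData",
    "read_genotypes",
    "write_vcf",
    "write_matrix",
    "read_phenotypes",
    "apply_basic_qc",
    "mean_impute",
    "write_results",
    "write_metadata",
]


@dataclass
class GenotypeData:
    """Dosage matrix plus variant metadata and sample IDs."""

    matrix: np.ndarray  # subjects x variants, {0,1,2, nan}
    variants: pd.DataFrame  # chrom, pos, id, ref, alt
    samples: list[str]
    n_multiallelic_skipped: int = 0


def _read_vcf(path: str) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("sample-ID collision in VCF header")
    cols, meta = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gts012: gt_types is the ALT dosage 0/1/2, with 3 = unknown
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.where(gt == 3, np.nan, gt)
        cols.append(dosage)
        meta.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    matrix = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeData(matrix, pd.DataFrame(meta), samples, skipped)


def _read_matrix(path: str) -> GenotypeData:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        raise ValueError("sample-ID collision in genotype matrix")
    ids = [str(c) for c in df.columns]
    meta = pd.DataFrame(
        {"chrom": ".", "pos": 0, "id": ids, "ref": ".", "alt": "."}
    )
    return GenotypeData(df.to_numpy(dtype=float), meta, samples, 0)


def read_genotypes(path: str, fmt: str = "auto") -> GenotypeData:
    """Read a genotype matrix from VCF or a delimited matrix file."""
    if fmt == "auto":
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "matrix"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_vcf(data: GenotypeData, path: str) -> None:
    """Write a minimal diploid GT-only VCF (uncompressed text)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(data.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom if chrom != '.' else '1'}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(data.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in data.variants.iterrows():
            calls = [
                "./." if np.isnan(g) else gt_map[float(g)] for g in data.matrix[:, j]
            ]
            chrom = row["chrom"] if row["chrom"] != "." else "1"
            pos = int(row["pos"]) if row["pos"] else j + 1
            ref = row["ref"] if row["ref"] != "." else "A"
            alt = row["alt"] if row["alt"] != "." else "C"
            fh.write(
                f"{chrom}\t{pos}\t{row['id']}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_matrix(data: GenotypeData, path: str, sep: str = "\t") -> None:
    df = pd.DataFrame(data.matrix, index=data.samples, columns=data.variants["id"])
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype/covariate table: sample_id, phenotype, then covariates."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError("phenotype table needs 'sample_id' and 'phenotype' columns")
    if not df["phenotype"].isin([0, 1]).all():
        raise ValueError("phenotype must be coded 0/1")
    return df


def mean_impute(matrix: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean."""
    matrix = np.array(matrix, dtype=float)
    means = np.nanmean(np.where(np.isnan(matrix).all(axis=0), 0.0, matrix), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(matrix))
    matrix[idx] = means[idx[1]]
    return matrix


def apply_basic_qc(
    data: GenotypeData, maf_min: float = 0.0, missing_max: float = 1.0
) -> tuple[GenotypeData, pd.DataFrame]:
    """Variant-level QC: MAF and missing-rate filters, then mean imputation.

    Returns the filtered (and imputed) data plus a report listing removed
    variants with their reason.
    """
    m = data.matrix
    n = m.shape[0]
    miss = np.isnan(m).mean(axis=0) if n else np.zeros(m.shape[1])
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(m, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)
    reasons = []
    keep = np.ones(m.shape[1], dtype=bool)
    for j in range(m.shape[1]):
        if miss[j] > missing_max:
            keep[j] = False
            reasons.append({"variant_id": data.variants["id"].iloc[j], "reason": "missingness"})
        elif maf[j] < maf_min:
            keep[j] = False
            reasons.append({"variant_id": data.variants["id"].iloc[j], "reason": "MAF"})
    filtered = GenotypeData(
        mean_impute(m[:, keep]),
        data.variants.loc[keep].reset_index(drop=True),
        data.samples,
        data.n_multiallelic_skipped,
    )
    report = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    return filtered, report


def write_results(table: pd.DataFrame, path: str) -> None:
    """Results TSV with deterministic column order and full float precision."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_metadata(config: dict, path: str) -> dict:
    """JSON run record: config, seed, library versions and a config hash."""
    import scipy

    from . import __version__

    record = {
        "config": config,
        "seed": config.get("seed"),
        "versions": {
            "iecat_rc": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config_hash": config_hash(config),
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return record
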