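"""Readers and writers for genotype/phenotype tables and test results.

Supported genotype sources: biallelic VCF (via cyvcf2), PLINK ``.raw``
additive dosage exports, and plain delimited numeric matrices with a
header of SNP ids.  Internal storage is always a pure {0,1,2} dosage
matrix with SNP identifiers (:class:`~pomskat.simdata.GenotypeMatrix`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .experiments import ExperimentResult
from .simdata import GenotypeMatrix
from .skat import TestResult

__all__ = [
    "DatasetBundle",
    "read_genotypes",
    "read_phenotype_covariates",
    "encode_levels",
    "load_dataset",
    "write_genotypes_tsv",
    "write_phenotype_covariates_tsv",
    "write_vcf",
    "write_results",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("set", "n", "M_used", "M_dropped", "T", "T_star",
                  "xi", "p", "method")
_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass(frozen=True)
class DatasetBundle:
    """Aligned genotypes, ordinal phenotype and covariates."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    covariates: np.ndarray
    subject_ids: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        n = self.genotypes.n
        if len(self.phenotype) != n or len(self.subject_ids) != n \
                or (self.covariates.size and self.covariates.shape[0] != n):
            raise ValueError("genotypes, phenotype, covariates and subject "
                             "ids must have aligned row counts")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")


def _impute_missing(dos: np.ndarray, snp_ids: list[str],
                    max_missing: float) -> tuple[np.ndarray, list[str]]:
    """Mean-impute sparse missingness; drop SNPs above the threshold."""
    dos = np.asarray(dos, dtype=float)
    miss = np.isnan(dos)
    rate = miss.mean(axis=0)
    keep = rate <= max_missing
    dropped = [s for s, k in zip(snp_ids, keep) if not k]
    if dropped:
        logger.warning("dropped %d SNP(s) above %.0f%% missingness: %s",
                       len(dropped), 100 * max_missing, ", ".join(dropped))
    dos, miss = dos[:, keep], miss[:, keep]
    n_imputed = int(miss.sum())
    if n_imputed:
        col_mean = np.nanmean(dos, axis=0)
        fill = np.clip(np.round(col_mean), 0, 2)
        dos = np.where(miss, fill[None, :], dos)
        logger.info("imputed %d missing genotype(s) to the rounded "
                    "column mean dosage", n_imputed)
    return dos.astype(np.int8), [s for s, k in zip(snp_ids, keep) if k]


def _read_vcf(path: Path, max_missing: float
              ) -> tuple[np.ndarray, list[str], list[str]]:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids = [], []
    # cyvcf2 gt_types: 0=hom ref, 1=het, 3=hom alt, 2=unknown
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic site %s:%d",
                           var.CHROM, var.POS)
            continue
        cols.append(code[np.asarray(var.gt_types)])
        ids.append(var.ID if var.ID not in (None, ".")
                   else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError(f"{path}: no biallelic sites found")
    dos, ids = _impute_missing(np.column_stack(cols), ids, max_missing)
    return dos, ids, samples


def _read_plink_raw(path: Path, max_missing: float
                    ) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=r"\s+")
    snp_cols = [c for c in df.columns if c not in _RAW_META]
    if not snp_cols:
        raise ValueError(f"{path}: no SNP columns after the PLINK metadata")
    # "rs123_A" -> "rs123": strip the counted-allele suffix
    ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    samples = [str(s) for s in df["IID"]] if "IID" in df else \
        [str(i) for i in range(len(df))]
    dos, ids = _impute_missing(df[snp_cols].to_numpy(dtype=float),
                               ids, max_missing)
    return dos, ids, samples


def _read_table(path: Path) -> pd.DataFrame:
    """Delimited table with the separator inferred from the header line."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    return pd.read_csv(path, sep=sep)


def _read_tsv(path: Path, max_missing: float
              ) -> tuple[np.ndarray, list[str], list[str]]:
    df = _read_table(path)
    id_col = next((c for c in df.columns
                   if c.lower() in ("subject_id", "iid", "sample", "id")), None)
    if id_col is not None:
        samples = [str(s) for s in df[id_col]]
        df = df.drop(columns=[id_col])
    else:
        samples = [str(i) for i in range(len(df))]
    dos, ids = _impute_missing(df.to_numpy(dtype=float),
                               list(df.columns), max_missing)
    return dos, ids, samples


def read_genotypes(path: str | Path, format: str | None = None,
                   max_missing: float = 0.05) -> GenotypeMatrix:
    """Read a dosage matrix from VCF, PLINK ``.raw`` or delimited text.

    Missing genotypes are imputed to the rounded column mean when a SNP's
    missingness is at most ``max_missing``; sparser SNPs are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".raw": "plink_raw"}.get(
            suffix, "vcf" if path.name.endswith(".vcf.gz") else "tsv")
    readers = {"vcf": _read_vcf, "plink_raw": _read_plink_raw,
               "tsv": _read_tsv}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}")
    dos, ids, samples = readers[format](path, max_missing)
    if not np.isin(dos, (0, 1, 2)).all():
        raise ValueError(f"{path}: dosages outside {{0,1,2}} after parsing")
    G = GenotypeMatrix.from_dosages(dos, ids)
    object.__setattr__(G, "_samples", tuple(samples))
    return G


def encode_levels(values: Sequence, level_order: Sequence) -> np.ndarray:
    """Map labeled ordinal categories onto consecutive codes 0..J-1."""
    lookup = {lvl: j for j, lvl in enumerate(level_order)}
    unseen = sorted({str(v) for v in values if v not in lookup})
    if unseen:
        raise ValueError(f"phenotype value(s) {unseen} not in the declared "
                         f"level order {list(level_order)}")
    return np.array([lookup[v] for v in values], dtype=np.int64)


def read_phenotype_covariates(
    path: str | Path,
    pheno_col: str,
    level_order: Sequence | None = None,
    covar_cols: Sequence[str] = (),
    id_col: str | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Read phenotype and covariates from a delimited table.

    Returns ``(y, X, subject_ids)``; rows with missing phenotype or
    covariate values are dropped (and logged).  When ``level_order`` is
    given, labels are mapped in that order; otherwise the column must
    already hold consecutive integers starting at 0.
    """
    df = _read_table(Path(path))
    needed = [pheno_col, *covar_cols] + ([id_col] if id_col else [])
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"column(s) {missing_cols} not found in {path}")
    before = len(df)
    df = df.dropna(subset=[pheno_col, *covar_cols])
    if len(df) < before:
        logger.info("dropped %d subject(s) with missing values",
                    before - len(df))
    if level_order is not None:
        y = encode_levels(df[pheno_col].tolist(), level_order)
    else:
        y = df[pheno_col].to_numpy(dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("degenerate phenotype: fewer than 2 observed levels")
    X = df[list(covar_cols)].to_numpy(dtype=float) if covar_cols \
        else np.empty((len(df), 0))
    if id_col:
        ids = tuple(str(s) for s in df[id_col])
    else:
        id_guess = next((c for c in df.columns
                         if c.lower() in ("subject_id", "iid", "id")), None)
        ids = tuple(str(s) for s in df[id_guess]) if id_guess else \
            tuple(str(i) for i in range(len(df)))
    return y, X, ids


def load_dataset(geno_path: str | Path, pheno_path: str | Path,
                 pheno_col: str, level_order: Sequence | None = None,
                 covar_cols: Sequence[str] = (),
                 geno_format: str | None = None) -> DatasetBundle:
    """Join genotype and phenotype tables on subject ids."""
    G = read_genotypes(geno_path, geno_format)
    y, X, pids = read_phenotype_covariates(pheno_path, pheno_col,
                                           level_order, covar_cols)
    gids = getattr(G, "_samples",
                   tuple(str(i) for i in range(G.n)))
    pos = {s: i for i, s in enumerate(gids)}
    unmatched = [s for s in pids if s not in pos]
    if unmatched:
        raise ValueError(f"subject(s) {unmatched[:5]} in the phenotype table "
                         "have no genotypes")
    order = [pos[s] for s in pids]
    G2 = GenotypeMatrix.from_dosages(G.dosages[order], G.snp_ids)
    return DatasetBundle(G2, y, X, tuple(pids),
                         {"genotypes": str(geno_path),
                          "phenotype": str(pheno_path)})


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path,
                        subject_ids: Sequence[str] | None = None) -> None:
    ids = subject_ids or [f"s{i + 1}" for i in range(G.n)]
    df = pd.DataFrame(G.dosages, columns=list(G.snp_ids))
    df.insert(0, "subject_id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def write_phenotype_covariates_tsv(y: np.ndarray, X: np.ndarray,
                                   path: str | Path,
                                   subject_ids: Sequence[str] | None = None,
                                   ) -> None:
    n = len(y)
    ids = subject_ids or [f"s{i + 1}" for i in range(n)]
    df = pd.DataFrame({"subject_id": list(ids), "phenotype": np.asarray(y)})
    X = np.asarray(X)
    for k in range(X.shape[1] if X.ndim == 2 else 0):
        df[f"x{k + 1}"] = X[:, k]
    df.to_csv(path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path: str | Path,
              subject_ids: Sequence[str] | None = None,
              chrom: str = "1") -> None:
    """Minimal biallelic VCF 4.2 with GT calls reconstructed from dosage."""
    ids = subject_ids or [f"s{i + 1}" for i in range(G.n)]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in ids) + "\n")
        for m, snp in enumerate(G.snp_ids):
            calls = "\t".join(gt[int(d)] for d in G.dosages[:, m])
            fh.write(f"{chrom}\t{m + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def _result_row(res: TestResult) -> dict:
    return {"set": res.set_name, "n": res.n, "M_used": res.M_used,
            "M_dropped": res.M_dropped, "T": res.statistic_T,
            "T_star": res.T_star, "xi": res.xi, "p": res.p_value,
            "method": res.method}


def write_results(results: Sequence[TestResult | ExperimentResult],
                  path: str | Path, format: str = "tsv") -> None:
    """Serialize test or experiment results with a fixed column order."""
    from . import __version__
    path = Path(path)
    if format == "tsv":
        rows = []
        for r in results:
            if isinstance(r, TestResult):
                rows.append(_result_row(r))
            else:
                rows.append({"set": f"J{r.config.J}_M{r.config.M}_"
                                    f"rho{r.config.rho}",
                             "n": r.config.n, "M_used": r.config.M,
                             "M_dropped": 0, "T": np.nan, "T_star": np.nan,
                             "xi": np.nan, "p": r.rejection_rate,
                             "method": r.method})
        pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(
            path, sep="\t", index=False)
    elif format == "json":
        payload = {"version": __version__, "results": []}
        for r in results:
            if isinstance(r, TestResult):
                row = _result_row(r)
                row["spectrum"] = {
                    "lambdas": r.spectrum.lambdas.tolist(),
                    "ET": r.spectrum.ET, "VarT": r.spectrum.VarT,
                    "M3": r.spectrum.M3, "xi": r.spectrum.xi}
            else:
                row = {"config": dataclasses.asdict(r.config),
                       "method": r.method, "reps": r.reps,
                       "alpha": r.alpha, "failures": r.failures,
                       "rejection_rate": r.rejection_rate,
                       "mc_se": r.mc_se,
                       "pvalues": np.asarray(r.pvalues).tolist()}
            payload["results"].append(row)
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown output format {format!r}")
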