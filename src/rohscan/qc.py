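"""SNP quality control.

Filters mirror standard 50K-array editing: keep autosomal SNPs with call
rate > 0.95, minor allele frequency > 0.01, and |observed - expected
heterozygosity| < 0.15.  Inequalities are strict, so boundary SNPs are
removed.  Removal reasons are assigned by the first failing filter in the
order call rate, MAF, heterozygosity deviation, autosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MAX_AUTOSOME, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    call_rate: float = 0.95
    maf: float = 0.01
    het_dev: float = 0.15


def compute_snp_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, allele frequency, MAF and heterozygosity.

    Expected heterozygosity is 2p(1-p) from the non-missing alternate-allele
    frequency p; observed heterozygosity is the fraction of heterozygous
    calls among non-missing.  A SNP with no calls gets call_rate 0 and NaN
    frequency fields (``maf_undefined`` flag set).
    """
    v = gm.values
    n = v.shape[0]
    if n == 0:
        raise ValueError("at least one animal required")
    called = v != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / n
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, v, 0).sum(axis=0)
        p = np.where(n_called > 0, alt / (2 * np.maximum(n_called, 1)), np.nan)
        maf = np.minimum(p, 1 - p)
        het_exp = 2 * p * (1 - p)
        het_obs = np.where(n_called > 0,
                           (v == 1).sum(axis=0) / np.maximum(n_called, 1),
                           np.nan)
    return pd.DataFrame({
        "snp_id": gm.snp_map.snp_id,
        "chromosome": gm.snp_map.chromosome,
        "call_rate": call_rate,
        "p_alt": p,
        "maf": maf,
        "het_obs": het_obs,
        "het_exp": het_exp,
        "maf_undefined": n_called == 0,
        "autosomal": (gm.snp_map.chromosome >= 1)
        & (gm.snp_map.chromosome <= MAX_AUTOSOME),
    })


def apply_snp_filters(stats: pd.DataFrame, gm: GenotypeMatrix,
                      thresholds: QCThresholds = QCThresholds(),
                      ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the QC filters; return the filtered matrix and a report.

    The report has one row per SNP with the statistics, a ``kept`` flag and
    the first failing reason among {call_rate, maf, het_dev, autosome} for
    removed SNPs.  Raises if every SNP is removed.
    """
    if len(stats) != gm.n_snps:
        raise ValueError("stats and genotype matrix disagree on SNP count")
    cr = stats["call_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    dev = np.abs(stats["het_obs"].to_numpy() - stats["het_exp"].to_numpy())
    auto = stats["autosomal"].to_numpy()

    pass_cr = cr > thresholds.call_rate
    pass_maf = np.nan_to_num(maf, nan=-1.0) > thresholds.maf
    pass_dev = np.nan_to_num(dev, nan=np.inf) < thresholds.het_dev
    keep = pass_cr & pass_maf & pass_dev & auto

    # first-failing order: call_rate, maf, het_dev, autosome
    reason = np.where(~pass_cr, "call_rate",
                      np.where(~pass_maf, "maf",
                               np.where(~pass_dev, "het_dev",
                                        np.where(~auto, "autosome", ""))))
    report = stats.copy()
    report["kept"] = keep
    report["reason"] = reason
    if not keep.any():
        raise ValueError("quality control removed every SNP")
    return gm.subset_snps(np.flatnonzero(keep)), report
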