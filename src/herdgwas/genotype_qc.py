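"""Variant-level quality control: biallelic, call-rate and MAF filters.

Thresholds default to the usual array-GWAS settings for a small cohort:
minor allele frequency >= 5% and per-variant call rate >= 90%, biallelic
records only. Survivors are re-oriented so dosages count the minor allele
(ties at 0.5 keep the ALT allele as minor, which makes the orientation
deterministic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


class UndefinedMAFError(ValueError):
    pass


def compute_maf(calls) -> float:
    """Minor allele frequency of a dosage vector, ignoring missing calls."""
    v = np.asarray(calls, dtype=float)
    n = np.isfinite(v).sum()
    if n == 0:
        raise UndefinedMAFError("all calls missing; MAF undefined")
    freq = np.nansum(v) / (2.0 * n)
    return float(min(freq, 1.0 - freq))


def alt_allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    """Per-variant counted-allele frequency from non-missing calls."""
    n_called = np.isfinite(geno.dosage).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.nansum(geno.dosage, axis=0) / (2.0 * n_called)


@dataclass
class QCReport:
    n_input: int
    n_multiallelic: int
    n_low_call_rate: int
    n_low_maf: int
    n_kept: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def filter_variants(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply biallelic -> call-rate -> MAF filters and orient to the minor allele.

    Filters are applied in that order, and each variant is counted against
    the first criterion it fails. All thresholds are inclusive (``>=``).
    Raises if no variant survives.
    """
    m = geno.n_variants
    alive = np.ones(m, dtype=bool)

    multi = geno.variants["alt"].astype(str).str.contains(",").to_numpy()
    n_multi = 0
    if biallelic_only:
        n_multi = int(multi.sum())
        alive &= ~multi

    call_rate = geno.call_rate()
    low_cr = alive & (call_rate < call_rate_min)
    n_low_cr = int(low_cr.sum())
    alive &= ~low_cr

    n_called = np.isfinite(geno.dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(geno.dosage, axis=0) / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    low_maf = alive & ~(maf >= maf_min)  # NaN freq (no calls) also fails
    n_low_maf = int(low_maf.sum())
    alive &= ~low_maf

    if not alive.any():
        raise ValueError("no variants survive QC; relax maf/call-rate thresholds")

    out = geno.subset_variants(alive)
    freq_kept = freq[alive]
    flip = freq_kept > 0.5  # ALT is major -> count REF (= minor) instead
    dosage = out.dosage.copy()
    if flip.any():
        dosage[:, flip] = 2.0 - dosage[:, flip]
    out.dosage = dosage
    out.counted = "minor"
    variants = out.variants.copy()
    variants["minor_allele"] = np.where(
        flip, variants["ref"].to_numpy(), variants["alt"].to_numpy()
    )
    variants["maf"] = np.minimum(freq_kept, 1.0 - freq_kept)
    out.variants = variants

    report = QCReport(
        n_input=m,
        n_multiallelic=n_multi,
        n_low_call_rate=n_low_cr,
        n_low_maf=n_low_maf,
        n_kept=int(alive.sum()),
    )
    logger.info("variant QC: %s", report.to_dict())
    return out, report
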