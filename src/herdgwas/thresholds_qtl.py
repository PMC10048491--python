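"""Effective-number-of-tests thresholds and QTL-region definition.

With millions of correlated variants, plain Bonferroni correction over the
variant count is far too strict. The pipeline instead estimates the number
of independent tests M by greedy LD pruning (sliding window of 500
variants, step 100, removing one member of every pair with r2 > 0.6) and
sets the significance thresholds to -log10(alpha / M) for alpha = 0.01,
0.05 and 0.1 (highly significant / significant / suggestive).

QTL regions are then defined in two stages from the corrected summary
statistics pooled across all traits:

1. coarse grouping — suggestive variants on a chromosome belong to one
   group while consecutive gaps stay within 2.5 Mb; groups with fewer than
   three suggestive variants are discarded;
2. region growth — within each surviving group, the region around each
   trait's top SNP is grown by repeatedly adding suggestive variants lying
   within 500 kb of the current region bounds; the core is the member
   position span and the display bounds add 100 kb of flank on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# pairwise LD
@dataclass
class LDStats:
    r2: float
    d_prime: float


def _em_haplotype_freqs(g1, g2, tol: float = 1e-8, max_iter: int = 1000):
    """Two-locus haplotype frequencies (pAB, pAb, paB, pab) by EM.

    Alleles: A/a = alt/ref at locus 1 (counted/other), B/b at locus 2.
    Genotype dosages count the A (resp. B) allele.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((g1 == i) & (g2 == j))
    pA = g1.sum() / (2 * n)
    pB = g2.sum() / (2 * n)
    # initialize at linkage equilibrium
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    for _ in range(max_iter):
        # probability the double het is AB/ab rather than Ab/aB
        denom = f[0] * f[3] + f[1] * f[2]
        w = f[0] * f[3] / denom if denom > 0 else 0.5
        nAB = (2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + w * n_dh)
        nAb = (2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + (1 - w) * n_dh)
        naB = (2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + (1 - w) * n_dh)
        nab = (2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + w * n_dh)
        new = np.array([nAB, nAb, naB, nab]) / (2 * n)
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def ld_pair(g1, g2) -> LDStats:
    """r2 (squared dosage correlation) and D' (EM haplotype frequencies)."""
    v1 = np.asarray(g1, dtype=float)
    v2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(v1) & np.isfinite(v2)
    if ok.sum() < 2:
        raise ValueError("need at least two overlapping non-missing calls")
    v1, v2 = v1[ok], v2[ok]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return LDStats(np.nan, np.nan)
    r = np.corrcoef(v1, v2)[0, 1]
    f = _em_haplotype_freqs(v1, v2)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else np.nan
    return LDStats(float(r * r), float(min(d_prime, 1.0)))


def pairwise_r2(G: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared correlation between columns of ``G``.

    Missing-aware: each pair's correlation uses only rows where both columns
    are observed, matching :func:`ld_pair` exactly.
    """
    G = np.asarray(G, dtype=float)
    M = np.isfinite(G).astype(float)
    X0 = np.where(np.isfinite(G), G, 0.0)
    N = M.T @ M
    S = X0.T @ M  # S[i,j] = sum of col i over rows shared with j
    P = X0.T @ X0
    SS = (X0 * X0).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = S / N
        mean_j = mean_i.T
        var_i = SS / N - mean_i**2
        var_j = var_i.T
        cov = P / N - mean_i * mean_j
        r2 = cov**2 / (var_i * var_j)
    return r2


# ----------------------------------------------------------------------
# LD pruning and thresholds
def prune_ld(
    geno: GenotypeMatrix,
    window: int = 500,
    step: int = 100,
    r2_max: float = 0.6,
) -> tuple[np.ndarray, int]:
    """Greedy sliding-window LD pruning; returns (kept boolean mask, M).

    Window and step are variant counts. Within each window every pair of
    still-kept variants with r2 > ``r2_max`` loses its lower-MAF member
    (tie: the later position is removed); removals persist across windows.
    Pairs are processed in ascending index order, which makes the result
    deterministic.
    """
    m = geno.n_variants
    kept = np.ones(m, dtype=bool)
    chroms = geno.variants["chrom"].to_numpy()
    n_called = np.isfinite(geno.dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(geno.dosage, axis=0) / (2.0 * n_called)
    mafs = np.minimum(freq, 1.0 - freq)

    for chrom in dict.fromkeys(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        mc = len(idx)
        for start in range(0, mc, step):
            win = idx[start : start + window]
            active = win[kept[win]]
            if len(active) < 2:
                if start + window >= mc:
                    break
                continue
            r2 = pairwise_r2(geno.dosage[:, active])
            iu, ju = np.triu_indices(len(active), k=1)
            with np.errstate(invalid="ignore"):
                hits = np.nonzero(r2[iu, ju] > r2_max)[0]
            for h in hits:
                a, b = active[iu[h]], active[ju[h]]
                if not (kept[a] and kept[b]):
                    continue
                if mafs[a] < mafs[b]:
                    kept[a] = False
                elif mafs[b] < mafs[a]:
                    kept[b] = False
                else:  # tie: drop the later position
                    kept[b] = False
            if start + window >= mc:
                break
    M = int(kept.sum())
    logger.info("LD pruning: %d of %d variants independent", M, m)
    return kept, M


@dataclass
class Threshold:
    alpha: float
    neg_log10_p: float
    rounded: float


def bonferroni_thresholds(M: int, alphas=(0.01, 0.05, 0.1)) -> dict:
    """Effective-test Bonferroni thresholds: alpha -> -log10(alpha / M)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    out = {}
    for alpha in alphas:
        if not 0 < alpha <= 1:
            raise ValueError(f"alpha {alpha} outside (0, 1]")
        exact = float(-np.log10(alpha / M))
        out[alpha] = Threshold(alpha=alpha, neg_log10_p=exact,
                               rounded=round(exact, 1))
    return out


# ----------------------------------------------------------------------
# QTL regions
@dataclass
class QTLRegion:
    chrom: str
    start: int  # core bounds, 1-based inclusive
    stop: int
    display_start: int
    display_stop: int
    members: tuple  # suggestive variant ids inside the core (pooled traits)
    top_snp: dict = field(default_factory=dict)  # trait -> (variant_id, pos, p)
    n_variants: int = 0

    @property
    def length_mb(self) -> float:
        return (self.stop - self.start) / 1e6


def define_qtl(
    assoc: pd.DataFrame,
    suggestive_neglogp: float,
    coarse_gap: int = 2_500_000,
    min_variants: int = 3,
    chain_gap: int = 500_000,
    flank: int = 100_000,
    p_column: str = "neg_log10_p",
) -> list:
    """Two-stage QTL-region definition from corrected summary statistics.

    ``assoc`` needs columns variant_id, chrom, pos, trait and ``p_column``
    (-log10 of the corrected p). Suggestive variants of all traits are
    pooled per chromosome. Returns regions sorted by (chromosome, start);
    per-trait regions with identical bounds inside one coarse group are
    merged into a single region carrying several top-SNP entries.
    """
    sugg = assoc.loc[assoc[p_column] >= suggestive_neglogp]
    if sugg.empty:
        return []
    regions: list[QTLRegion] = []
    chrom_order = list(dict.fromkeys(assoc["chrom"]))
    for chrom in chrom_order:
        sub = sugg.loc[sugg["chrom"] == chrom]
        if sub.empty:
            continue
        pooled = (
            sub.groupby("variant_id", sort=False)
            .agg(pos=("pos", "first"))
            .sort_values("pos")
        )
        pos = pooled["pos"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > coarse_gap)[0]
        group_bounds = zip(
            np.concatenate([[0], breaks + 1]),
            np.concatenate([breaks + 1, [len(pos)]]),
        )
        for lo, hi in group_bounds:
            group_pos = pos[lo:hi]
            if len(group_pos) < min_variants:
                continue
            group_ids = pooled.index.to_numpy()[lo:hi]
            in_group = sub.loc[sub["variant_id"].isin(group_ids)]
            grown: dict[tuple, QTLRegion] = {}
            for trait, tsub in in_group.groupby("trait", sort=False):
                top = tsub.sort_values(
                    [p_column, "pos"], ascending=[False, True]
                ).iloc[0]
                start = stop = int(top["pos"])
                while True:
                    inside = (group_pos >= start - chain_gap) & (
                        group_pos <= stop + chain_gap
                    )
                    new_start = int(group_pos[inside].min())
                    new_stop = int(group_pos[inside].max())
                    if (new_start, new_stop) == (start, stop):
                        break
                    start, stop = new_start, new_stop
                key = (start, stop)
                member_mask = (group_pos >= start) & (group_pos <= stop)
                if key not in grown:
                    grown[key] = QTLRegion(
                        chrom=str(chrom),
                        start=start,
                        stop=stop,
                        display_start=max(1, start - flank),
                        display_stop=stop + flank,
                        members=tuple(group_ids[member_mask]),
                        n_variants=int(member_mask.sum()),
                    )
                grown[key].top_snp[str(trait)] = (
                    str(top["variant_id"]), int(top["pos"]),
                    float(top[p_column]),
                )
            regions.extend(grown.values())
    regions.sort(key=lambda r: (chrom_order.index(r.chrom), r.start))
    logger.info("QTL definition: %d regions", len(regions))
    return regions
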