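"""Population-stratification clusters from identity-by-state sharing.

Related cows share more alleles than unrelated ones. The pipeline estimates
relatedness clusters by complete-linkage agglomeration on the pairwise
identity-by-state (IBS) distance, constrained by a pairwise population
concordance (PPC) test: two groups may never merge if any cross-pair looks
like it comes from different populations.

The PPC test compares, for one pair of individuals, the number of sites
where both are heterozygous (IBS2-het) against the number of sites where
they are opposite homozygotes (IBS0). Under panmixia these occur in a 2:1
ratio, so the observed IBS2-het count among the informative sites is tested
against a Binomial(n, 2/3) with an exact two-sided test. Strongly
discordant pairs (p below the cutoff, default 1e-5) forbid a merge.

The resulting cluster label enters the association model as the mandatory
population-stratification fixed effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class IBSMatrix:
    """Symmetric mean IBS score per pair (0..2; diagonal 2)."""

    ids: np.ndarray
    score: np.ndarray

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.score / 2.0


@dataclass
class ClusterAssignment:
    ids: np.ndarray
    labels: np.ndarray  # contiguous cluster ids starting at 1

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def _genotype_indicators(geno: GenotypeMatrix):
    d = geno.dosage
    a0 = (d == 0).astype(np.float64)
    a1 = (d == 1).astype(np.float64)
    a2 = (d == 2).astype(np.float64)
    return a0, a1, a2


def ibs_matrix(geno: GenotypeMatrix) -> IBSMatrix:
    """Pairwise mean of ``2 - |d_i - d_j|`` over variants non-missing in both."""
    if geno.n_individuals < 2:
        raise ValueError("IBS matrix needs at least two individuals")
    a0, a1, a2 = _genotype_indicators(geno)
    same = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    hom = a0 + a2
    one_off = a1 @ hom.T + hom @ a1.T
    opposite = a0 @ a2.T + a2 @ a0.T
    shared = same + one_off + opposite
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"no shared non-missing variants for pair ({geno.ids[i]}, {geno.ids[j]})"
        )
    score = (2.0 * same + one_off) / shared
    return IBSMatrix(ids=geno.ids.copy(), score=score)


@lru_cache(maxsize=100_000)
def _binom_pvalue(k: int, n: int, alternative: str) -> float:
    return float(stats.binomtest(k, n, 2.0 / 3.0, alternative=alternative).pvalue)


def ppc_test(g1, g2, alternative: str = "two-sided") -> float:
    """Exact binomial PPC p-value for one pair of dosage vectors.

    ``alternative="two-sided"`` tests any departure from the 2:1 ratio;
    ``"less"`` tests the deficit of shared heterozygotes that marks a pair
    from different populations (the form the clustering constraint uses:
    related pairs show an *excess* and must not be forbidden from merging).
    """
    v1 = np.asarray(g1, dtype=float)
    v2 = np.asarray(g2, dtype=float)
    both = np.isfinite(v1) & np.isfinite(v2)
    ibs2het = int(np.sum((v1 == 1) & (v2 == 1) & both))
    ibs0 = int(np.sum(both & (np.abs(v1 - v2) == 2)))
    n = ibs2het + ibs0
    if n == 0:
        warnings.warn("PPC test with zero informative sites; p = 1")
        return 1.0
    return _binom_pvalue(ibs2het, n, alternative)


def ppc_pvalues(
    geno: GenotypeMatrix, alternative: str = "less"
) -> np.ndarray:
    """Symmetric matrix of PPC p-values for all pairs (diagonal 1).

    Defaults to the one-sided deficiency test used by the clustering
    constraint.
    """
    a0, a1, a2 = _genotype_indicators(geno)
    ibs2het = np.rint(a1 @ a1.T).astype(int)
    ibs0 = np.rint(a0 @ a2.T + a2 @ a0.T).astype(int)
    n = geno.n_individuals
    p = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = ibs2het[i, j] + ibs0[i, j]
            if tot > 0:
                p[i, j] = p[j, i] = _binom_pvalue(ibs2het[i, j], tot, alternative)
    return p


def cluster_ppc(
    ibs: IBSMatrix, ppc_p: np.ndarray, p_cutoff: float = 1e-5
) -> ClusterAssignment:
    """Constrained complete-linkage clustering on IBS distance.

    Merges proceed in ascending complete-linkage distance; a merge is
    forbidden while any cross-group pair has a PPC p-value below
    ``p_cutoff``. Ties are broken by the lexicographically smallest member
    index pair. Clustering stops when no permissible merge remains.
    """
    n = len(ibs.ids)
    dist = ibs.distance
    forbidden = np.asarray(ppc_p) < p_cutoff
    clusters: list[list[int]] = [[i] for i in range(n)]
    # complete-linkage distance and forbidden flag between current clusters
    cd = dist.copy()
    np.fill_diagonal(cd, np.inf)
    cf = forbidden.copy()

    while len(clusters) > 1:
        allowed = ~cf
        np.fill_diagonal(allowed, False)
        if not allowed.any():
            break
        masked = np.where(allowed, cd, np.inf)
        dmin = masked.min()
        if not np.isfinite(dmin):
            break
        cand = np.argwhere(masked == dmin)
        cand = cand[cand[:, 0] < cand[:, 1]]
        # deterministic tie-break: smallest member indices
        key = [(clusters[i][0], clusters[j][0]) for i, j in cand]
        a, b = cand[int(np.lexsort((np.array(key)[:, 1], np.array(key)[:, 0]))[0])]
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
        cd[a] = np.maximum(cd[a], cd[b])
        cd[:, a] = cd[a]
        cf[a] |= cf[b]
        cf[:, a] = cf[a]
        cd = np.delete(np.delete(cd, b, axis=0), b, axis=1)
        cf = np.delete(np.delete(cf, b, axis=0), b, axis=1)
        np.fill_diagonal(cd, np.inf)

    clusters.sort(key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters, start=1):
        labels[members] = cid
    logger.info("PPC clustering: %d clusters from %d individuals", len(clusters), n)
    return ClusterAssignment(ids=ibs.ids.copy(), labels=labels)
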