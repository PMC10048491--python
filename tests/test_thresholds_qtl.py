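"""Pairwise LD, pruning, effective-test thresholds and QTL regions."""

import numpy as np
import pandas as pd
import pytest

from herdgwas import thresholds_qtl as tq
from tests.conftest import make_geno


# ----------------------------------------------------------------------
# ld_pair
def test_identical_variants_full_ld():
    g = np.tile([0.0, 1.0, 2.0, 1.0], 20)
    ld = tq.ld_pair(g, g)
    assert ld.r2 == pytest.approx(1.0)
    assert ld.d_prime == pytest.approx(1.0)


def test_independent_variants_low_r2():
    rng = np.random.default_rng(1)
    n = 10_000
    r2s = []
    for _ in range(50):
        g1 = rng.binomial(2, 0.3, size=n).astype(float)
        g2 = rng.binomial(2, 0.3, size=n).astype(float)
        r2s.append(tq.ld_pair(g1, g2).r2)
    assert np.median(r2s) < 0.001


def test_monomorphic_pair_is_na():
    g1 = np.zeros(50)
    g2 = np.tile([0.0, 1.0], 25)
    ld = tq.ld_pair(g1, g2)
    assert np.isnan(ld.r2) and np.isnan(ld.d_prime)


def test_d_prime_matches_haplotype_table_oracle():
    """All-homozygote genotypes carry their haplotypes unambiguously, so the
    EM solution equals the exact haplotype-count estimate."""
    # haplotype counts (per individual, both haplotypes identical):
    # 4x AB/AB, 1x Ab/Ab, 1x aB/aB, 4x ab/ab -> 20 haplotypes
    g1 = np.array([2.0] * 4 + [2.0] + [0.0] + [0.0] * 4)
    g2 = np.array([2.0] * 4 + [0.0] + [2.0] + [0.0] * 4)
    pAB, pA, pB = 8 / 20, 10 / 20, 10 / 20
    D = pAB - pA * pB  # 0.4 - 0.25 = 0.15
    d_prime_oracle = D / min(pA * (1 - pB), (1 - pA) * pB)  # 0.15/0.25 = 0.6
    ld = tq.ld_pair(g1, g2)
    assert ld.d_prime == pytest.approx(d_prime_oracle, abs=1e-9)
    r_oracle = np.corrcoef(g1, g2)[0, 1]
    assert ld.r2 == pytest.approx(r_oracle**2, abs=1e-12)


def test_ld_symmetry():
    rng = np.random.default_rng(3)
    g1 = rng.binomial(2, 0.4, 500).astype(float)
    g2 = np.where(rng.random(500) < 0.7, g1, rng.binomial(2, 0.4, 500))
    a, b = tq.ld_pair(g1, g2), tq.ld_pair(g2, g1)
    assert a.r2 == pytest.approx(b.r2)
    assert a.d_prime == pytest.approx(b.d_prime)


def test_pairwise_r2_matches_ld_pair_with_missing():
    rng = np.random.default_rng(4)
    G = rng.binomial(2, 0.4, size=(200, 6)).astype(float)
    G[rng.random(G.shape) < 0.1] = np.nan
    mat = tq.pairwise_r2(G)
    for i in range(6):
        for j in range(i + 1, 6):
            expected = tq.ld_pair(G[:, i], G[:, j]).r2
            assert mat[i, j] == pytest.approx(expected, abs=1e-10)


# ----------------------------------------------------------------------
# pruning
def test_independent_variants_all_kept():
    rng = np.random.default_rng(5)
    G = rng.binomial(2, 0.4, size=(300, 40)).astype(float)
    geno = make_geno(G)
    kept, M = tq.prune_ld(geno)
    assert M == 40 and kept.all()


def test_duplicated_variant_loses_one_copy():
    rng = np.random.default_rng(6)
    col = rng.binomial(2, 0.4, 200).astype(float)
    G = np.column_stack([col, rng.binomial(2, 0.4, 200), col])
    geno = make_geno(G)
    kept, M = tq.prune_ld(geno)
    assert M == 2
    assert kept[0] and not kept[2]  # tie on MAF: later position removed


def _oracle_prune(geno, window, step, r2_max):
    """Brute-force sliding-window pruning with ld_pair per pair."""
    m = geno.n_variants
    kept = np.ones(m, dtype=bool)
    mafs = []
    for j in range(m):
        col = geno.dosage[:, j]
        v = col[np.isfinite(col)]
        f = v.sum() / (2 * len(v))
        mafs.append(min(f, 1 - f))
    chroms = geno.variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            for a_i in range(len(win)):
                for b_i in range(a_i + 1, len(win)):
                    a, b = win[a_i], win[b_i]
                    if not (kept[a] and kept[b]):
                        continue
                    r2 = tq.ld_pair(geno.dosage[:, a], geno.dosage[:, b]).r2
                    if np.isnan(r2) or r2 <= r2_max:
                        continue
                    if mafs[a] < mafs[b]:
                        kept[a] = False
                    else:
                        kept[b] = False
            if start + window >= len(idx):
                break
    return kept


def test_prune_matches_exhaustive_oracle():
    """50-variant toy with planted LD blocks: kept set equals the oracle."""
    rng = np.random.default_rng(7)
    n = 300
    cols = []
    base = None
    for j in range(50):
        if j % 10 == 0:
            base = rng.binomial(2, rng.uniform(0.2, 0.5), n).astype(float)
        noisy = base.copy()
        flip = rng.random(n) < 0.15
        noisy[flip] = rng.binomial(2, 0.4, flip.sum())
        cols.append(noisy)
    G = np.column_stack(cols)
    geno = make_geno(G)
    kept, M = tq.prune_ld(geno, window=20, step=5, r2_max=0.6)
    oracle = _oracle_prune(geno, window=20, step=5, r2_max=0.6)
    np.testing.assert_array_equal(kept, oracle)
    assert M == int(oracle.sum())
    assert 0 < M < 50  # the blocks really did trigger removals


def test_prune_invariant_to_individual_order():
    rng = np.random.default_rng(8)
    G = rng.binomial(2, 0.3, size=(150, 30)).astype(float)
    G[:, 1] = G[:, 0]
    geno = make_geno(G)
    _, M1 = tq.prune_ld(geno)
    perm = rng.permutation(150)
    geno_p = make_geno(G[perm], ids=[f"ind{i}" for i in perm])
    _, M2 = tq.prune_ld(geno_p)
    assert M1 == M2


# ----------------------------------------------------------------------
# thresholds
def test_effective_test_thresholds_reported_values():
    """M = 642,791 independent variants gives 7.8 / 7.1 / 6.8 (1 decimal)."""
    thr = tq.bonferroni_thresholds(642_791)
    assert thr[0.01].rounded == 7.8
    assert thr[0.05].rounded == 7.1
    assert thr[0.1].rounded == 6.8


def test_threshold_trivial_case():
    thr = tq.bonferroni_thresholds(1, alphas=(1.0,))
    assert thr[1.0].neg_log10_p == pytest.approx(0.0)


def test_threshold_monotonicity():
    for M in (10, 1000, 642_791):
        thr = tq.bonferroni_thresholds(M)
        assert (
            thr[0.01].neg_log10_p > thr[0.05].neg_log10_p > thr[0.1].neg_log10_p
        )
    m_small = tq.bonferroni_thresholds(100)[0.05].neg_log10_p
    m_large = tq.bonferroni_thresholds(10_000)[0.05].neg_log10_p
    assert m_large > m_small


def test_threshold_invalid_inputs():
    with pytest.raises(ValueError):
        tq.bonferroni_thresholds(0)
    with pytest.raises(ValueError):
        tq.bonferroni_thresholds(10, alphas=(1.5,))


# ----------------------------------------------------------------------
# QTL regions
def _assoc(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "trait", "neg_log10_p"]
    )


def test_group_below_three_variants_discarded():
    df = _assoc(
        [
            ("a", "1", 1_000_000, "t", 7.0),
            ("b", "1", 1_001_000, "t", 7.5),
        ]
    )
    assert tq.define_qtl(df, suggestive_neglogp=6.8) == []


def test_region_growth_hand_trace():
    """Three members 400 kb apart chain into one region with 100 kb flanks."""
    df = _assoc(
        [
            ("a", "1", 1_000_000, "t", 6.9),
            ("b", "1", 1_400_000, "t", 7.5),  # top SNP
            ("c", "1", 1_800_000, "t", 7.0),
        ]
    )
    regions = tq.define_qtl(df, suggestive_neglogp=6.8)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.stop) == (1_000_000, 1_800_000)
    assert (r.display_start, r.display_stop) == (900_000, 1_900_000)
    assert r.top_snp["t"][0] == "b"
    assert r.n_variants == 3


def test_coarse_gap_splits_groups():
    rows = []
    for i, pos in enumerate((1_000_000, 1_100_000, 1_200_000)):
        rows.append((f"a{i}", "1", pos, "t", 7.0))
    for i, pos in enumerate((4_200_000, 4_300_000, 4_400_000)):
        rows.append((f"b{i}", "1", pos, "t", 7.0))
    regions = tq.define_qtl(_assoc(rows), suggestive_neglogp=6.8)
    assert len(regions) == 2  # 3.0 Mb gap > 2.5 Mb
    assert regions[0].stop < regions[1].start


def test_chain_gap_limits_growth():
    """A suggestive variant 600 kb away from the bounds is not absorbed, but
    still counts toward the coarse group."""
    df = _assoc(
        [
            ("a", "1", 1_000_000, "t", 8.0),  # top
            ("b", "1", 1_300_000, "t", 7.0),
            ("c", "1", 1_900_000, "t", 6.9),  # 600 kb beyond b
        ]
    )
    regions = tq.define_qtl(df, suggestive_neglogp=6.8)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].stop) == (1_000_000, 1_300_000)
    assert regions[0].members == ("a", "b")


def test_members_all_exceed_cutoff_and_no_empty_call():
    assert tq.define_qtl(_assoc([("a", "1", 5_000, "t", 3.0)]), 6.8) == []
    rows = [(f"v{i}", "1", 1_000_000 + i * 100_000, "t", 6.8 + 0.1 * i)
            for i in range(5)]
    regions = tq.define_qtl(_assoc(rows), suggestive_neglogp=6.8)
    df = _assoc(rows).set_index("variant_id")
    for r in regions:
        for vid in r.members:
            assert df.loc[vid, "neg_log10_p"] >= 6.8


def test_multi_trait_top_snps_share_one_region():
    rows = [
        ("a", "1", 1_000_000, "milk", 7.0),
        ("b", "1", 1_200_000, "milk", 7.9),
        ("b", "1", 1_200_000, "fat", 8.5),
        ("c", "1", 1_400_000, "fat", 7.1),
    ]
    regions = tq.define_qtl(_assoc(rows), suggestive_neglogp=6.8)
    assert len(regions) == 1
    assert set(regions[0].top_snp) == {"milk", "fat"}
    assert regions[0].top_snp["milk"][0] == "b"
    assert regions[0].top_snp["fat"][0] == "b"


def test_top_snp_tie_broken_by_position():
    rows = [
        ("a", "1", 1_000_000, "t", 7.5),
        ("b", "1", 1_100_000, "t", 7.5),
        ("c", "1", 1_200_000, "t", 7.0),
    ]
    regions = tq.define_qtl(_assoc(rows), suggestive_neglogp=6.8)
    assert regions[0].top_snp["t"][0] == "a"
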