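"""Per-variant OLS, inflation factor, genomic control, group t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdgwas import association as assoc
from herdgwas import genotype_qc, model_select, phenotypes, simdata
from herdgwas.model_select import ModelSpec
from tests.conftest import make_geno


# ----------------------------------------------------------------------
# fit_variant
def test_exact_fit_recovers_coefficient():
    g = np.tile([0.0, 1.0, 2.0], 10)
    y = 2.0 * g
    fit = assoc.fit_variant(y, np.ones((30, 1)), g)
    assert fit.beta == pytest.approx(2.0, abs=1e-12)
    assert fit.p < 1e-100


def test_eight_row_fixture_matches_normal_equations():
    """Hand-solvable fixture: (X'X)^-1 X'y oracle to 1e-10."""
    y = np.array([3.1, 4.0, 2.7, 5.5, 4.9, 3.3, 6.0, 5.1])
    covar = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
    g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 1.0, 0.0])
    X = np.column_stack([np.ones(8), covar])
    design = np.column_stack([X, g])
    beta_oracle = np.linalg.inv(design.T @ design) @ design.T @ y
    resid = y - design @ beta_oracle
    sigma2 = resid @ resid / (8 - 3)
    se_oracle = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[2, 2])
    t_oracle = beta_oracle[2] / se_oracle
    p_oracle = 2 * stats.t.sf(abs(t_oracle), 5)

    fit = assoc.fit_variant(y, X, g)
    assert fit.beta == pytest.approx(beta_oracle[2], abs=1e-10)
    assert fit.se == pytest.approx(se_oracle, abs=1e-10)
    assert fit.p == pytest.approx(p_oracle, rel=1e-9)


def test_fit_matches_statsmodels():
    """Independent cross-check against a reference OLS implementation."""
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    n = 120
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    g = rng.integers(0, 3, size=n).astype(float)
    y = 0.4 * g + X @ np.array([1.0, 0.3, -0.2]) + rng.normal(size=n)
    res = sm.OLS(y, np.column_stack([X, g])).fit()
    fit = assoc.fit_variant(y, X, g)
    assert fit.beta == pytest.approx(res.params[-1], rel=1e-10)
    assert fit.se == pytest.approx(res.bse[-1], rel=1e-10)
    assert fit.p == pytest.approx(res.pvalues[-1], rel=1e-8)


def test_monomorphic_genotype_flagged_na():
    y = np.random.default_rng(0).normal(size=20)
    fit = assoc.fit_variant(y, np.ones((20, 1)), np.ones(20))
    assert np.isnan(fit.beta) and np.isnan(fit.p)


def test_listwise_deletion():
    rng = np.random.default_rng(7)
    n = 100
    g = rng.integers(0, 3, size=n).astype(float)
    y = 0.5 * g + rng.normal(size=n)
    y_miss = y.copy()
    y_miss[:10] = np.nan
    g_miss = g.copy()
    g_miss[10:20] = np.nan
    fit = assoc.fit_variant(y_miss, np.ones((n, 1)), g_miss)
    assert fit.n == 80
    fit_ref = assoc.fit_variant(y[20:], np.ones((80, 1)), g[20:])
    assert fit.beta == pytest.approx(fit_ref.beta)


def test_null_type_one_error_calibrated():
    """Permutation null at n = 10^4: rejection rate at alpha = 0.05 within
    the binomial Monte-Carlo bound for 1000 replicates."""
    rng = np.random.default_rng(99)
    n, reps = 10_000, 1000
    y = rng.normal(size=n)
    G = rng.integers(0, 3, size=(n, reps)).astype(float)
    X = np.ones((n, 1))
    beta, se, t, p, nobs = assoc._gwas_one_trait(y, X, G)
    rate = float(np.mean(p < 0.05))
    assert 0.037 <= rate <= 0.064
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01


# ----------------------------------------------------------------------
# run_gwas
def _gwas_inputs(cfg):
    geno = simdata.simulate_genotypes(cfg)
    records, truth = simdata.simulate_phenotypes(geno, cfg)
    table, _ = phenotypes.build_phenotype_table(records, min_per_level=5)
    table["cluster"] = truth.cluster_label.loc[table.index]
    qg, _ = genotype_qc.filter_variants(geno.subset_individuals(table.index))
    return qg, table, truth


def test_planted_qtl_recovered_across_seeds():
    """Top association lands within 250 kb of the causal variant in >= 9/10
    seeds (effect 0.5 SD, MAF 0.3, n = 2000)."""
    hits = 0
    for seed in range(10):
        cfg = simdata.SimConfig(
            n_individuals=2000, n_chromosomes=1, variants_per_chromosome=2000,
            qtl=(simdata.QTLSpec("1", 50_000_000, "milk_kg", 400.0, 0.3),),
            seed=200 + seed,
        )
        qg, table, _ = _gwas_inputs(cfg)
        spec = ModelSpec(trait="milk_kg:LA1", included=("farm",))
        res = assoc.run_gwas(table, qg, {"milk_kg:LA1": spec})
        top = res.loc[res["p_raw"].idxmin()]
        if abs(top["pos"] - 50_000_000) <= 250_000:
            hits += 1
    assert hits >= 9


def test_zero_variant_input_gives_empty_table():
    geno = make_geno(np.zeros((5, 0)))
    table = pd.DataFrame({"cluster": [1] * 5}, index=[f"ind{i}" for i in range(5)])
    out = assoc.run_gwas(table, geno, {})
    assert out.empty


def test_orphan_individuals_rejected(small_sim):
    _, geno, records, truth = small_sim
    table, _ = phenotypes.build_phenotype_table(records, min_per_level=5)
    table["cluster"] = 1
    table.loc["ghost_cow"] = table.iloc[0]
    with pytest.raises(KeyError, match="ghost_cow"):
        assoc.run_gwas(table, geno, {"milk_kg:LA1": ModelSpec("milk_kg:LA1")})


# ----------------------------------------------------------------------
# inflation and genomic control
def test_lambda_of_uniform_pvalues_is_one():
    rng = np.random.default_rng(17)
    p = rng.uniform(size=100_000)
    assert assoc.inflation_factor(p) == pytest.approx(1.0, abs=0.02)


def test_lambda_definition_at_half():
    assert assoc.inflation_factor(np.full(11, 0.5)) == pytest.approx(1.0)


def test_lambda_scale_equivariance():
    rng = np.random.default_rng(18)
    chi2 = rng.chisquare(1, size=20_000)
    p1 = stats.chi2.sf(chi2, 1)
    p2 = stats.chi2.sf(2.0 * chi2, 1)
    lam1 = assoc.inflation_factor(p1)
    lam2 = assoc.inflation_factor(p2)
    assert lam2 == pytest.approx(2.0 * lam1, rel=1e-9)


def test_gc_halves_chi2_when_lambda_double_target():
    rng = np.random.default_rng(19)
    chi2 = rng.chisquare(1, size=50_000)
    # force lambda_obs to exactly 2.4 by rescaling around the median
    chi2 = chi2 * (2.4 * assoc.CHI2_MEDIAN / np.median(chi2))
    p = stats.chi2.sf(chi2, 1)
    corrected, lam = assoc.gc_correct(p, target=1.2)
    assert lam == pytest.approx(2.4, abs=1e-9)
    chi2_corr = stats.chi2.isf(corrected, 1)
    np.testing.assert_allclose(chi2_corr, chi2 / 2.0, rtol=1e-8)


def test_gc_identity_when_not_inflated():
    rng = np.random.default_rng(20)
    p = rng.uniform(size=10_000)
    corrected, lam = assoc.gc_correct(p, target=1.2)
    np.testing.assert_array_equal(corrected, p)
    assert lam < 1.2


def test_gc_reaches_target_on_inflated_null():
    rng = np.random.default_rng(21)
    chi2 = 1.5 * rng.chisquare(1, size=100_000)
    p = stats.chi2.sf(chi2, 1)
    corrected, lam = assoc.gc_correct(p, target=1.2)
    assert lam == pytest.approx(1.5, abs=0.02)
    assert assoc.inflation_factor(corrected) == pytest.approx(1.2, abs=0.01)


def test_gc_preserves_ranking_and_never_inflates():
    rng = np.random.default_rng(22)
    chi2 = 2.0 * rng.chisquare(1, size=5_000)
    p = stats.chi2.sf(chi2, 1)
    df = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, len(p) + 1),
            "variant_id": [f"v{i}" for i in range(len(p))],
            "trait": "milk_kg:LA1",
            "p_raw": p,
        }
    )
    out, reports = assoc.genomic_control(df)
    assert (out["p_gc"] >= out["p_raw"] - 1e-15).all()
    order_raw = np.argsort(out["p_raw"].to_numpy())
    order_gc = np.argsort(out["p_gc"].to_numpy())
    np.testing.assert_array_equal(order_raw, order_gc)
    assert reports[0].chrom_class == "autosome"
    # recomputed lambda equals min(lambda_obs, target)
    assert assoc.inflation_factor(out["p_gc"]) == pytest.approx(1.2, abs=1e-6)


def test_gc_corrects_autosomes_and_x_separately():
    rng = np.random.default_rng(23)
    chi2_a = 2.0 * rng.chisquare(1, size=20_000)
    chi2_x = 3.0 * rng.chisquare(1, size=20_000)
    df = pd.DataFrame(
        {
            "chrom": ["1"] * 20_000 + ["X"] * 20_000,
            "pos": list(range(1, 20_001)) * 2,
            "variant_id": [f"v{i}" for i in range(40_000)],
            "trait": "t",
            "p_raw": stats.chi2.sf(np.concatenate([chi2_a, chi2_x]), 1),
        }
    )
    out, reports = assoc.genomic_control(df)
    by_class = {r.chrom_class: r for r in reports}
    assert by_class["autosome"].lambda_obs == pytest.approx(2.0, abs=0.06)
    assert by_class["X"].lambda_obs == pytest.approx(3.0, abs=0.09)
    for cls, chroms in (("autosome", ["1"]), ("X", ["X"])):
        mask = out["chrom"].isin(chroms)
        lam = assoc.inflation_factor(out.loc[mask, "p_gc"])
        assert lam == pytest.approx(1.2, abs=1e-6)


def test_structure_confounding_inflates_lambda_and_ps_reduces_it():
    """Cluster-confounded phenotypes inflate lambda beyond 1.2 without the
    stratification covariate; including it lowers lambda in every seed."""
    lam_without, lam_with = [], []
    for seed in range(10):
        cfg = simdata.SimConfig(
            n_individuals=400, n_chromosomes=1, variants_per_chromosome=1000,
            n_subpops=4, fst=0.15, confound_sd=1.5,
            covariate_effects={}, seed=300 + seed,
        )
        geno = simdata.simulate_genotypes(cfg)
        records, truth = simdata.simulate_phenotypes(geno, cfg)
        table, _ = phenotypes.build_phenotype_table(records, min_per_level=2)
        table["cluster"] = truth.cluster_label.loc[table.index]
        qg, _ = genotype_qc.filter_variants(geno.subset_individuals(table.index))
        spec = ModelSpec(trait="milk_kg:LA1")
        no_ps = table.copy()
        no_ps["cluster"] = 1
        res0 = assoc.run_gwas(no_ps, qg, {"milk_kg:LA1": spec})
        res1 = assoc.run_gwas(table, qg, {"milk_kg:LA1": spec})
        lam_without.append(assoc.inflation_factor(res0["p_raw"]))
        lam_with.append(assoc.inflation_factor(res1["p_raw"]))
    assert np.mean(lam_without) > 1.2
    reduced = sum(w > v for w, v in zip(lam_without, lam_with))
    assert reduced >= 9


def test_null_gwas_lambda_near_one():
    """No QTL, no structure: lambda within [0.95, 1.05]."""
    cfg = simdata.SimConfig(
        n_individuals=500, n_sires=500, n_chromosomes=1,
        variants_per_chromosome=20_000,
        h2={"milk_kg": 0.0, "fat_pct": 0.0, "protein_pct": 0.0},
        covariate_effects={}, n_founder_haplotypes=100, seed=47,
    )
    geno = simdata.simulate_genotypes(cfg)
    records, _ = simdata.simulate_phenotypes(geno, cfg)
    table, _ = phenotypes.build_phenotype_table(records, min_per_level=2)
    table["cluster"] = 1
    qg, _ = genotype_qc.filter_variants(geno.subset_individuals(table.index))
    res = assoc.run_gwas(table, qg, {"milk_kg:LA1": ModelSpec("milk_kg:LA1")})
    assert assoc.inflation_factor(res["p_raw"]) == pytest.approx(1.0, abs=0.05)


# ----------------------------------------------------------------------
# genotype-group t-tests
def test_ttest_identical_groups_near_one():
    rng = np.random.default_rng(30)
    n = 3000
    g = np.tile([0.0, 1.0, 2.0], n // 3)
    y = rng.normal(size=n)  # no genotype effect at all
    out = assoc.genotype_group_ttests(y, np.ones((n, 1)), g)
    assert len(out) == 3
    assert (out["p"] > 0.001).all()


def test_ttest_additive_effect_ordering():
    """0-vs-2 separates more strongly than 0-vs-1 for an additive effect."""
    rng = np.random.default_rng(31)
    wins = 0
    for _ in range(100):
        g = np.tile([0.0, 1.0, 2.0], 40)
        y = 0.5 * g + rng.normal(size=len(g))
        out = assoc.genotype_group_ttests(y, np.ones((len(g), 1)), g).set_index(
            ["group1", "group2"]
        )
        if out.loc[(0, 2), "p"] < out.loc[(0, 1), "p"]:
            wins += 1
    assert wins > 50


def test_ttest_two_groups_only():
    rng = np.random.default_rng(32)
    g = np.tile([0.0, 2.0], 30)
    y = rng.normal(size=60)
    out = assoc.genotype_group_ttests(y, np.ones((60, 1)), g)
    assert len(out) == 1
    assert (out.loc[0, ["group1", "group2"]] == [0, 2]).all()


def test_ttest_singleton_group_na():
    rng = np.random.default_rng(33)
    g = np.array([0.0] * 20 + [1.0] * 20 + [2.0])
    y = rng.normal(size=41)
    out = assoc.genotype_group_ttests(y, np.ones((41, 1)), g).set_index(
        ["group1", "group2"]
    )
    assert np.isnan(out.loc[(0, 2), "p"])
    assert np.isfinite(out.loc[(0, 1), "p"])
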