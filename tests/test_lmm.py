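"""Mixed-model GWAS: GRM, REML, Wald scan, inflation, conditioning, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import herniaqtl as hq
from _utils import make_panel, random_panel
from herniaqtl.lmm import (
    CHI2_1DF_MEDIAN,
    KinshipMatrix,
    fit_null,
    inflation_factor,
    wald_scan,
)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_single_variant_hand_computation():
    """Dosages (0, 2) at freq 0.5: centered values (-1, +1), normalizer
    2 p (1-p) = 0.5, so K = [[2, -2], [-2, 2]]."""
    haps = np.array([[[0], [0]], [[1], [1]]], dtype=np.int8)
    gt = make_panel(haps)
    K = hq.build_grm(gt)
    assert np.allclose(K.values, [[2.0, -2.0], [-2.0, 2.0]])


def test_grm_identical_genotypes_identical_rows():
    rng = np.random.default_rng(0)
    gt = random_panel(rng, n=6, L=40)
    gt.haplotypes[3] = gt.haplotypes[0]
    K = hq.build_grm(gt)
    assert np.allclose(K.values[0], K.values[3])
    assert np.allclose(np.diag(K.values).mean(), 1.0, atol=0.35)


def test_grm_orders_relatives(small_sim):
    """Mean kinship: full sibs > half sibs > non-sibs within F2."""
    ped = small_sim.pedigree
    f2 = ped[ped["generation"] == "F2"]
    gt = small_sim.genotypes.subset_samples(f2["id"].tolist())
    K = hq.build_grm(gt).values
    parents = {r["id"]: (r["sire"], r["dam"]) for _, r in f2.iterrows()}
    ids = gt.samples
    full, half, unrel = [], [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            si, di = parents[ids[i]]
            sj, dj = parents[ids[j]]
            shared = (si == sj) + (di == dj)
            [unrel, half, full][shared].append(K[i, j])
    assert np.mean(full) > np.mean(half) > np.mean(unrel)


def test_grm_requires_polymorphism():
    haps = np.zeros((3, 2, 5), dtype=np.int8)
    with pytest.raises(ValueError, match="polymorphic"):
        hq.build_grm(make_panel(haps))


def test_kinship_matrix_validates_psd():
    with pytest.raises(ValueError, match="positive semi-definite"):
        KinshipMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        KinshipMatrix(np.array([[1.0, 0.5], [0.1, 1.0]]), ["a", "b"])


# ---------------------------------------------------------------------------
# REML null fit
# ---------------------------------------------------------------------------

def test_reml_identity_kinship_matches_sample_variance():
    """With K = I the likelihood depends on the split only through the total
    variance, which must equal the (REML) sample variance."""
    rng = np.random.default_rng(1)
    n = 200
    y = rng.normal(2.0, 3.0, n)
    K = KinshipMatrix(np.eye(n), [str(i) for i in range(n)])
    fit = fit_null(y, np.ones((n, 1)), K)
    assert fit.tau_inv * (fit.lmbda + 1.0) == pytest.approx(np.var(y, ddof=1))


def test_reml_null_heritability_shrinks_to_zero():
    """y with no genetic effect drives lambda to the boundary (PVE ~ 0)."""
    pves = []
    for s in range(10):
        rng = np.random.default_rng(s)
        A = rng.normal(size=(150, 150))
        K = KinshipMatrix(A @ A.T / 150, [str(i) for i in range(150)])
        y = rng.normal(size=150)
        pves.append(fit_null(y, np.ones((150, 1)), K).pve)
    assert np.mean(pves) < 0.1
    assert min(pves) == 0.0  # the boundary candidate is reachable


def test_reml_recovers_simulated_heritability():
    """PVE ~ 0.4 simulated on pedigree GRMs is recovered within +-0.15."""
    ests = []
    for s in range(10):
        design = hq.SimDesign(
            seed=s, n_f2=250, n_f3_ordinary=1, n_f3_designed=1, n_variants=1000
        )
        res = hq.simulate_population(design)
        f2 = res.pedigree[res.pedigree["generation"] == "F2"]["id"].tolist()
        K = hq.build_grm(res.genotypes.subset_samples(f2))
        rng = np.random.default_rng(100 + s)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(len(f2)))
        y = (
            L @ rng.normal(size=len(f2)) * np.sqrt(0.4)
            + rng.normal(size=len(f2)) * np.sqrt(0.6)
        )
        ests.append(fit_null(y, np.ones((len(f2), 1)), K).pve)
    assert abs(np.mean(ests) - 0.4) <= 0.15


def test_reml_rejects_singular_covariates():
    n = 50
    rng = np.random.default_rng(2)
    K = KinshipMatrix(np.eye(n), [str(i) for i in range(n)])
    W = np.column_stack([np.ones(n), np.ones(n)])
    with pytest.raises(ValueError, match="singular"):
        fit_null(rng.normal(size=n), W, K)


# ---------------------------------------------------------------------------
# Wald scan
# ---------------------------------------------------------------------------

def _gls_oracle(gt, y, W, K, fit):
    """Direct covariance inversion, independently of the scan's whitening."""
    V = fit.tau_inv * (fit.lmbda * K.values + np.eye(len(y)))
    Vi = np.linalg.inv(V)
    X = gt.dosages(impute_mean=True)
    out = []
    for j in range(gt.n_variants):
        Xj = np.column_stack([W, X[:, j]])
        C = np.linalg.inv(Xj.T @ Vi @ Xj)
        b = C @ Xj.T @ Vi @ y
        out.append((b[-1], np.sqrt(C[-1, -1])))
    return np.array(out)


def test_wald_equals_direct_gls_inversion():
    rng = np.random.default_rng(3)
    n, m = 30, 8
    A = rng.normal(size=(n, n))
    K = KinshipMatrix(A @ A.T / n, [str(i) for i in range(n)])
    gt = random_panel(rng, n=n, L=m)
    y = rng.normal(size=n)
    W = np.column_stack([np.ones(n), rng.normal(size=n)])
    fit = fit_null(y, W, K)
    res = wald_scan(gt, y, W, K, fit)
    oracle = _gls_oracle(gt, y, W, K, fit)
    ok = res["skip_reason"] == ""
    assert np.allclose(res.loc[ok, "beta"], oracle[ok, 0])
    assert np.allclose(res.loc[ok, "se"], oracle[ok, 1])


def test_wald_identity_kinship_equals_ols():
    """K = I and no covariates: beta and p equal ordinary linear regression."""
    rng = np.random.default_rng(4)
    n = 60
    gt = random_panel(rng, n=n, L=10)
    y = rng.normal(size=n)
    K = KinshipMatrix(np.eye(n), [str(i) for i in range(n)])
    W = np.ones((n, 1))
    fit = fit_null(y, W, K)
    res = wald_scan(gt, y, W, K, fit)
    X = gt.dosages()
    for j in range(10):
        xc = X[:, j] - X[:, j].mean()
        beta = xc @ (y - y.mean()) / (xc @ xc)
        assert res["beta"].iloc[j] == pytest.approx(beta)
        # with K = I the GLS covariance is tau^-1 (lambda + 1) I
        se = np.sqrt(fit.tau_inv * (fit.lmbda + 1.0) / (xc @ xc))
        assert res["se"].iloc[j] == pytest.approx(se)


def test_wald_skips_untestable_variants():
    rng = np.random.default_rng(5)
    n = 40
    gt = random_panel(rng, n=n, L=4)
    gt.haplotypes[:, :, 1] = 0  # monomorphic
    gt.haplotypes[:, :, 2] = -1  # all missing
    cov = gt.dosages(impute_mean=True)[:, 0]
    y = rng.normal(size=n)
    K = KinshipMatrix(np.eye(n), [str(i) for i in range(n)])
    W = np.column_stack([np.ones(n), cov])
    fit = fit_null(y, W, K)
    res = wald_scan(gt, y, W, K, fit)
    assert res["skip_reason"].iloc[0] == "collinear"  # equals covariate column
    assert res["skip_reason"].iloc[1] == "monomorphic"
    assert res["skip_reason"].iloc[2] == "all_missing"
    assert res["skip_reason"].iloc[3] == ""
    assert (res.loc[res["skip_reason"] == "", "p_wald"] > 0).all()


def test_permuted_phenotype_pvalues_uniform():
    """Wald p-values are uniform under label permutation (KS at alpha 0.01,
    5,000 independent variants, fixed seed)."""
    rng = np.random.default_rng(11)
    n, m = 200, 5000
    gt = random_panel(rng, n=n, L=m)
    y = rng.permutation((rng.random(n) < 0.3).astype(float))
    K = hq.build_grm(gt)
    W = np.ones((n, 1))
    fit = fit_null(y, W, K)
    res = wald_scan(gt, y, W, K, fit)
    ks = stats.kstest(res["p_wald"].to_numpy(), "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# inflation factor
# ---------------------------------------------------------------------------

def test_inflation_factor_reference_and_scale():
    stats_at_median = np.full(500, CHI2_1DF_MEDIAN)
    p = stats.chi2.sf(stats_at_median, 1)
    lam, _ = inflation_factor(p)
    assert lam == pytest.approx(1.0)
    lam2, _ = inflation_factor(stats.chi2.sf(2 * stats_at_median, 1))
    assert lam2 == pytest.approx(2.0)


def test_inflation_factor_uniform_null():
    u = np.random.default_rng(5).uniform(size=10_000)
    lam, qq = inflation_factor(u)
    assert 0.95 <= lam <= 1.05
    assert len(qq) == 10_000
    with pytest.raises(ValueError, match="100"):
        inflation_factor(u[:50])


# ---------------------------------------------------------------------------
# conditional scan and bootstrap
# ---------------------------------------------------------------------------

def test_conditional_skips_conditioner_and_perfect_ld():
    rng = np.random.default_rng(6)
    n = 80
    gt = random_panel(rng, n=n, L=6)
    gt.haplotypes[:, :, 3] = gt.haplotypes[:, :, 2]  # perfect LD pair
    y = gt.dosages()[:, 2] + rng.normal(0, 0.5, n)
    K = hq.build_grm(gt)
    res, still = hq.conditional_scan(gt, y, None, K, 2)
    assert res["skip_reason"].iloc[2] == "conditioning_variant"
    assert res["skip_reason"].iloc[3] == "collinear"
    with pytest.raises(ValueError, match="monomorphic"):
        mono = gt.copy()
        mono.haplotypes[:, :, 0] = 0
        hq.conditional_scan(mono, y, None, K, 0)


def test_conditioning_on_unlinked_variant_keeps_signal(enriched_run):
    """Conditioning on a variant uncorrelated with the planted locus leaves
    the primary signal intact."""
    gt = enriched_run["genotypes"]
    y = enriched_run["y"]
    gwas = enriched_run["gwas"]
    pos = gt.variants["pos"].to_numpy()
    causal_pos = enriched_run["causal_pos"]
    far = int(np.argmax(np.abs(pos - causal_pos)))  # other chromosome end
    res, still = hq.conditional_scan(gt, y, None, gwas.K_, far)
    assert not still  # the 5-Mb window around the conditioner stays clean
    near = (np.abs(res["pos"] - causal_pos) <= 2e6) & (res["skip_reason"] == "")
    assert (res.loc[near, "p_wald"] < 5e-8).any()


def test_bootstrap_forced_detection_and_strata():
    """A fully penetrant planted locus survives every stratified bootstrap
    replicate at the genome-wide threshold."""
    from dataclasses import replace

    from _utils import analysis_subset

    design = replace(
        hq.desk_design(seed=0), penetrance_carrier=1.0, penetrance_noncarrier=0.0
    )
    res = hq.simulate_population(design)
    gt, y, _ = analysis_subset(res)
    causal_pos = res.design.causal_position
    region = ("1", causal_pos - 2_000_000, causal_pos + 2_000_000)
    out = hq.bootstrap_stability(
        gt, y, None, region, B=10, rng=np.random.default_rng(0)
    )
    assert out["fraction"] == 1.0
    assert out["ci_low"] <= out["fraction"] <= out["ci_high"]
    with pytest.raises(ValueError, match="stratum"):
        hq.bootstrap_stability(
            gt, np.zeros_like(y), None, region, B=2, rng=np.random.default_rng(0)
        )


def test_bootstrap_null_rarely_significant():
    """A phenotype independent of genotype keeps the regional bootstrap
    fraction near zero at the genome-wide threshold."""
    rng = np.random.default_rng(7)
    gt = random_panel(rng, n=100, L=120)
    y = (rng.random(100) < 0.3).astype(float)
    region = ("1", 0, 200_000)
    out = hq.bootstrap_stability(
        gt, y, None, region, B=20, rng=np.random.default_rng(1)
    )
    assert out["fraction"] <= 0.1


def test_gwas_estimator_interface(enriched_run):
    scan = enriched_run["gwas"]
    assert 0.0 <= scan.pve_ <= 1.0
    assert scan.lambda_ >= 0.0
    tab = scan.to_table()
    assert list(tab.columns) == ["chr", "ps", "rs", "maf", "beta", "se", "p_wald"]
    params = scan.get_params()
    assert params["significance"] == 5e-8
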