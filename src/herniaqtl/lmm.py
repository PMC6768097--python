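"""Single-marker linear mixed model association on case/control labels.

Model: y = W a + x b + u + e with u ~ MVN(0, lambda tau^-1 K) and
e ~ MVN(0, tau^-1 I). K is a centered genomic relationship matrix, lambda the
genetic-to-residual variance ratio, and PVE = lambda / (1 + lambda) the
heritability-like proportion of variance explained. Case/control labels enter
as a quantitative 0/1 response (the GEMMA convention), with no liability
transformation.

lambda is estimated once by REML on the null (no-SNP) model and held fixed
for every per-variant generalized-least-squares Wald test — the EMMAX-style
approximation, orders of magnitude faster than per-variant re-optimization
and adequate at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from .genio import PhasedGenotypes, allele_freq

#: genome-wide significance threshold used throughout the analysis
GENOME_WIDE_P = 5e-8

#: median of the chi-square distribution with 1 df (genomic-control reference)
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix with its sample order."""

    values: np.ndarray
    ids: list

    def __post_init__(self):
        K = np.asarray(self.values, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.ids):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("kinship matrix is not positive semi-definite")
        self.values = K


def build_grm(genotypes: PhasedGenotypes, subset=None) -> KinshipMatrix:
    """Centered GRM: per polymorphic variant subtract twice the allele
    frequency from the dosage and accumulate outer products, normalized by
    the total expected variance sum_j 2 p_j (1 - p_j) (VanRaden method 1) so
    the diagonal mean sits near 1. Frequencies come from the analysis subset;
    missing dosages are mean-imputed (centered to zero)."""
    gt = genotypes if subset is None else genotypes.subset_samples(subset)
    if gt.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    freq = allele_freq(gt)["freq"].to_numpy()
    poly = ~np.isnan(freq) & (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError("no polymorphic variants")
    p = freq[poly]
    X = gt.dosages(impute_mean=True)[:, poly] - 2.0 * p
    K = X @ X.T / np.sum(2.0 * p * (1.0 - p))
    return KinshipMatrix(K, list(gt.samples))


@dataclass
class LMMFit:
    """Null-model REML fit."""

    lmbda: float  # genetic-to-residual variance ratio
    tau_inv: float  # residual variance tau^-1
    pve: float  # lambda / (1 + lambda)
    loglik: float  # REML log-likelihood at the optimum
    alpha: np.ndarray  # fixed-effect estimates for W
    # eigen machinery reused by the scan
    eigvals: np.ndarray = None
    eigvecs: np.ndarray = None


def _reml_machinery(y, W, K):
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != y.shape[0]:
        W = W.T
    n, c = W.shape
    if n < c + 2:
        raise ValueError("need n >= number of covariates + 2")
    if np.linalg.matrix_rank(W) < c:
        raise ValueError("singular covariate matrix")
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        raise ValueError("K is not PSD beyond tolerance")
    vals = np.clip(vals, 0.0, None)
    return y, W, vals, vecs


def _reml_loglik(lam, yt, Wt, vals):
    """Restricted log-likelihood with tau^-1 profiled out analytically."""
    n, c = Wt.shape
    d = lam * vals + 1.0
    sd = np.sqrt(d)
    ys = yt / sd
    Ws = Wt / sd[:, None]
    WtW = Ws.T @ Ws
    try:
        alpha = np.linalg.solve(WtW, Ws.T @ ys)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    resid = ys - Ws @ alpha
    rss = float(resid @ resid)
    if rss <= 0:
        return -np.inf, None, None
    sigma2 = rss / (n - c)
    sign, logdet_WtW = np.linalg.slogdet(WtW)
    if sign <= 0:
        return -np.inf, None, None
    ll = -0.5 * (
        (n - c) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(d))
        + logdet_WtW
    )
    return ll, alpha, sigma2


def fit_null(y, W, K: KinshipMatrix, log10_bounds=(-5.0, 5.0), tol=1e-6) -> LMMFit:
    """REML fit of the null mixed model.

    K is eigendecomposed once; tau and the fixed effects are profiled out
    analytically and the restricted likelihood is maximized over
    log10(lambda) in ``log10_bounds`` by bounded scalar search, with the
    lambda = 0 boundary evaluated explicitly.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    y, W, vals, vecs = _reml_machinery(y, W, Kv)
    yt = vecs.T @ y
    Wt = vecs.T @ W

    def neg(loglam):
        return -_reml_loglik(10.0**loglam, yt, Wt, vals)[0]

    res = optimize.minimize_scalar(
        neg, bounds=log10_bounds, method="bounded", options={"xatol": tol}
    )
    candidates = [10.0 ** float(res.x), 0.0, 10.0 ** log10_bounds[0], 10.0 ** log10_bounds[1]]
    best_lam, best_ll, best_alpha, best_s2 = None, -np.inf, None, None
    for lam in candidates:
        ll, alpha, s2 = _reml_loglik(lam, yt, Wt, vals)
        if ll > best_ll:
            best_lam, best_ll, best_alpha, best_s2 = lam, ll, alpha, s2
    return LMMFit(
        lmbda=float(best_lam),
        tau_inv=float(best_s2),
        pve=float(best_lam / (1.0 + best_lam)),
        loglik=float(best_ll),
        alpha=best_alpha,
        eigvals=vals,
        eigvecs=vecs,
    )


def wald_scan(
    genotypes: PhasedGenotypes,
    y,
    W,
    K: KinshipMatrix,
    fit: LMMFit,
    variant_index=None,
) -> pd.DataFrame:
    """Per-variant GLS Wald test with covariance tau^-1 (lambda K + I) held
    fixed from the null fit.

    Monomorphic, all-missing, and covariate-collinear variants are skipped
    with an explicit reason. Returns the association table (chrom, pos, id,
    maf, beta, se, wald, p_wald, significant, skip_reason).
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != y.shape[0]:
        W = W.T
    if genotypes.n_samples != y.shape[0]:
        raise ValueError("genotypes and phenotype dimensions differ")
    d = fit.lmbda * fit.eigvals + 1.0
    sd = np.sqrt(d)
    U = fit.eigvecs
    ys = (U.T @ y) / sd
    Ws = (U.T @ W) / sd[:, None]
    # residualize against covariates in whitened space (FWL)
    Q, _ = np.linalg.qr(Ws)
    y_r = ys - Q @ (Q.T @ ys)

    freq = allele_freq(genotypes)
    idx = np.arange(genotypes.n_variants) if variant_index is None else np.asarray(variant_index)
    X = genotypes.dosages(impute_mean=True)[:, idx]
    f = freq["freq"].to_numpy()[idx]
    maf = freq["maf"].to_numpy()[idx]
    Xs = (U.T @ X) / sd[:, None]
    X_r = Xs - Q @ (Q.T @ Xs)

    xtx = np.einsum("ij,ij->j", X_r, X_r)
    xty = X_r.T @ y_r
    raw_ss = np.einsum("ij,ij->j", Xs, Xs)

    skip = np.array([""] * len(idx), dtype=object)
    mono = np.isnan(f) | (f <= 0.0) | (f >= 1.0)
    allmiss = freq["all_missing"].to_numpy()[idx]
    skip[mono] = "monomorphic"
    skip[allmiss] = "all_missing"
    collinear = (~mono) & (xtx <= 1e-10 * np.maximum(raw_ss, 1e-300))
    skip[collinear] = "collinear"
    testable = skip == ""

    beta = np.full(len(idx), np.nan)
    se = np.full(len(idx), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[testable] = xty[testable] / xtx[testable]
        se[testable] = np.sqrt(fit.tau_inv / xtx[testable])
    wald = (beta / se) ** 2
    p = stats.chi2.sf(wald, df=1)
    p = np.where(testable, np.maximum(p, np.finfo(float).tiny), np.nan)

    out = genotypes.variants.iloc[idx][["chrom", "pos", "id"]].reset_index(drop=True)
    out["maf"] = maf
    out["beta"] = beta
    out["se"] = se
    out["wald"] = wald
    out["p_wald"] = p
    out["significant"] = (p < GENOME_WIDE_P) & testable
    out["skip_reason"] = skip
    return out


def inflation_factor(assoc_or_p, min_tests: int = 100):
    """Genomic-control inflation factor and Q-Q table.

    lambda_GC is the median observed Wald chi-square over the 1-df chi-square
    median; accepts an association table (using its Wald column where present,
    else converting p) or a bare p-value array.
    """
    if isinstance(assoc_or_p, pd.DataFrame):
        tab = assoc_or_p[assoc_or_p["skip_reason"] == ""]
        stats_obs = tab["wald"].to_numpy()
        p = tab["p_wald"].to_numpy()
    else:
        p = np.asarray(assoc_or_p, dtype=float)
        stats_obs = stats.chi2.isf(p, df=1)
    stats_obs = stats_obs[~np.isnan(stats_obs)]
    if len(stats_obs) == 0:
        raise ValueError("no tested variants")
    if len(stats_obs) < min_tests:
        raise ValueError(f"need >= {min_tests} tested variants for a stable median")
    lam_gc = float(np.median(stats_obs) / CHI2_1DF_MEDIAN)
    p = np.sort(p[~np.isnan(p)])
    expected = (np.arange(1, len(p) + 1) - 0.5) / len(p)
    qq = pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(p),
        }
    )
    return lam_gc, qq


class MixedModelGWAS(BaseEstimator):
    """EMMAX-style mixed-model case/control association scan.

    Parameters
    ----------
    significance : float, default 5e-8
        Genome-wide significance threshold.
    log10_lambda_bounds : tuple, default (-5, 5)
        Search bounds for log10 of the variance ratio.

    Attributes (after :meth:`fit`)
    ------------------------------
    lambda_, tau_inv_, pve_, loglik_, alpha_ : null-model REML fit
    K_ : KinshipMatrix used
    results_ : per-variant association table
    lambda_gc_ : genomic-control inflation factor
    """

    def __init__(self, significance: float = GENOME_WIDE_P, log10_lambda_bounds=(-5.0, 5.0)):
        self.significance = significance
        self.log10_lambda_bounds = log10_lambda_bounds

    def fit(self, genotypes: PhasedGenotypes, y, covariates=None, K: KinshipMatrix = None):
        y = np.asarray(y, dtype=float).ravel()
        W = _design_matrix(len(y), covariates)
        if K is None:
            K = build_grm(genotypes)
        self.K_ = K
        self.null_fit_ = fit_null(y, W, K, log10_bounds=self.log10_lambda_bounds)
        self.lambda_ = self.null_fit_.lmbda
        self.tau_inv_ = self.null_fit_.tau_inv
        self.pve_ = self.null_fit_.pve
        self.loglik_ = self.null_fit_.loglik
        self.alpha_ = self.null_fit_.alpha
        res = wald_scan(genotypes, y, W, K, self.null_fit_)
        res["significant"] = (res["p_wald"] < self.significance) & (res["skip_reason"] == "")
        self.results_ = res
        try:
            self.lambda_gc_, self.qq_ = inflation_factor(res)
        except ValueError:
            self.lambda_gc_, self.qq_ = np.nan, None
        self._y, self._W, self._gt = y, W, genotypes
        return self

    def to_table(self) -> pd.DataFrame:
        """Association output with the published column names."""
        r = self.results_
        return pd.DataFrame(
            {
                "chr": r["chrom"],
                "ps": r["pos"],
                "rs": r["id"],
                "maf": r["maf"],
                "beta": r["beta"],
                "se": r["se"],
                "p_wald": r["p_wald"],
            }
        )


def _design_matrix(n, covariates) -> np.ndarray:
    """Intercept plus numeric covariate columns; constant or categorical
    columns are one-hot coded against their first level."""
    cols = [np.ones(n)]
    if covariates is not None:
        C = pd.DataFrame(covariates)
        for name in C.columns:
            col = C[name]
            if col.dtype.kind in "OUSb" or str(col.dtype) == "category":
                dummies = pd.get_dummies(col, drop_first=True)
                for d in dummies.columns:
                    cols.append(dummies[d].to_numpy(dtype=float))
            else:
                arr = col.to_numpy(dtype=float)
                if np.ptp(arr) > 0:
                    cols.append(arr)
    return np.column_stack(cols)


def conditional_scan(
    genotypes: PhasedGenotypes,
    y,
    covariates,
    K: KinshipMatrix,
    condition_variant: int,
    window_bp: float = 5_000_000,
    significance: float = GENOME_WIDE_P,
):
    """Re-run the scan with the conditioning variant's dosage as a covariate.

    The conditioning variant and variants perfectly collinear with it are
    skipped. Returns ``(assoc_table, window_still_significant)`` where the
    bool reports whether any tested variant within ``window_bp`` of the
    conditioner remains below the threshold.
    """
    y = np.asarray(y, dtype=float).ravel()
    dose = genotypes.dosages(impute_mean=True)[:, condition_variant]
    if np.ptp(dose) == 0:
        raise ValueError("conditioning variant is monomorphic")
    W = _design_matrix(len(y), covariates)
    W = np.column_stack([W, dose])
    fit = fit_null(y, W, K)
    res = wald_scan(genotypes, y, W, K, fit)
    res.loc[res.index[condition_variant], "skip_reason"] = "conditioning_variant"
    res.loc[res.index[condition_variant], "significant"] = False
    cv = genotypes.variants.iloc[condition_variant]
    in_window = (
        (res["chrom"] == cv["chrom"])
        & (np.abs(res["pos"] - cv["pos"]) <= window_bp)
        & (res["skip_reason"] == "")
    )
    still = bool((res.loc[in_window, "p_wald"] < significance).any())
    return res, still


def bootstrap_stability(
    genotypes: PhasedGenotypes,
    y,
    covariates,
    region,
    B: int,
    rng: np.random.Generator,
    threshold: float = GENOME_WIDE_P,
):
    """Case/control stratified bootstrap of the scan's regional signal.

    Affected and unaffected individuals are resampled with replacement within
    their own strata; the GRM and the null fit are recomputed per replicate on
    the resampled index set (duplicated individuals enter K and y
    consistently). ``region`` is (chrom, start_bp, end_bp). Returns a dict
    with the fraction of replicates showing >= 1 significant regional variant
    and its Clopper–Pearson 95% interval.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("a phenotype stratum is empty")
    region_idx = genotypes.variant_range(*region)
    if len(region_idx) == 0:
        raise ValueError("region contains no variants")
    cov = pd.DataFrame(covariates) if covariates is not None else None
    hits = 0
    for _ in range(B):
        idx = np.concatenate(
            [
                rng.choice(cases, size=len(cases), replace=True),
                rng.choice(controls, size=len(controls), replace=True),
            ]
        )
        gt_b = genotypes.subset_samples(idx)
        # resampled duplicates need unique sample ids for the container
        gt_b.samples = [f"{s}#{k}" for k, s in enumerate(gt_b.samples)]
        y_b = y[idx]
        cov_b = cov.iloc[idx] if cov is not None else None
        W = _design_matrix(len(y_b), cov_b)
        K = build_grm(gt_b)
        fit = fit_null(y_b, W, K)
        res = wald_scan(gt_b, y_b, W, K, fit, variant_index=region_idx)
        ok = res["skip_reason"] == ""
        if bool((res.loc[ok, "p_wald"] < threshold).any()):
            hits += 1
    lo, hi = proportion_confint(hits, B, alpha=0.05, method="beta")
    return {
        "fraction": hits / B,
        "hits": hits,
        "B": B,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
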