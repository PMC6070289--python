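"""Negative-binomial statistics for translational efficiency.

Counts K_ij for feature i in library j are modeled as negative binomial with
mean mu_ij and dispersion phi_i (variance mu + phi*mu^2).  Libraries are
normalized with median-of-ratios size factors.  A parametric dispersion
trend phi(mu) = a0 + a1/mu is fitted from replicated libraries; log2(TE)
and its standard error come from a two-group NB contrast of RPF against
mRNA counts, and an SE surface interpolates standard errors for samples
without replicates.  TE-ratio hypotheses (beta, beta_u, gamma) are tested
with normal Wald statistics, and the posterior probability that a
transcribed uORF with zero RPF reads is nonetheless translated, P_m(R0),
is evaluated by double marginalization over the prior TE and the latent
mRNA abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (features x libraries input).

    factor_j = median over features of K_ij / geometric-mean_i(K_i.), using
    only features with nonzero counts in every library; factors are rescaled
    to geometric mean 1.
    """
    K = np.asarray(counts, dtype=float)
    pos = (K > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no feature has nonzero counts in every library")
    logK = np.log(K[pos])
    log_ratios = logK - logK.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()
    return np.exp(log_sf)


# ---------------------------------------------------------------------------
# Dispersion trend
# ---------------------------------------------------------------------------

@dataclass
class DispersionTrend:
    """Parametric mean–dispersion trend phi(mu) = a0 + a1/mu."""

    assay: str
    a0: float
    a1: float
    feature_means: np.ndarray | None = None
    feature_dispersions: np.ndarray | None = None

    def __call__(self, mu):
        mu = np.asarray(mu, dtype=float)
        out = self.a0 + self.a1 / np.maximum(mu, 1e-12)
        return np.maximum(out, 1e-10)


def _nb_logpmf(k, mu, phi):
    r = 1.0 / phi
    return (
        special.gammaln(k + r) - special.gammaln(k + 1) - special.gammaln(r)
        + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu))
    )


def estimate_dispersion_trend(
    replicate_counts: pd.DataFrame | np.ndarray,
    assay: str = "mrna",
    min_mean: float = 30.0,
    trim_ratio: float = 10.0,
    n_trim_passes: int = 2,
) -> DispersionTrend:
    """Fit phi(mu) = a0 + a1/mu from replicated (normalized) count columns.

    The trend parameters are estimated by joint Cox–Reid adjusted maximum
    likelihood across all well-transcribed features (normalized mean >=
    ``min_mean``): each feature's mean is its replicate average and the
    per-feature likelihood contribution carries the 0.5*log(sum of GLM
    working weights) adjustment that corrects for the plugged-in mean.
    Gross outliers — features whose moment dispersion exceeds ``trim_ratio``
    times the current trend — are excluded between passes.  With only two
    replicates, per-feature dispersion noise spans an order of magnitude, so
    the trim ratio is deliberately loose; aggressive trimming (e.g. 4x)
    removes legitimate sampling variation and biases the trend downward.
    """
    K = np.asarray(replicate_counts, dtype=float)
    if K.ndim != 2 or K.shape[1] < 2:
        raise ValueError("at least 2 replicate columns required")
    means = K.mean(axis=1)
    keep = means >= min_mean
    if keep.sum() < 10:
        raise ValueError("too few well-transcribed features for a dispersion trend")
    mu = means[keep]
    Kk = K[keep]
    n = Kk.shape[1]
    s2 = Kk.var(axis=1, ddof=1)
    phi_moment = np.maximum(s2 - mu, 0.0) / mu**2
    if not np.any(s2 > 0):
        return DispersionTrend(assay=assay, a0=0.0, a1=0.0,
                               feature_means=mu, feature_dispersions=phi_moment)

    use = np.ones(len(mu), dtype=bool)
    a0 = a1 = 0.0
    for _ in range(n_trim_passes + 1):
        mh, Kh = mu[use], Kk[use]

        def neg_adj_loglik(log_params):
            p0, p1 = np.exp(log_params)
            phi = p0 + p1 / mh
            ll = _nb_logpmf(Kh, mh[:, None], phi[:, None]).sum()
            w = n * mh / (1.0 + phi * mh)
            return -(ll - 0.5 * np.log(w).sum())

        res = optimize.minimize(
            neg_adj_loglik, np.log([0.1, 1.0]), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        a0, a1 = (float(v) for v in np.exp(res.x))
        if a0 < 1e-6:
            a0 = 0.0
        if a1 < 1e-6:
            a1 = 0.0
        trend = np.maximum(a0 + a1 / mu, 1e-10)
        new_use = phi_moment / trend <= trim_ratio
        if new_use.sum() < 10 or np.array_equal(new_use, use):
            break
        use = new_use
    return DispersionTrend(assay=assay, a0=a0, a1=a1,
                           feature_means=mu, feature_dispersions=phi_moment)


# ---------------------------------------------------------------------------
# log2(TE) and its standard error
# ---------------------------------------------------------------------------

def estimate_log2te_and_se(
    mrna_counts: np.ndarray,
    rpf_counts: np.ndarray,
    trend_mrna: DispersionTrend,
    trend_rpf: DispersionTrend,
) -> pd.DataFrame:
    """Per-feature log2(TE) and SE from replicated normalized counts.

    Implements the two-group NB GLM contrast (RPF vs mRNA, log link) in
    closed form: with fixed dispersions, the group means are the MLEs, so
    log2TE = log2(mean RPF / mean mRNA) and the SE comes from the GLM
    information, Var(log TE) = 1/sum(w_rpf) + 1/sum(w_mrna) with working
    weights w = mu / (1 + phi*mu).  Features with zero counts throughout
    either assay are skipped (NaN).
    """
    M = np.atleast_2d(np.asarray(mrna_counts, dtype=float))
    R = np.atleast_2d(np.asarray(rpf_counts, dtype=float))
    mu_m = M.mean(axis=1)
    mu_r = R.mean(axis=1)
    ok = (mu_m > 0) & (mu_r > 0)
    log2te = np.where(ok, np.log2(np.maximum(mu_r, 1e-300) / np.maximum(mu_m, 1e-300)), np.nan)
    w_m = M.shape[1] * mu_m / (1.0 + trend_mrna(mu_m) * mu_m)
    w_r = R.shape[1] * mu_r / (1.0 + trend_rpf(mu_r) * mu_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / w_r + 1.0 / w_m) / LN2
    se = np.where(ok, se, np.nan)
    return pd.DataFrame({"log2te": log2te, "se": se,
                         "mean_mrna": mu_m, "mean_rpf": mu_r})


# ---------------------------------------------------------------------------
# SE surface
# ---------------------------------------------------------------------------

@dataclass
class SESurface:
    """Smooth positive SE(log2TE, mRNA count) surface fitted from replicates.

    A Gaussian additive model on log(SE) with B-spline bases in log2TE and
    log10(count); the log scale guarantees positive predictions.  Queries
    outside the fitted domain are clamped to the boundary and flagged.
    """

    _result: object
    te_bounds: tuple[float, float]
    logcount_bounds: tuple[float, float]
    _df: int = 4

    def predict(self, log2te, mrna_count) -> tuple[np.ndarray, np.ndarray]:
        log2te = np.atleast_1d(np.asarray(log2te, dtype=float))
        logc = np.log10(np.maximum(np.atleast_1d(np.asarray(mrna_count, dtype=float)), 1e-12))
        clamped = (
            (log2te < self.te_bounds[0]) | (log2te > self.te_bounds[1])
            | (logc < self.logcount_bounds[0]) | (logc > self.logcount_bounds[1])
        )
        te_c = np.clip(log2te, *self.te_bounds)
        lc_c = np.clip(logc, *self.logcount_bounds)
        X = _spline_design(te_c, lc_c, self.te_bounds, self.logcount_bounds, self._df)
        return np.exp(X @ self._result), clamped


def _spline_design(te, logc, te_bounds, lc_bounds, df):
    from scipy.interpolate import BSpline

    def basis(x, lo, hi):
        inner = np.linspace(lo, hi, df - 1)[1:-1]
        t = np.r_[[lo] * 4, inner, [hi] * 4]
        n_basis = len(t) - 4
        cols = [BSpline.basis_element(t[i : i + 5], extrapolate=False)(np.clip(x, lo, hi))
                for i in range(n_basis)]
        B = np.nan_to_num(np.column_stack(cols))
        # open-end fix: rightmost basis value at exactly hi
        B[x >= hi, -1] = np.maximum(B[x >= hi, -1], 1.0)
        return B

    return np.column_stack([
        np.ones(len(te)), basis(te, *te_bounds)[:, 1:], basis(logc, *lc_bounds)[:, 1:]
    ])


def fit_se_surface(log2te, mrna_count, se, df: int = 4) -> SESurface:
    """Fit the SE surface from per-feature (log2TE, mRNA count, SE) triples."""
    log2te = np.asarray(log2te, dtype=float)
    count = np.asarray(mrna_count, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(log2te) & np.isfinite(se) & (se > 0) & (count > 0)
    if ok.sum() < 100:
        raise ValueError("at least 100 features required to fit the SE surface")
    te, logc, y = log2te[ok], np.log10(count[ok]), np.log(se[ok])
    te_bounds = (float(te.min()), float(te.max()))
    lc_bounds = (float(logc.min()), float(logc.max()))
    if te_bounds[0] == te_bounds[1] or lc_bounds[0] == lc_bounds[1]:
        raise ValueError("degenerate fitting domain")
    X = _spline_design(te, logc, te_bounds, lc_bounds, df)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SESurface(coef, te_bounds, lc_bounds, df)


# ---------------------------------------------------------------------------
# Wald tests on TE ratios
# ---------------------------------------------------------------------------

def _check_se(*ses) -> None:
    for se in ses:
        se = np.asarray(se, dtype=float)
        if np.any(se[np.isfinite(se)] <= 0):
            raise ValueError("standard errors must be positive")


def _wald_frame(log2_ratio, se, label) -> pd.DataFrame:
    log2_ratio = np.atleast_1d(np.asarray(log2_ratio, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    _check_se(se)
    z = log2_ratio / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({f"log2_{label}": log2_ratio, "se": se, "z": z, "p": p})
    ok = np.isfinite(p)
    q = np.full(len(p), np.nan)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    out["q"] = q
    return out


def wald_test_beta(log2te_uorf, log2te_cds, se_uorf, se_cds) -> pd.DataFrame:
    """Wald test of beta = TE_uORF / TE_CDS within a sample.

    log2(beta) = log2TE_uORF - log2TE_CDS with SE the root sum of squares of
    the two component SEs; two-sided normal P values, BH-adjusted.
    """
    _check_se(se_uorf, se_cds)
    log2b = np.asarray(log2te_uorf, dtype=float) - np.asarray(log2te_cds, dtype=float)
    se = np.sqrt(np.asarray(se_uorf, dtype=float) ** 2 + np.asarray(se_cds, dtype=float) ** 2)
    return _wald_frame(log2b, se, "beta")


def wald_test_beta_u(log2te_uorf1, log2te_uorf2, se1, se2) -> pd.DataFrame:
    """Wald test of beta_u = TE_uORF,2 / TE_uORF,1 between two samples."""
    _check_se(se1, se2)
    log2bu = np.asarray(log2te_uorf2, dtype=float) - np.asarray(log2te_uorf1, dtype=float)
    se = np.sqrt(np.asarray(se1, dtype=float) ** 2 + np.asarray(se2, dtype=float) ** 2)
    return _wald_frame(log2bu, se, "beta_u")


def wald_test_gamma(
    log2te_uorf1, log2te_cds1, log2te_uorf2, log2te_cds2,
    se_uorf1, se_cds1, se_uorf2, se_cds2,
) -> pd.DataFrame:
    """Wald test of gamma = (TE_CDS,2/TE_CDS,1) / (TE_uORF,2/TE_uORF,1).

    log2(gamma) = (log2TE_CDS,2 - log2TE_CDS,1) - (log2TE_uORF,2 -
    log2TE_uORF,1); the SE is the root sum of squares of all four component
    SEs.
    """
    _check_se(se_uorf1, se_cds1, se_uorf2, se_cds2)
    log2g = (
        np.asarray(log2te_cds2, dtype=float) - np.asarray(log2te_cds1, dtype=float)
        - (np.asarray(log2te_uorf2, dtype=float) - np.asarray(log2te_uorf1, dtype=float))
    )
    se = np.sqrt(
        np.asarray(se_uorf1, dtype=float) ** 2 + np.asarray(se_cds1, dtype=float) ** 2
        + np.asarray(se_uorf2, dtype=float) ** 2 + np.asarray(se_cds2, dtype=float) ** 2
    )
    return _wald_frame(log2g, se, "gamma")


# ---------------------------------------------------------------------------
# Zero-RPF posterior
# ---------------------------------------------------------------------------

def _nb_zero_mass(mean: np.ndarray, trend_rpf: DispersionTrend) -> np.ndarray:
    """P(NB = 0) = (1 + phi*m)^(-1/phi) with phi from the RPF trend; the
    m -> 0 limit is 1 (phi(m) = a0 + a1/m diverges but phi*m -> a1)."""
    m = np.asarray(mean, dtype=float)
    out = np.ones_like(m)
    pos = m > 0
    phi = trend_rpf(m[pos])
    out[pos] = np.exp(-np.log1p(phi * m[pos]) / phi)
    return out


@dataclass
class ZeroRPFNull:
    """Null TE specification for the zero-RPF test.

    kind 'c' — TE equals the downstream CDS's (normal prior on log2 TE with
    variance 2*SE^2); 'u' — TE equals the uORF's average TE in other
    well-expressed samples (same prior form); 'point' — a fixed TE value
    (prior collapses to a point mass, default 0.1).
    """

    kind: str
    log2_te: float | None = None
    se: float | None = None
    value: float | None = None

    @staticmethod
    def from_cds(log2_te_cds: float, se: float) -> "ZeroRPFNull":
        return ZeroRPFNull("c", log2_te=log2_te_cds, se=se)

    @staticmethod
    def from_other_samples(tes: Sequence[float], se: float, mean: str = "arithmetic"
                           ) -> "ZeroRPFNull":
        tes = np.asarray(tes, dtype=float)
        if len(tes) < 2:
            raise ValueError("H0(u) needs TEs from at least 2 other samples")
        u = float(tes.mean()) if mean == "arithmetic" else float(stats.gmean(tes))
        return ZeroRPFNull("u", log2_te=np.log2(u), se=se)

    @staticmethod
    def point(value: float = 0.1) -> "ZeroRPFNull":
        return ZeroRPFNull("point", value=value)


def prob_zero_rpf(
    k_obs_mrna: float,
    null: ZeroRPFNull,
    trend_mrna: DispersionTrend,
    trend_rpf: DispersionTrend,
    n_grid: int = 2001,
    prior_sds: float = 6.0,
) -> float:
    """Posterior probability P_m(R0) of zero RPF reads on a transcribed uORF.

    P = integral over the prior of TE (x) of
    sum_K fNB(K; mu=K_obs, phi_M(mu)) * fNB(0; x*K, phi_R(x*K)),
    the outer integral on a trapezoidal grid over log2(x) spanning
    ``prior_sds`` prior standard deviations (the prior variance is 2*SE^2);
    the inner sum runs to the 1 - 1e-6 NB quantile.  A point-mass null
    collapses the integral.
    """
    mu = float(k_obs_mrna)
    if mu <= 0:
        raise ValueError("k_obs_mrna must be positive")
    phi_m = float(trend_mrna(mu))
    r = 1.0 / phi_m
    p_nb = r / (r + mu)
    k_max = int(stats.nbinom.ppf(1.0 - 1e-6, r, p_nb))
    K = np.arange(0, k_max + 1)
    w_K = stats.nbinom.pmf(K, r, p_nb)
    w_K /= w_K.sum()

    if null.kind == "point":
        x0 = float(null.value)
        if x0 < 0:
            raise ValueError("null TE must be >= 0")
        if x0 == 0.0:
            return 1.0
        return float(np.sum(w_K * _nb_zero_mass(x0 * K, trend_rpf)))

    if null.se is None or null.se <= 0:
        raise ValueError("a non-point null needs a positive prior SE")
    prior_sd = np.sqrt(2.0) * null.se
    grid = np.linspace(null.log2_te - prior_sds * prior_sd,
                       null.log2_te + prior_sds * prior_sd, n_grid)
    dens = stats.norm.pdf(grid, loc=null.log2_te, scale=prior_sd)
    w_x = dens / np.trapezoid(dens, grid)
    x = 2.0 ** grid
    zero_mass = _nb_zero_mass(np.outer(x, K), trend_rpf)  # (n_grid, k_max+1)
    inner = zero_mass @ w_K
    return float(np.clip(np.trapezoid(w_x * inner, grid), 0.0, 1.0))


def pooled_zero_rpf(
    k_obs_list: Sequence[float],
    null: ZeroRPFNull,
    trend_mrna: DispersionTrend,
    trend_rpf: DispersionTrend,
    **kwargs,
) -> float:
    """Zero-RPF posterior after pooling normalized mRNA counts across samples.

    With fewer than 2 samples this falls back to the single-sample test.
    """
    k_obs = [float(k) for k in k_obs_list]
    if not k_obs:
        raise ValueError("at least one sample required")
    return prob_zero_rpf(sum(k_obs), null, trend_mrna, trend_rpf, **kwargs)


# ---------------------------------------------------------------------------
# P-value combination, FDR, concordance
# ---------------------------------------------------------------------------

def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2*sum(ln p) ~ chi2 with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zero values first")
    X = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(X, 2 * len(p)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def concordance_chi2(n_inverse: int, n_concordant: int) -> tuple[float, float]:
    """One-df goodness-of-fit of inverse vs concordant TE changes against a
    50:50 expectation, no continuity correction.

    ``n_inverse`` counts uORF/CDS pairs whose TE changes went in opposite
    directions (beta_u > 1 with gamma < 1, or beta_u < 1 with gamma > 1);
    ``n_concordant`` counts same-direction pairs.  Returns (chi2, P).
    """
    n1, n2 = float(n_inverse), float(n_concordant)
    if n1 + n2 < 1:
        raise ValueError("at least one observation required")
    nbar = (n1 + n2) / 2.0
    chi2 = (n1 - nbar) ** 2 / nbar + (n2 - nbar) ** 2 / nbar
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Count-based TE
# ---------------------------------------------------------------------------

def count_based_te(norm_rpf: float, norm_mrna: float) -> float:
    """TE from normalized counts (normalized RPF / normalized mRNA); used
    alongside the RPKM-based TE, which differs slightly because it corrects
    for feature length.  Comparisons should agree in sign between the two
    before a difference is called significant."""
    if norm_mrna <= 0:
        raise ValueError("TE undefined for zero normalized mRNA count")
    return norm_rpf / norm_mrna
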