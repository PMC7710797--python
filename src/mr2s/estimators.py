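"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume :class:`~mr2s.summary_io.HarmonizedInstruments`
holding per-SNP exposure effects γ_j (SE σ_Xj) and outcome effects Γ_j
(SE σ_Yj) on a common allele frame, and return an :class:`MREstimate`
with the causal slope β, its SE, the odds-ratio transform exp(β) with a
95% CI, and a two-sided p-value.

Methods
-------
ivw
    Inverse-variance-weighted meta-analysis of per-SNP Wald ratios
    Γ_j/γ_j; consistent when every instrument is valid.
mr_egger
    Weighted regression of Γ_j on γ_j with a free intercept; the slope is
    consistent under directional pleiotropy provided instrument strength
    is independent of direct effects, and the intercept estimates the
    average direct (pleiotropic) effect.
weighted_median
    Median of the Wald ratios weighted by inverse variance; consistent
    when at least half the total weight comes from valid instruments.
max_likelihood
    Joint normal likelihood for (γ_j, Γ_j = β·γ_j) honouring exposure-side
    measurement error.
mr_raps
    Profile-score estimating equation with optional additive
    overdispersion; robust to many weak instruments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._exceptions import DataError, EstimationError
from .summary_io import HarmonizedInstruments

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratios β_j = Γ_j/γ_j with first-order SEs σ_Yj/|γ_j|."""

    snp_id: np.ndarray
    beta: np.ndarray
    se: np.ndarray

    @property
    def w(self) -> np.ndarray:
        """Inverse-variance weights 1/se²."""
        return 1.0 / self.se**2


@dataclass
class MREstimate:
    """One estimator's causal effect on the log-odds (slope) scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "n_snps": self.n_snps, "beta": self.beta,
            "se": self.se, "or": self.or_, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pvalue": self.pvalue, **self.extra,
        }


@dataclass
class PleiotropyResult:
    """Egger intercept test for average directional pleiotropy."""

    intercept: float
    se: float
    pvalue: float


def _require(h: HarmonizedInstruments, k_min: int, method: str) -> None:
    if h.k < k_min:
        raise DataError(f"{method} needs at least {k_min} instruments, got {h.k}; "
                        "use the per-SNP Wald ratios instead")


def _norm_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(h: HarmonizedInstruments) -> RatioEstimate:
    """Per-SNP causal estimates Γ_j/γ_j; SNPs with γ_j = 0 are excluded."""
    keep = h.gamma != 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} SNP(s) with zero exposure effect excluded "
                      "from Wald ratios")
    if not keep.any():
        raise DataError("no SNP with non-zero exposure effect")
    return RatioEstimate(
        snp_id=h.snp_id[keep],
        beta=h.Gamma[keep] / h.gamma[keep],
        se=h.sigma_y[keep] / np.abs(h.gamma[keep]),
    )


def ivw(h: HarmonizedInstruments, re_mode: str = "multiplicative") -> MREstimate:
    """Inverse-variance-weighted combination of Wald ratios.

    β = Σ w_j β_j / Σ w_j with w_j = γ_j²/σ_Yj².  With
    ``re_mode="multiplicative"`` (default) the fixed-effect SE (Σ w_j)^-1/2
    is inflated by max(1, sqrt(Q/(k−1))) so between-SNP heterogeneity
    widens, but never narrows, the interval; ``re_mode="fixed"`` skips the
    inflation.
    """
    _require(h, 2, "ivw")
    r = wald_ratio(h)
    k = len(r.beta)
    if k < 2:
        raise DataError("ivw needs at least 2 usable instruments")
    w = r.w
    beta = float(np.sum(w * r.beta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r.beta - beta) ** 2))
    scale = 1.0
    if re_mode == "multiplicative":
        scale = max(1.0, math.sqrt(q / (k - 1)))
    se *= scale
    return MREstimate("ivw", beta, se, _norm_p(beta, se), k,
                      extra={"Q": q, "se_scale": scale, "re_mode": re_mode})


def _egger_wls(gx, gy, w, fit_intercept: bool = True):
    """Weighted least squares with the residual SE floored at 1.

    Returns (params, ses, df_resid) where ses are the classical WLS SEs with
    the residual standard deviation replaced by max(1, sigma): parameter
    uncertainty is never scaled down for an apparently underdispersed fit.
    """
    X = np.column_stack([np.ones_like(gx), gx]) if fit_intercept else gx[:, None]
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = gy * sw
    coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    dof = len(gx) - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    try:
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "Egger design is singular (exposure effects carry no spread)") from exc
    ses = np.sqrt(np.diag(xtx_inv) * max(1.0, sigma2))
    return coef, ses, dof


def mr_egger(h: HarmonizedInstruments,
             _fit_intercept: bool = True) -> tuple[MREstimate, PleiotropyResult]:
    """Egger regression: WLS of Γ_j on γ_j with weights 1/σ_Yj².

    SNPs are first re-oriented so every γ_j > 0 (the fit is not invariant
    to per-SNP sign flips otherwise).  The slope estimates the causal
    effect; the intercept estimates average directional pleiotropy.
    P-values use the t distribution with k − 2 df.  ``_fit_intercept=False``
    is a test hook: the through-origin fit must reproduce the IVW slope.
    """
    _require(h, 3, "mr_egger")
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    gx = h.gamma * sign
    gy = h.Gamma * sign
    w = 1.0 / h.sigma_y**2
    coef, ses, dof = _egger_wls(gx, gy, w, fit_intercept=_fit_intercept)
    if not _fit_intercept:
        beta, se = float(coef[0]), float(ses[0])
        p = float(2.0 * stats.t.sf(abs(beta) / se, df=len(gx) - 1))
        return (MREstimate("egger_through_origin", beta, se, p, h.k),
                PleiotropyResult(0.0, float("nan"), float("nan")))
    b0, beta = float(coef[0]), float(coef[1])
    se0, se = float(ses[0]), float(ses[1])
    p = float(2.0 * stats.t.sf(abs(beta) / se, df=dof))
    p0 = float(2.0 * stats.t.sf(abs(b0) / se0, df=dof))
    est = MREstimate("egger", beta, se, p, h.k, extra={"intercept": b0})
    return est, PleiotropyResult(b0, se0, p0)


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by interpolation of the cumulative weight.

    With ordered ratios r_(1..k) and standardized cumulative weights
    p_j = (S_j − w_j/2)/S_k, the estimate interpolates r at p = 0.5.
    """
    R = np.atleast_2d(ratios)
    W = np.atleast_2d(weights)
    order = np.argsort(R, axis=1)
    r = np.take_along_axis(R, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    S = np.cumsum(w, axis=1)
    p = (S - w / 2.0) / S[:, -1:]
    n, k = r.shape
    idx = (p < 0.5).sum(axis=1)  # first position with p >= 0.5
    out = np.empty(n)
    lo = idx == 0
    hi = idx == k
    out[lo] = r[lo, 0]
    out[hi] = r[hi, -1]
    mid = ~(lo | hi)
    if mid.any():
        i = idx[mid]
        rows = np.nonzero(mid)[0]
        p1, p2 = p[rows, i - 1], p[rows, i]
        r1, r2 = r[rows, i - 1], r[rows, i]
        out[mid] = r1 + (0.5 - p1) / (p2 - p1) * (r2 - r1)
    return out


def weighted_median(h: HarmonizedInstruments, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Inverse-variance weighted median of the Wald ratios.

    The point estimate interpolates the ordered ratios at cumulative weight
    one half; the SE is the standard deviation of the estimator over
    ``n_boot`` parametric-bootstrap resamples of (γ̂_j, Γ̂_j) from normal
    distributions centred at the observed values.
    """
    _require(h, 3, "weighted_median")
    r = wald_ratio(h)
    est = float(_weighted_median_rows(r.beta, r.w)[0])
    rng = np.random.default_rng(seed)
    g = rng.normal(h.gamma, h.sigma_x, size=(n_boot, h.k))
    G = rng.normal(h.Gamma, h.sigma_y, size=(n_boot, h.k))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = G / g
        weights = g**2 / h.sigma_y**2
    boots = _weighted_median_rows(ratios, weights)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", est, se, _norm_p(est, se), h.k,
                      extra={"n_boot": n_boot})


def _ml_profile_neg2ll(beta: float, h: HarmonizedInstruments) -> float:
    # γ_j profiled out analytically: residual Γ̂ − βγ̂ has variance σ_Y² + β²σ_X²
    v = h.sigma_y**2 + beta**2 * h.sigma_x**2
    return float(np.sum((h.Gamma - beta * h.gamma) ** 2 / v))


def max_likelihood(h: HarmonizedInstruments) -> MREstimate:
    """Maximum-likelihood slope under γ̂_j ~ N(γ_j, σ_Xj²), Γ̂_j ~ N(βγ_j, σ_Yj²).

    The nuisance exposure effects γ_j are profiled out in closed form,
    leaving a one-dimensional optimization in β initialized at the IVW
    estimate.  The SE comes from the curvature of the profile
    log-likelihood at the optimum (observed information).
    """
    _require(h, 2, "max_likelihood")
    b0 = ivw(h, re_mode="fixed").beta
    span = 10.0 * max(abs(b0), 0.1) + 1.0
    res = optimize.minimize_scalar(_ml_profile_neg2ll, args=(h,),
                                   bounds=(b0 - span, b0 + span), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise EstimationError("maximum-likelihood optimization failed", res)
    beta = float(res.x)
    eps = 1e-5 * (abs(beta) + 1.0)
    d2 = (_ml_profile_neg2ll(beta + eps, h) - 2 * res.fun
          + _ml_profile_neg2ll(beta - eps, h)) / eps**2
    if d2 <= 0:
        raise EstimationError("non-positive curvature at the ML optimum", beta, d2)
    se = math.sqrt(2.0 / d2)
    return MREstimate("max_likelihood", beta, se, _norm_p(beta, se), h.k)


def _raps_score(beta: float, h: HarmonizedInstruments, tau2: float = 0.0) -> float:
    """Profile score: derivative of the profile log-likelihood in β.

    ψ(β) = Σ_j r_j (γ̂_j(σ_Yj² + τ²) + β σ_Xj² Γ̂_j) / v_j² with
    r_j = Γ̂_j − βγ̂_j and v_j = σ_Yj² + β²σ_Xj² + τ².  Unlike the naive
    weighted score Σ γ̂_j r_j / v_j, this has mean zero at the true β even
    when the exposure effects are measured with error, which is the point
    of the estimator.
    """
    v = h.sigma_y**2 + beta**2 * h.sigma_x**2 + tau2
    r = h.Gamma - beta * h.gamma
    num = h.gamma * (h.sigma_y**2 + tau2) + beta * h.sigma_x**2 * h.Gamma
    return float(np.sum(r * num / v**2))


def _solve_score(h: HarmonizedInstruments, tau2: float, b0: float) -> float:
    span = max(abs(b0), 0.1)
    for _ in range(40):
        lo, hi = b0 - span, b0 + span
        if _raps_score(lo, h, tau2) * _raps_score(hi, h, tau2) < 0:
            return float(optimize.brentq(_raps_score, lo, hi, args=(h, tau2),
                                         xtol=1e-12))
        span *= 2.0
    raise EstimationError("profile-score equation has no root in expanded bracket",
                          b0, span)


def mr_raps(h: HarmonizedInstruments, overdispersion: bool = False) -> MREstimate:
    """Profile-score estimator accounting for exposure-side measurement error.

    Solves the profile-score equation (see :func:`_raps_score`) for β, with
    τ² = 0 (simple score) or jointly estimated additive overdispersion
    τ² ≥ 0 capturing systematic pleiotropy.  The SE is the sandwich
    (robust score) variance.  The Huber/Tukey-loss robust variants are not
    implemented.
    """
    _require(h, 3, "mr_raps")
    b0 = ivw(h, re_mode="fixed").beta
    tau2 = 0.0
    beta = _solve_score(h, tau2, b0)
    if overdispersion:
        def tau_eq(t2, b):
            v = h.sigma_y**2 + b**2 * h.sigma_x**2 + t2
            return float(np.sum(((h.Gamma - b * h.gamma) ** 2 - v) / v**2))

        for _ in range(100):
            if tau_eq(0.0, beta) <= 0:
                new_tau2 = 0.0
            else:
                hi = float(np.var(h.Gamma - beta * h.gamma)) + 1.0
                while tau_eq(hi, beta) > 0:
                    hi *= 4.0
                new_tau2 = float(optimize.brentq(tau_eq, 0.0, hi, args=(beta,),
                                                 xtol=1e-14))
            new_beta = _solve_score(h, new_tau2, beta)
            converged = abs(new_beta - beta) < 1e-10 and abs(new_tau2 - tau2) < 1e-12
            beta, tau2 = new_beta, new_tau2
            if converged:
                break
        else:
            raise EstimationError("overdispersion iteration did not converge", beta, tau2)

    v = h.sigma_y**2 + beta**2 * h.sigma_x**2 + tau2
    r = h.Gamma - beta * h.gamma
    psi = r * (h.gamma * (h.sigma_y**2 + tau2) + beta * h.sigma_x**2 * h.Gamma) / v**2
    eps = 1e-6 * (abs(beta) + 1.0)
    dpsi = (_raps_score(beta + eps, h, tau2) - _raps_score(beta - eps, h, tau2)) / (2 * eps)
    if dpsi == 0:
        raise EstimationError("degenerate score derivative in mr_raps", beta)
    se = math.sqrt(float(np.sum(psi**2))) / abs(dpsi)
    return MREstimate("raps", beta, se, _norm_p(beta, se), h.k,
                      extra={"tau2": tau2, "overdispersion": overdispersion})


ALL_METHODS = ("ivw", "egger", "weighted_median", "max_likelihood", "raps")
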