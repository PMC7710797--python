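"""Heterogeneity, pleiotropy, directionality and influence diagnostics.

These checks probe the instrumental-variable assumptions behind the
estimators: Cochran's Q and I² quantify between-SNP heterogeneity of the
Wald ratios; the Egger intercept and the PRESSO resampling test look for
directional pleiotropy and outlying instruments; the Steiger test asks
whether the instruments explain more variance in the exposure than in the
outcome (the assumed causal direction); leave-one-out quantifies the
influence of single SNPs; and the confounder screen removes instruments
associated with a measured third trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError, DataError
from .estimators import MREstimate, ivw, mr_egger, max_likelihood, wald_ratio
from .instruments import variance_explained
from .summary_io import HarmonizedInstruments, SummaryTable

logger = logging.getLogger(__name__)


@dataclass
class HeterogeneityResult:
    method: str
    Q: float
    df: int
    i2: float
    pvalue: float


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_p: np.ndarray
    outliers: list
    corrected: MREstimate | None
    n_sim: int
    seed: int | None


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: bool
    pvalue: float


@dataclass
class LooTable:
    full: MREstimate
    table: pd.DataFrame = field(repr=False)  # snp_id, beta, se, pvalue, or, flags

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def i_squared(Q: float, df: int) -> float:
    """I² heterogeneity proportion max(0, (Q − df)/Q), truncated at 0.

    Q at or below its degrees of freedom means no detectable excess
    dispersion; the truncation maps such values to exactly 0."""
    return max(0.0, (Q - df) / Q) if Q > 0 else 0.0


def cochran_q(h: HarmonizedInstruments, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic around a pooled estimate.

    For ``ivw`` and ``max_likelihood`` the Q is the weighted sum of squared
    deviations of the per-SNP Wald ratios from the pooled slope (df = k−1);
    for ``egger`` it is the weighted residual sum of squares around the
    intercept-including fit (df = k−2).  I² = max(0, (Q−df)/Q).
    """
    if method in ("ivw", "max_likelihood"):
        if h.k < 2:
            raise DataError("heterogeneity needs at least 2 instruments")
        r = wald_ratio(h)
        pooled = ivw(h, re_mode="fixed").beta if method == "ivw" else max_likelihood(h).beta
        Q = float(np.sum(r.w * (r.beta - pooled) ** 2))
        df = len(r.beta) - 1
    elif method == "egger":
        if h.k < 3:
            raise DataError("Egger heterogeneity needs at least 3 instruments")
        est, pl = mr_egger(h)
        sign = np.where(h.gamma < 0, -1.0, 1.0)
        resid = h.Gamma * sign - pl.intercept - est.beta * h.gamma * sign
        Q = float(np.sum(resid**2 / h.sigma_y**2))
        df = h.k - 2
    else:
        raise ConfigurationError(f"unknown heterogeneity method {method!r}")
    return HeterogeneityResult(method, Q, df, i_squared(Q, df),
                               float(stats.chi2.sf(Q, df)))


def i2_gx(h: HarmonizedInstruments) -> float:
    """I² of the SNP-exposure effects: expected relative attenuation of the
    Egger slope from exposure-side measurement error (NOME violation)."""
    if h.k < 3:
        raise DataError("i2_gx needs at least 3 instruments")
    w = 1.0 / h.sigma_x**2
    g = np.abs(h.gamma)
    gbar = float(np.sum(w * g) / np.sum(w))
    Qgx = float(np.sum((g - gbar) ** 2 * w))
    return i_squared(Qgx, h.k - 1)


def _loo_ivw_betas(ratios: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every SNP, vectorized."""
    S1 = np.sum(w * ratios, axis=-1, keepdims=True)
    S0 = np.sum(w, axis=-1, keepdims=True)
    return (S1 - w * ratios) / (S0 - w)


def mr_presso(h: HarmonizedInstruments, n_sim: int = 1000, alpha: float = 0.05,
              seed: int | None = None) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier resampling test.

    The observed RSS sums, over SNPs, the squared outcome residual from the
    leave-one-out IVW prediction, scaled by σ_Yj².  Its null distribution
    is simulated by redrawing γ*_j ~ N(γ̂_j, σ_Xj²) and
    Γ*_j ~ N(β_(−j)·γ̂_j, σ_Yj²) and recomputing the RSS (including the
    leave-one-out fits) on each replicate.  global_p uses the
    (1 + count)/(n_sim + 1) estimator, so it can never be exactly zero.
    Per-SNP outlier p-values compare each observed residual with its own
    simulated distribution and are Bonferroni-adjusted; the corrected
    estimate is the IVW fit after removing flagged outliers.
    """
    if h.k < 4:
        raise DataError("mr_presso needs at least 4 instruments")
    if np.any(h.gamma == 0):
        h = h.subset(h.gamma != 0)
    if h.k < 4:
        raise DataError("mr_presso needs at least 4 usable instruments")
    r = wald_ratio(h)
    k = len(r.beta)
    w = r.w
    beta_loo = _loo_ivw_betas(r.beta[None, :], w[None, :])[0]
    resid_obs = (h.Gamma - beta_loo * h.gamma) ** 2 / h.sigma_y**2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    g_star = rng.normal(h.gamma, h.sigma_x, size=(n_sim, k))
    G_star = rng.normal(beta_loo * h.gamma, h.sigma_y, size=(n_sim, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_star = G_star / g_star
        w_star = g_star**2 / h.sigma_y**2
    beta_loo_star = _loo_ivw_betas(ratios_star, w_star)
    resid_star = (G_star - beta_loo_star * g_star) ** 2 / h.sigma_y**2
    rss_star = resid_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (n_sim + 1)
    adjusted = np.minimum(1.0, outlier_p * k)
    flagged = adjusted < alpha
    outliers = list(h.snp_id[flagged])

    corrected = None
    if flagged.sum() < k - 1:
        corrected = ivw(h.subset(~flagged))
        corrected = MREstimate("presso_corrected", corrected.beta, corrected.se,
                               corrected.pvalue, corrected.n_snps, corrected.extra)
    return PressoResult(rss_obs=rss_obs, global_p=global_p, outlier_p=outlier_p,
                        outliers=outliers, corrected=corrected, n_sim=n_sim, seed=seed)


def steiger(h: HarmonizedInstruments, n_exposure: float | None = None,
            n_outcome: float | None = None) -> SteigerResult:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-SNP r² uses the z-based formula z²/(z² + n − 2) and is summed over
    instruments for each trait.  The p-value compares the implied
    multiple-correlation magnitudes through Fisher's z transform for two
    independent samples.  Equal r² reports direction False with p = 1.
    """
    def _resolve(n_arg, n_arr, side):
        if n_arg is not None:
            return float(n_arg)
        if n_arr is not None and np.isfinite(n_arr).all():
            return float(np.mean(n_arr))
        raise ConfigurationError(
            f"steiger needs the {side} sample size: pass n_{side} or provide "
            "sample-size columns in the summary tables")

    nx = _resolve(n_exposure, h.n_exposure, "exposure")
    ny = _resolve(n_outcome, h.n_outcome, "outcome")
    r2x = float(np.sum(variance_explained(beta=h.gamma, se=h.sigma_x, n=nx, mode="z_based")))
    r2y = float(np.sum(variance_explained(beta=h.Gamma, se=h.sigma_y, n=ny, mode="z_based")))
    r2x, r2y = min(r2x, 1.0 - 1e-12), min(r2y, 1.0 - 1e-12)
    zx, zy = np.arctanh(math.sqrt(r2x)), np.arctanh(math.sqrt(r2y))
    z = (zx - zy) / math.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(r2_exposure=r2x, r2_outcome=r2y,
                         direction=bool(r2x > r2y), pvalue=p)


def leave_one_out(h: HarmonizedInstruments, alpha: float = 0.05) -> LooTable:
    """IVW estimate omitting each SNP in turn, with influence flags.

    ``sign_change`` marks rows whose slope changes sign relative to the
    all-SNP estimate; ``significance_change`` marks rows crossing the
    two-sided normal ``alpha`` threshold in either direction.
    """
    if h.k < 3:
        raise DataError("leave_one_out needs at least 3 instruments")
    full = ivw(h)
    rows = []
    for j in range(h.k):
        mask = np.ones(h.k, dtype=bool)
        mask[j] = False
        est = ivw(h.subset(mask))
        rows.append({
            "snp_id": h.snp_id[j], "beta": est.beta, "se": est.se,
            "or": est.or_, "pvalue": est.pvalue, "n_snps": est.n_snps,
            "sign_change": (est.beta > 0) != (full.beta > 0),
            "significance_change": (est.pvalue < alpha) != (full.pvalue < alpha),
        })
    return LooTable(full=full, table=pd.DataFrame(rows))


def confounder_screen(instruments: SummaryTable, third_trait: SummaryTable,
                      alpha_family: float = 0.05):
    """Remove instruments associated with a measured potential confounder.

    The per-SNP threshold is the Bonferroni-corrected ``alpha_family / N``
    with N the instrument count.  Instruments absent from the third-trait
    table cannot be screened and are retained with a warning.  Returns
    ``(flagged_ids, filtered_table, threshold)``.
    """
    N = len(instruments)
    if N == 0:
        raise DataError("confounder screen needs a non-empty instrument table")
    threshold = alpha_family / N
    flagged = []
    unscreened = 0
    for _, row in instruments.data.iterrows():
        hit = third_trait.lookup(row["snp_id"])
        if hit is None:
            unscreened += 1
            continue
        if hit["pvalue"] < threshold:
            flagged.append(row["snp_id"])
    if unscreened:
        logger.warning("%d instrument(s) absent from the third-trait table were "
                       "retained unscreened", unscreened)
    keep = instruments.data[~instruments.data["snp_id"].isin(flagged)]
    return flagged, SummaryTable(instruments.trait_label, keep.copy()), threshold
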