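"""Monte-Carlo calibration and recovery studies for the whole toolchain.

Each study regenerates synthetic two-sample GWAS data many times under a
stated truth and measures frequentist operating characteristics: type-I
error of the tests under the null, bias and confidence-interval coverage
of the estimators under a causal effect, recovery of the mean direct
effect by the Egger intercept under directional pleiotropy, and the
outlier test's detection rate with an implanted pleiotropic SNP.  These
functions back both the test suite and the reproduction script; they are
deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np

from .estimators import ivw, max_likelihood, mr_egger, mr_raps, weighted_median
from .sensitivity import cochran_q, mr_presso, steiger
from .synthetic import Pleiotropy, SyntheticTruth, generate_harmonized

RECOVERY_METHODS = ("ivw", "egger", "weighted_median", "max_likelihood", "raps")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(int(seed) % (2**31))
    return ss.generate_state(n) % (2**31)


def null_calibration(n_reps: int = 400, seed: int = 0, k: int = 50,
                     n_sim_presso: int = 1000, alpha: float = 0.05) -> dict:
    """Type-I error of IVW, Cochran's Q and the PRESSO global test under the
    null generator (no causal effect, no pleiotropy)."""
    seeds = _child_seeds(seed, n_reps)
    rej_ivw = rej_q = rej_presso = 0
    for i, s in enumerate(seeds):
        h = generate_harmonized(SyntheticTruth(beta_true=0.0, k=k, seed=int(s)))
        rej_ivw += ivw(h).pvalue < alpha
        rej_q += cochran_q(h, "ivw").pvalue < alpha
        rej_presso += mr_presso(h, n_sim=n_sim_presso, seed=int(s) + 1).global_p < alpha
    return {
        "n_reps": n_reps, "alpha": alpha,
        "ivw_rejection_rate": rej_ivw / n_reps,
        "cochran_q_rejection_rate": rej_q / n_reps,
        "presso_global_rejection_rate": rej_presso / n_reps,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


def recovery_study(n_reps: int = 400, seed: int = 0, beta_true: float = 0.2,
                   k: int = 50, n_boot: int = 1000) -> dict:
    """Bias and 95% CI coverage of all five estimators under a causal effect.

    Returns per-method mean estimate, Monte-Carlo SE of that mean, coverage
    of exp(beta_true) by the OR confidence interval, and the deviation of
    the mean from truth in Monte-Carlo SE units.
    """
    seeds = _child_seeds(seed, n_reps)
    est = {m: [] for m in RECOVERY_METHODS}
    cover = {m: 0 for m in RECOVERY_METHODS}
    for s in seeds:
        h = generate_harmonized(SyntheticTruth(beta_true=beta_true, k=k, seed=int(s)))
        fits = {
            "ivw": ivw(h),
            "egger": mr_egger(h)[0],
            "weighted_median": weighted_median(h, n_boot=n_boot, seed=int(s) + 1),
            "max_likelihood": max_likelihood(h),
            "raps": mr_raps(h),
        }
        for m, e in fits.items():
            est[m].append(e.beta)
            cover[m] += e.ci_low < np.exp(beta_true) < e.ci_high
    out: dict = {"n_reps": n_reps, "beta_true": beta_true}
    for m in RECOVERY_METHODS:
        v = np.asarray(est[m])
        mcse = float(v.std(ddof=1) / np.sqrt(n_reps))
        out[m] = {
            "mean": float(v.mean()), "mc_se": mcse,
            "deviation_in_mc_se": float(abs(v.mean() - beta_true) / mcse),
            "coverage": cover[m] / n_reps,
        }
    return out


def directional_pleiotropy_study(n_reps: int = 500, seed: int = 0,
                                 mu: float = 0.02, tau: float = 0.01,
                                 beta_true: float = 0.2, k: int = 50) -> dict:
    """Egger intercept recovery of the mean direct effect μ, and the IVW
    bias that directional pleiotropy induces."""
    seeds = _child_seeds(seed, n_reps)
    intercepts, ivw_betas = [], []
    for s in seeds:
        truth = SyntheticTruth(beta_true=beta_true, k=k, seed=int(s),
                               pleiotropy=Pleiotropy("directional", mu=mu, tau=tau))
        h = generate_harmonized(truth)
        intercepts.append(mr_egger(h)[1].intercept)
        ivw_betas.append(ivw(h).beta)
    b0 = np.asarray(intercepts)
    mcse = float(b0.std(ddof=1) / np.sqrt(n_reps))
    return {
        "n_reps": n_reps, "mu": mu,
        "intercept_mean": float(b0.mean()), "intercept_mc_se": mcse,
        "deviation_in_mc_se": float(abs(b0.mean() - mu) / mcse),
        "ivw_mean": float(np.mean(ivw_betas)),
    }


def outlier_detection_study(n_reps: int = 100, seed: int = 0,
                            beta_true: float = 0.2, k: int = 50,
                            magnitude: float = 0.12,
                            n_sim: int = 1000) -> dict:
    """PRESSO detection of one implanted pleiotropic SNP.

    ``magnitude`` ≈ 10 outcome SEs at the default sample sizes.  Reports
    the fraction of replicates flagging the implanted SNP and how often the
    outlier-corrected IVW lands closer to the truth than the plain IVW.
    """
    seeds = _child_seeds(seed, n_reps)
    flagged = corrected_closer = 0
    for s in seeds:
        truth = SyntheticTruth(
            beta_true=beta_true, k=k, seed=int(s),
            pleiotropy=Pleiotropy("outlier", indices=(0,), magnitudes=(magnitude,)))
        h = generate_harmonized(truth)
        res = mr_presso(h, n_sim=n_sim, seed=int(s) + 1)
        if h.snp_id[0] in res.outliers:
            flagged += 1
        if res.corrected is not None:
            plain = ivw(h)
            corrected_closer += (abs(res.corrected.beta - beta_true)
                                 < abs(plain.beta - beta_true))
    return {
        "n_reps": n_reps, "magnitude": magnitude,
        "detection_rate": flagged / n_reps,
        "corrected_closer_rate": corrected_closer / n_reps,
    }


def steiger_direction_study(n_reps: int = 200, seed: int = 0,
                            beta_true: float = 0.2, k: int = 50) -> dict:
    """How often the directionality test recovers the generating direction."""
    seeds = _child_seeds(seed, n_reps)
    correct = 0
    for s in seeds:
        h = generate_harmonized(SyntheticTruth(beta_true=beta_true, k=k, seed=int(s)))
        correct += steiger(h).direction
    return {"n_reps": n_reps, "direction_correct_rate": correct / n_reps}
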