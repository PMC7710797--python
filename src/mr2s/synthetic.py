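"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the setting the estimators assume: k independent
SNPs instrument an exposure; per-SNP effects on the outcome are
Γ_j = β·γ_j + α_j where β is the causal effect and α_j a direct
(pleiotropic) effect; the exposure and outcome associations are estimated
in two non-overlapping samples, so their sampling errors are independent.
Effects are on a standardized continuous-trait scale; for binary traits
the same mechanics apply with betas read as log odds ratios.

Pleiotropy models
-----------------
``none``            α_j = 0 (all instruments valid).
``balanced``        α_j ~ N(0, τ²): heterogeneity without directional bias.
``directional``     α_j ~ N(μ, τ²): biases IVW; the Egger intercept
                    estimates μ.
``outlier``         α_j = 0 except at chosen indices with stated
                    magnitudes (PRESSO's target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError, DataError
from .instruments import LDMatrix
from .summary_io import HarmonizedInstruments, SummaryTable

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclass
class Pleiotropy:
    """Direct-effect model for the instruments; see the module docstring."""

    kind: str = "none"            # none | balanced | directional | outlier
    mu: float = 0.0               # mean direct effect (directional)
    tau: float = 0.0              # SD of direct effects (balanced/directional)
    indices: tuple = ()           # outlier positions (outlier)
    magnitudes: tuple = ()        # outlier direct effects, same length

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "outlier"):
            raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")
        if self.tau < 0:
            raise ConfigurationError("tau must be non-negative")
        if self.kind == "outlier" and len(self.indices) != len(self.magnitudes):
            raise ConfigurationError("outlier indices and magnitudes differ in length")

    def draw(self, rng: np.random.Generator, k: int) -> np.ndarray:
        alpha = np.zeros(k)
        if self.kind == "balanced":
            alpha = rng.normal(0.0, self.tau, k)
        elif self.kind == "directional":
            alpha = rng.normal(self.mu, self.tau, k)
        elif self.kind == "outlier":
            alpha[list(self.indices)] = np.asarray(self.magnitudes, dtype=float)
        return alpha


@dataclass
class SyntheticTruth:
    """Generating parameters for one synthetic exposure/outcome pair.

    Defaults describe a well-powered two-sample design with strong
    instruments: 50 SNPs, 20 000 individuals per sample, true exposure
    effects γ_j ~ |N(0, 0.25²)| (effect allele coded exposure-increasing)
    resampled until the implied F statistic clears ``f_floor``.  The
    per-allele log odds ratios this implies (median ≈ 0.17) and the F
    range are in line with genome-wide-significant hits for common
    immune-mediated diseases; instruments this strong keep the
    regression-dilution attenuation of the ratio-based estimators well
    below their Monte-Carlo resolution, which is what the recovery
    studies in :mod:`mr2s.calibration` assume.
    """

    beta_true: float = 0.0
    k: int = 50
    n_x: int = 20_000
    n_y: int = 20_000
    gamma_sd: float = 0.25
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    maf_range: tuple = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    f_floor: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ConfigurationError("k must be at least 4")
        if min(self.n_x, self.n_y) <= 3:
            raise ConfigurationError("sample sizes must exceed 3")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ConfigurationError("palindromic_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi <= 0.5")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


def _draw_effects(rng, truth: SyntheticTruth, sigma_x: np.ndarray) -> np.ndarray:
    """True exposure effects resampled per SNP until F = (γ/σ_X)² ≥ f_floor.

    Effects are half-normal (γ_j ≥ 0): the effect allele is coded as the
    exposure-increasing allele, as GWAS instrument lists conventionally
    report.  Direct (pleiotropic) effects are defined on this oriented
    frame, so a directional model really is directional.
    """
    gamma = np.abs(rng.normal(0.0, truth.gamma_sd, truth.k))
    for _ in range(1000):
        weak = (gamma / sigma_x) ** 2 < truth.f_floor
        if not weak.any():
            return gamma
        gamma[weak] = np.abs(rng.normal(0.0, truth.gamma_sd, int(weak.sum())))
    raise DataError(
        "cannot reach the F floor: increase n_x or gamma_sd, or lower f_floor")


def _sample_alleles(rng, truth: SyntheticTruth):
    k = truth.k
    palindromic = rng.random(k) < truth.palindromic_fraction
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    for j in range(k):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    return ea, oa, palindromic


def generate_pair(truth: SyntheticTruth):
    """Generate (exposure SummaryTable, outcome SummaryTable, truth echo).

    The echo is a dict holding the input parameters plus the realized true
    per-SNP effects, for parameter-recovery tests.
    """
    rng = np.random.default_rng(truth.seed)
    k = truth.k
    maf = rng.uniform(*truth.maf_range, k)
    sigma_x = 1.0 / np.sqrt(2.0 * truth.n_x * maf * (1.0 - maf))
    sigma_y = 1.0 / np.sqrt(2.0 * truth.n_y * maf * (1.0 - maf))
    gamma = _draw_effects(rng, truth, sigma_x)
    alpha = truth.pleiotropy.draw(rng, k)
    Gamma = truth.beta_true * gamma + alpha
    gamma_hat = rng.normal(gamma, sigma_x)
    Gamma_hat = rng.normal(Gamma, sigma_y)
    ea, oa, palindromic = _sample_alleles(rng, truth)
    snp_id = np.array([f"snp{j + 1:04d}" for j in range(k)], dtype=object)

    def _table(label, beta, se, n):
        return SummaryTable(label, pd.DataFrame({
            "snp_id": snp_id, "effect_allele": ea, "other_allele": oa,
            "eaf": maf, "beta": beta, "se": se,
            "pvalue": 2.0 * stats.norm.sf(np.abs(beta / se)),
            "n": float(n),
        }))

    exposure = _table("exposure", gamma_hat, sigma_x, truth.n_x)
    outcome = _table("outcome", Gamma_hat, sigma_y, truth.n_y)
    echo = dict(asdict(truth), gamma_true=gamma.tolist(), alpha_true=alpha.tolist(),
                palindromic=palindromic.tolist())
    return exposure, outcome, echo


def generate_harmonized(truth: SyntheticTruth) -> HarmonizedInstruments:
    """Generate instruments already on a common allele frame.

    Convenience for estimator-level studies: same noise model as
    :func:`generate_pair` but skipping allele bookkeeping, so no SNP is
    lost to palindrome or frequency filters.
    """
    exposure, outcome, echo = generate_pair(truth)
    ex, out = exposure.data, outcome.data
    return HarmonizedInstruments(
        snp_id=ex["snp_id"].to_numpy(dtype=object),
        gamma=ex["beta"].to_numpy(float), sigma_x=ex["se"].to_numpy(float),
        Gamma=out["beta"].to_numpy(float), sigma_y=out["se"].to_numpy(float),
        eaf=ex["eaf"].to_numpy(float),
        flags=pd.DataFrame({"flipped": np.zeros(truth.k, bool),
                            "palindromic": echo["palindromic"],
                            "proxy": [""] * truth.k}),
        drops=pd.DataFrame(columns=["snp_id", "reason"]),
        n_exposure=np.full(truth.k, float(truth.n_x)),
        n_outcome=np.full(truth.k, float(truth.n_y)),
    )


def generate_bidirectional(truth_forward: SyntheticTruth,
                           truth_reverse: SyntheticTruth):
    """Two trait tables supporting MR in both causal directions.

    Trait A carries ``truth_forward.k`` instruments with causal effect
    ``truth_forward.beta_true`` on trait B; trait B carries
    ``truth_reverse.k`` instruments with effect ``truth_reverse.beta_true``
    on A.  Each returned table contains both instrument sets (ids prefixed
    ``a_``/``b_``), so a reverse analysis can select B's instruments from
    the same files.  Returns (table_a, table_b, echo).
    """
    exp_f, out_f, echo_f = generate_pair(truth_forward)
    exp_r, out_r, echo_r = generate_pair(truth_reverse)

    def _prefix(df, pre):
        df = df.copy()
        df["snp_id"] = pre + df["snp_id"]
        return df

    table_a = SummaryTable("trait_a", pd.concat(
        [_prefix(exp_f.data, "a_"), _prefix(out_r.data, "b_")], ignore_index=True))
    table_b = SummaryTable("trait_b", pd.concat(
        [_prefix(out_f.data, "a_"), _prefix(exp_r.data, "b_")], ignore_index=True))
    return table_a, table_b, {"forward": echo_f, "reverse": echo_r}


def make_ld_matrix(blocks, snp_ids=None) -> LDMatrix:
    """Block-diagonal LD matrix from (size, within_r2) tuples.

    Within-block off-diagonal r² equals ``within_r2``, cross-block r² is 0,
    and the diagonal is 1.  SNP ids default to ``snp0001``… matching
    :func:`generate_pair` output order.
    """
    sizes = [int(s) for s, _ in blocks]
    total = sum(sizes)
    r2 = np.zeros((total, total))
    start = 0
    for size, within in blocks:
        if not 0.0 <= within <= 1.0:
            raise ConfigurationError("within-block r² must lie in [0, 1]")
        sl = slice(start, start + size)
        r2[sl, sl] = within
        start += size
    np.fill_diagonal(r2, 1.0)
    if snp_ids is None:
        snp_ids = [f"snp{j + 1:04d}" for j in range(total)]
    if len(snp_ids) != total:
        raise ConfigurationError("snp_ids length must match total block size")
    return LDMatrix(list(snp_ids), r2)
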