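"""Instrument selection and strength diagnostics.

Candidate instruments are genome-wide-significant SNPs pruned to approximate
linkage equilibrium by greedy clumping on pairwise r².  Instrument strength
is summarized by the per-SNP F statistic (squared Wald z) and the variance
in the exposure explained by each SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataError
from .summary_io import SummaryTable

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.01
WEAK_INSTRUMENT_F = 10.0


@dataclass
class LDMatrix:
    """Pairwise r² between SNPs: symmetric, unit diagonal, values in [0,1]."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("LD matrix shape does not match SNP id list")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ConfigurationError("LD r² values must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def pairwise(self, a: str, b: str) -> float | None:
        """r² between two SNPs, or None when either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


def select_instruments(table: SummaryTable, p_threshold: float = GENOME_WIDE_P,
                       ld: LDMatrix | None = None,
                       r2_threshold: float = DEFAULT_CLUMP_R2) -> SummaryTable:
    """Significance filter followed by greedy LD clumping.

    SNPs with ``pvalue < p_threshold`` are kept, sorted by ascending
    p-value (ties broken by snp_id), and accepted one by one: a SNP enters
    the instrument set iff its r² with every already-accepted SNP is below
    ``r2_threshold``.  Without an LD matrix only the significance filter is
    applied (with a warning); a SNP missing from the LD matrix is treated
    as independent, with a warning.
    """
    df = table.data[table.data["pvalue"] < p_threshold]
    if df.empty:
        raise DataError(f"no SNP passes p < {p_threshold:g} in {table.trait_label!r}")
    if ld is None:
        logger.warning("no LD matrix supplied: applying significance filter only")
        return SummaryTable(table.trait_label, df.copy())

    df = df.sort_values(["pvalue", "snp_id"], kind="mergesort")
    accepted: list[str] = []
    missing_warned = False
    for sid in df["snp_id"]:
        clash = False
        for kept in accepted:
            r2 = ld.pairwise(sid, kept)
            if r2 is None:
                if not missing_warned:
                    logger.warning("SNP(s) absent from LD matrix treated as independent")
                    missing_warned = True
                continue
            if r2 >= r2_threshold:
                clash = True
                break
        if not clash:
            accepted.append(sid)
    keep = df[df["snp_id"].isin(accepted)]
    return SummaryTable(table.trait_label, keep.copy())


def f_statistic(beta, se):
    """Per-SNP instrument F statistic, the squared Wald z: F = (beta/se)²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DataError("se must be positive")
    return (beta / se) ** 2


def variance_explained(beta=None, se=None, eaf=None, n=None, mode: str = "z_based"):
    """Variance in the (standardized) exposure explained by a SNP.

    ``z_based`` uses r² = z²/(z² + n − 2) with z = beta/se and needs only
    summary statistics; ``af_based`` uses r² = 2·beta²·eaf·(1−eaf), valid
    when beta is on a standardized-trait scale.
    """
    if mode == "z_based":
        if beta is None or se is None or n is None:
            raise ConfigurationError("z_based mode needs beta, se and n")
        z2 = f_statistic(beta, se)
        n = np.asarray(n, dtype=float)
        return z2 / (z2 + n - 2.0)
    if mode == "af_based":
        if beta is None or eaf is None:
            raise ConfigurationError("af_based mode needs beta and eaf")
        beta = np.asarray(beta, dtype=float)
        eaf = np.asarray(eaf, dtype=float)
        return 2.0 * beta**2 * eaf * (1.0 - eaf)
    raise ConfigurationError(f"unknown variance_explained mode {mode!r}")


@dataclass
class InstrumentDiagnostics:
    """Per-SNP F and r² with their summaries; ``r2_total`` sums per-SNP r²."""

    table: pd.DataFrame  # snp_id, F, r2
    f_min: float
    f_max: float
    f_mean: float
    r2_total: float

    @classmethod
    def from_table(cls, table: SummaryTable, mode: str = "z_based") -> "InstrumentDiagnostics":
        df = table.data
        F = f_statistic(df["beta"], df["se"])
        if mode == "z_based":
            r2 = variance_explained(beta=df["beta"], se=df["se"], n=df["n"], mode=mode)
        else:
            r2 = variance_explained(beta=df["beta"], eaf=df["eaf"], mode=mode)
        out = pd.DataFrame({"snp_id": df["snp_id"].to_numpy(), "F": np.asarray(F),
                            "r2": np.asarray(r2)})
        r2v = out["r2"].to_numpy(float)
        return cls(table=out, f_min=float(out["F"].min()), f_max=float(out["F"].max()),
                   f_mean=float(out["F"].mean()),
                   r2_total=float(np.nansum(r2v)))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def weak_instrument_filter(table: SummaryTable, f_min: float = WEAK_INSTRUMENT_F):
    """Split a table into (strong, dropped-ids) at the F ≥ f_min rule."""
    F = f_statistic(table.data["beta"], table.data["se"])
    weak = np.asarray(F) < f_min
    dropped = list(table.data.loc[weak, "snp_id"])
    if weak.all():
        raise DataError("all instruments are weak (F below threshold)")
    strong = SummaryTable(table.trait_label, table.data.loc[~weak].copy())
    return strong, dropped
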