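"""GWAS summary-statistics containers, TSV I/O, and allele harmonization.

A two-sample Mendelian randomization analysis starts from two tables of
per-SNP association estimates: one for the exposure trait and one for the
outcome trait, drawn from non-overlapping samples.  Before any causal
estimator can run, the two tables must be put on a common allele frame:
the outcome effect of every instrument is re-expressed per copy of the
exposure table's effect allele, strand flips are resolved through base
complementation, and palindromic variants (A/T or G/C) whose strand cannot
be resolved from allele labels are removed when their allele frequency is
uninformative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column name -> default header in input TSV files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}

MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

#: window of effect-allele frequencies inside which a palindromic SNP's
#: strand cannot be trusted and the variant is dropped
DEFAULT_PALINDROME_WINDOW = (0.01, 0.30)


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log odds ratio for binary traits); ``eaf`` and ``n`` may be NaN when
    the source study does not report them.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float = math.nan
    n: float = math.nan

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise DataError(f"{self.snp_id}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise DataError(f"{self.snp_id}: se must be positive")
        if not math.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise DataError(f"{self.snp_id}: eaf outside [0, 1]")
        if not 0.0 < self.pvalue <= 1.0:
            raise DataError(f"{self.snp_id}: p-value outside (0, 1]")


@dataclass
class SummaryTable:
    """A set of :class:`VariantAssociation` records for one trait.

    ``data`` holds one row per SNP with the canonical columns
    ``snp_id, effect_allele, other_allele, eaf, beta, se, pvalue, n``;
    ``snp_id`` is unique.
    """

    trait_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"summary table missing columns: {missing}")
        for opt in ("eaf", "n"):
            if opt not in self.data.columns:
                self.data[opt] = np.nan
        if self.data["snp_id"].duplicated().any():
            raise DataError("duplicate snp_id in SummaryTable")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def lookup(self, snp_id: str) -> pd.Series | None:
        hit = self.data.loc[self.data["snp_id"] == snp_id]
        return None if hit.empty else hit.iloc[0]

    def subset(self, snp_ids) -> "SummaryTable":
        keep = self.data[self.data["snp_id"].isin(set(snp_ids))]
        return SummaryTable(self.trait_label, keep.copy())

    def to_tsv(self, path, column_map: dict | None = None) -> None:
        cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
        out = self.data.rename(columns=cmap)
        out.to_csv(path, sep="\t", index=False)


def read_summary_table(path, column_map: dict | None = None,
                       trait_label: str | None = None) -> SummaryTable:
    """Read a tab-separated GWAS summary file into a validated table.

    ``column_map`` maps canonical names (``snp_id``, ``beta``, ...) to the
    file's headers, overriding :data:`DEFAULT_COLUMN_MAP` entries.  Rows
    violating record invariants (non-positive SE, invalid alleles, p-value
    outside (0, 1]) are dropped with a logged count; duplicated SNP ids
    keep the first occurrence.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    raw = pd.read_csv(path, sep="\t")
    rename = {v: k for k, v in cmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory columns {missing} (headers found: {list(raw.columns)})")
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan

    df = df[["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"]].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    n0 = len(df)
    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    df = df[ok]
    # missing p-values are reconstructed from the Wald z; present ones are
    # cross-checked and mismatches only warned about (GWAS files round p)
    z = (df["beta"] / df["se"]).abs()
    implied = 2.0 * stats.norm.sf(z)
    missing_p = df["pvalue"].isna() | (df["pvalue"] <= 0) | (df["pvalue"] > 1)
    df.loc[missing_p, "pvalue"] = implied[missing_p]
    with np.errstate(divide="ignore"):
        both = ~missing_p & (df["pvalue"] > 0)
        mism = both & (np.abs(np.log10(df["pvalue"]) - np.log10(np.maximum(implied, 1e-300))) > 1.0)
    if mism.any():
        logger.warning("%s: %d rows with p-value inconsistent with |beta/se| (kept)",
                       path, int(mism.sum()))

    dup = df["snp_id"].duplicated()
    if dup.any():
        logger.warning("%s: %d duplicated snp_id rows dropped (first kept)", path, int(dup.sum()))
        df = df[~dup]
    dropped = n0 - len(df)
    if dropped:
        logger.info("%s: dropped %d invalid rows of %d", path, dropped, n0)
    if df.empty:
        raise DataError(f"{path}: no valid rows after validation")
    return SummaryTable(trait_label or str(path), df.reset_index(drop=True))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {G,C}."""
    pair = {effect_allele, other_allele}
    if not pair <= VALID_ALLELES or len(pair) != 2:
        raise DataError(f"invalid allele pair {effect_allele}/{other_allele}")
    return pair in ({"A", "T"}, {"G", "C"})


def has_intermediate_af(eaf: float, window=DEFAULT_PALINDROME_WINDOW) -> bool:
    """True iff ``lo < eaf < hi`` (strict), evaluated on the effect-allele
    frequency as given."""
    lo, hi = window
    return lo < eaf < hi


@dataclass
class HarmonizedInstruments:
    """Per-SNP aligned exposure/outcome effects ready for MR estimation.

    Arrays are parallel and ordered as in the exposure table: ``gamma`` /
    ``sigma_x`` are the SNP-exposure effect and SE, ``Gamma`` / ``sigma_y``
    the SNP-outcome effect and SE, all expressed per copy of the same
    effect allele.  ``drops`` records every excluded exposure SNP with one
    machine-readable reason.
    """

    snp_id: np.ndarray
    gamma: np.ndarray
    sigma_x: np.ndarray
    Gamma: np.ndarray
    sigma_y: np.ndarray
    eaf: np.ndarray
    flags: pd.DataFrame = field(repr=False)
    drops: pd.DataFrame = field(repr=False)
    n_exposure: np.ndarray | None = None
    n_outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise DataError("harmonized SEs must be positive")

    @property
    def k(self) -> int:
        return len(self.snp_id)

    def __len__(self) -> int:
        return self.k

    def subset(self, mask) -> "HarmonizedInstruments":
        mask = np.asarray(mask)
        return HarmonizedInstruments(
            snp_id=self.snp_id[mask], gamma=self.gamma[mask], sigma_x=self.sigma_x[mask],
            Gamma=self.Gamma[mask], sigma_y=self.sigma_y[mask], eaf=self.eaf[mask],
            flags=self.flags.loc[mask].reset_index(drop=True),
            drops=self.drops.iloc[0:0],
            n_exposure=None if self.n_exposure is None else self.n_exposure[mask],
            n_outcome=None if self.n_outcome is None else self.n_outcome[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "snp_id": self.snp_id, "gamma": self.gamma, "sigma_x": self.sigma_x,
            "Gamma": self.Gamma, "sigma_y": self.sigma_y, "eaf": self.eaf,
        })
        return pd.concat([df, self.flags.reset_index(drop=True)], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def drops_to_tsv(self, path) -> None:
        self.drops.to_csv(path, sep="\t", index=False)


def _align_alleles(ea_x: str, oa_x: str, ea_y: str, oa_y: str,
                   palindromic: bool) -> str | None:
    """Classify the outcome allele pair relative to the exposure pair.

    Returns ``"same"``, ``"flip"``, or ``None`` when irreconcilable.  For
    non-palindromic SNPs a strand (complement) transformation is tried
    before giving up; for palindromic SNPs complementation is a no-op and
    the label match is taken at face value.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flip"
    if not palindromic:
        cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        if (cea, coa) == (ea_x, oa_x):
            return "same"
        if (cea, coa) == (oa_x, ea_x):
            return "flip"
    return None


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              proxy_table: dict | None = None, *,
              palindrome_window=DEFAULT_PALINDROME_WINDOW,
              maf_min: float = 0.01) -> HarmonizedInstruments:
    """Align outcome effects to the exposure table's effect alleles.

    For every exposure SNP found in the outcome table (directly, or through
    ``proxy_table`` mapping target id -> proxy id in high LD):

    * matching allele labels keep the outcome effect as is;
    * swapped labels negate the outcome beta and reflect its frequency;
    * strand-complement matches are resolved by complementing first;
    * palindromic SNPs whose exposure effect-allele frequency lies strictly
      inside ``palindrome_window`` (or is missing) are dropped — the strand
      cannot be resolved;
    * palindromic SNPs kept outside the window are additionally oriented by
      allele frequency when both tables report one;
    * SNPs with minor-allele frequency below ``maf_min`` in either table
      are dropped.

    Output rows follow exposure-table order.  Every input SNP is accounted
    for: retained, or present in ``drops`` with exactly one reason.
    """
    rows, drops = [], []
    for _, ex in exposure.data.iterrows():
        sid = ex["snp_id"]
        out = outcome.lookup(sid)
        proxy_used = ""
        if out is None and proxy_table and sid in proxy_table:
            out = outcome.lookup(proxy_table[sid])
            proxy_used = proxy_table[sid] if out is not None else ""
        if out is None:
            drops.append((sid, "missing_in_outcome"))
            continue

        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        palindromic = is_palindromic(ea_x, oa_x)
        if palindromic:
            if pd.isna(ex["eaf"]):
                drops.append((sid, "palindromic_missing_eaf"))
                continue
            if has_intermediate_af(float(ex["eaf"]), palindrome_window):
                drops.append((sid, "palindromic_intermediate"))
                continue

        def _low_maf(eaf) -> bool:
            return (not pd.isna(eaf)) and min(float(eaf), 1.0 - float(eaf)) < maf_min

        if _low_maf(ex["eaf"]) or _low_maf(out["eaf"]):
            drops.append((sid, "low_maf"))
            continue

        action = _align_alleles(ea_x, oa_x, out["effect_allele"], out["other_allele"],
                                palindromic)
        if action is None:
            drops.append((sid, "allele_mismatch"))
            continue

        flipped = action == "flip"
        eaf_y = float(out["eaf"]) if not pd.isna(out["eaf"]) else math.nan
        if flipped and not math.isnan(eaf_y):
            eaf_y = 1.0 - eaf_y
        # palindromic kept outside the window: the label match cannot tell
        # strands apart, so align by which side of 0.5 the frequencies fall
        if palindromic and not math.isnan(eaf_y) and not pd.isna(ex["eaf"]):
            if (float(ex["eaf"]) - 0.5) * (eaf_y - 0.5) < 0:
                flipped = not flipped
                eaf_y = 1.0 - eaf_y

        Gamma = -float(out["beta"]) if flipped else float(out["beta"])
        rows.append({
            "snp_id": sid, "gamma": float(ex["beta"]), "sigma_x": float(ex["se"]),
            "Gamma": Gamma, "sigma_y": float(out["se"]),
            "eaf": float(ex["eaf"]) if not pd.isna(ex["eaf"]) else math.nan,
            "flipped": flipped, "palindromic": palindromic, "proxy": proxy_used,
            "n_exposure": float(ex["n"]) if not pd.isna(ex["n"]) else math.nan,
            "n_outcome": float(out["n"]) if not pd.isna(out["n"]) else math.nan,
        })

    drops_df = pd.DataFrame(drops, columns=["snp_id", "reason"])
    if not rows:
        raise DataError(
            "no exposure instrument could be harmonized against the outcome table "
            f"({len(drops_df)} dropped: {drops_df['reason'].value_counts().to_dict()})")
    df = pd.DataFrame(rows)
    return HarmonizedInstruments(
        snp_id=df["snp_id"].to_numpy(dtype=object),
        gamma=df["gamma"].to_numpy(float), sigma_x=df["sigma_x"].to_numpy(float),
        Gamma=df["Gamma"].to_numpy(float), sigma_y=df["sigma_y"].to_numpy(float),
        eaf=df["eaf"].to_numpy(float),
        flags=df[["flipped", "palindromic", "proxy"]].copy(),
        drops=drops_df,
        n_exposure=df["n_exposure"].to_numpy(float),
        n_outcome=df["n_outcome"].to_numpy(float),
    )
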