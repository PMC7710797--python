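"""Orchestration of the full bidirectional MR analysis.

``run_direction`` chains instrument selection, the weak-instrument filter,
an optional confounder screen, harmonization, the five estimators and the
sensitivity battery into a single :class:`MRReport`.  ``run_bidirectional``
runs the analysis in both causal directions, applying an unadjusted
significance level forward and a Bonferroni family-wise level in reverse,
and labels the trait pair causal-forward / causal-reverse / both / neither.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigurationError, DataError
from .estimators import ivw, max_likelihood, mr_egger, mr_raps, weighted_median
from .instruments import (GENOME_WIDE_P, DEFAULT_CLUMP_R2, WEAK_INSTRUMENT_F,
                          InstrumentDiagnostics, LDMatrix, select_instruments,
                          weak_instrument_filter)
from .sensitivity import (cochran_q, confounder_screen, i2_gx, leave_one_out,
                          mr_presso, steiger)
from .summary_io import (DEFAULT_PALINDROME_WINDOW, SummaryTable, harmonize,
                         read_summary_table)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All thresholds and options of one bidirectional analysis.

    Defaults are the conventional cut-offs for GWAS-based MR: genome-wide
    instrument significance 5e-8, clumping r² < 0.01, MAF ≥ 0.01, per-SNP
    F ≥ 10, palindrome ambiguity window (0.01, 0.30) on the effect-allele
    frequency.  ``seed`` drives every stochastic component (weighted-median
    bootstrap, PRESSO simulations) through independent substreams.
    """

    exposure_path: str | None = None
    outcome_path: str | None = None
    third_trait_path: str | None = None
    ld_path: str | None = None
    proxy_path: str | None = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    direction: str = "both"                 # forward | reverse | both
    p_instrument: float = GENOME_WIDE_P
    r2_clump: float = DEFAULT_CLUMP_R2
    maf_min: float = 0.01
    f_min: float = WEAK_INSTRUMENT_F
    palindrome_window: tuple = DEFAULT_PALINDROME_WINDOW
    re_mode: str = "multiplicative"
    n_boot: int = 1000
    n_sim: int = 1000
    raps_overdispersion: bool = False
    alpha_forward: float = 0.05
    alpha_reverse_family: float = 0.05
    m_reverse: int = 1
    seed: int = 0
    column_map: dict | None = None

    def __post_init__(self) -> None:
        for name in ("p_instrument", "r2_clump", "maf_min", "f_min",
                     "alpha_forward", "alpha_reverse_family"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.direction not in ("forward", "reverse", "both"):
            raise ConfigurationError("direction must be forward, reverse or both")
        if self.m_reverse < 1:
            raise ConfigurationError("m_reverse must be at least 1")
        self.palindrome_window = tuple(self.palindrome_window)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["palindrome_window"] = list(self.palindrome_window)
        return d

    def child_seed(self, stream: int) -> int:
        """Deterministic per-component substream seed (kept below 2^31)."""
        ss = np.random.SeedSequence([int(self.seed) % (2**31), stream])
        return int(ss.generate_state(1)[0] % (2**31))


def bonferroni_threshold(alpha_family: float, m: int) -> float:
    """Family-wise level divided by the number of tests (full precision)."""
    if m < 1:
        raise ConfigurationError("m must be at least 1")
    return alpha_family / m


def display_threshold(threshold: float) -> str:
    """Human-readable threshold at 4 decimal places."""
    return f"{threshold:.4f}"


@dataclass
class MRReport:
    """Everything one direction of the analysis produced."""

    direction: str
    exposure_label: str
    outcome_label: str
    alpha: float
    n_candidates: int
    stage_counts: dict
    diagnostics: InstrumentDiagnostics | None
    estimates: list
    pleiotropy: object | None
    heterogeneity: list
    i2_gx: float | None
    presso: object | None
    steiger: object | None
    loo: object | None
    confounder_flagged: list
    drops: pd.DataFrame = field(repr=False)
    scatter: pd.DataFrame = field(repr=False)
    config: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = ""

    @property
    def significant(self) -> bool:
        ivw_est = next((e for e in self.estimates if e.method == "ivw"), None)
        return ivw_est is not None and ivw_est.pvalue < self.alpha

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.estimates])

    def sensitivity_frame(self) -> pd.DataFrame:
        rows = [{"method": het.method, "Q": het.Q, "df": het.df, "i2": het.i2,
                 "heterogeneity_p": het.pvalue} for het in self.heterogeneity]
        df = pd.DataFrame(rows)
        if self.pleiotropy is not None and not df.empty:
            df.loc[df["method"] == "egger", "egger_intercept"] = self.pleiotropy.intercept
            df.loc[df["method"] == "egger", "intercept_p"] = self.pleiotropy.pvalue
        return df

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "exposure": self.exposure_label,
            "outcome": self.outcome_label,
            "alpha": self.alpha,
            "significant": self.significant,
            "n_candidates": self.n_candidates,
            "stage_counts": self.stage_counts,
            "estimates": [e.to_dict() for e in self.estimates],
            "heterogeneity": [dataclasses.asdict(x) for x in self.heterogeneity],
            "i2_gx": self.i2_gx,
            "confounder_flagged": list(self.confounder_flagged),
            "drops": self.drops.to_dict("records"),
            "warnings": self.warnings,
            "config": self.config,
            "version": self.version,
        }
        if self.diagnostics is not None:
            d["instrument_f"] = {"min": self.diagnostics.f_min,
                                 "max": self.diagnostics.f_max,
                                 "mean": self.diagnostics.f_mean,
                                 "r2_total": self.diagnostics.r2_total}
        if self.pleiotropy is not None:
            d["egger_intercept"] = dataclasses.asdict(self.pleiotropy)
        if self.presso is not None:
            d["presso"] = {
                "rss_obs": self.presso.rss_obs, "global_p": self.presso.global_p,
                "outliers": [str(s) for s in self.presso.outliers],
                "n_sim": self.presso.n_sim,
                "corrected": (self.presso.corrected.to_dict()
                              if self.presso.corrected else None),
            }
        if self.steiger is not None:
            d["steiger"] = dataclasses.asdict(self.steiger)
        return d

    def write(self, outdir) -> None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tag = self.direction
        with open(out / f"report_{tag}.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
        self.estimates_frame().to_csv(out / f"estimates_{tag}.tsv", sep="\t", index=False)
        self.sensitivity_frame().to_csv(out / f"sensitivity_{tag}.tsv", sep="\t",
                                        index=False)
        self.drops.to_csv(out / f"drops_{tag}.tsv", sep="\t", index=False)
        self.scatter.to_csv(out / f"scatter_{tag}.tsv", sep="\t", index=False)
        if self.loo is not None:
            self.loo.to_tsv(out / f"leave_one_out_{tag}.tsv")
        if self.diagnostics is not None:
            self.diagnostics.to_tsv(out / f"instrument_diagnostics_{tag}.tsv")


def run_direction(config: AnalysisConfig, exposure: SummaryTable,
                  outcome: SummaryTable, third_trait: SummaryTable | None = None,
                  ld: LDMatrix | None = None, proxy_table: dict | None = None,
                  direction: str = "forward",
                  alpha: float | None = None) -> MRReport:
    """One direction of the analysis: exposure → outcome.

    Raises :class:`DataError` when no instrument survives to harmonization;
    with fewer than 3 surviving instruments, only the estimators whose
    preconditions hold are run and a prominent warning is recorded.
    """
    if alpha is None:
        alpha = config.alpha_forward
    warnings_log: list[str] = []
    n_candidates = len(exposure)
    stage_counts = {"candidates": n_candidates}

    selected = select_instruments(exposure, config.p_instrument, ld, config.r2_clump)
    stage_counts["significant_independent"] = len(selected)

    selected, weak_ids = weak_instrument_filter(selected, config.f_min)
    stage_counts["strong"] = len(selected)

    flagged: list = []
    if third_trait is not None:
        flagged, selected, thr = confounder_screen(selected, third_trait,
                                                   config.alpha_forward)
        stage_counts["after_confounder_screen"] = len(selected)
        if flagged:
            warnings_log.append(
                f"{len(flagged)} instrument(s) removed by the confounder screen "
                f"at p < {display_threshold(thr)}")

    h = harmonize(selected, outcome, proxy_table,
                  palindrome_window=config.palindrome_window,
                  maf_min=config.maf_min)
    stage_counts["harmonized"] = h.k
    drops = pd.concat([
        pd.DataFrame({"snp_id": weak_ids, "reason": "weak_instrument"}),
        pd.DataFrame({"snp_id": flagged, "reason": "confounder_associated"}),
        h.drops,
    ], ignore_index=True)

    diagnostics = None
    if np.isfinite(selected.data["n"]).all():
        diagnostics = InstrumentDiagnostics.from_table(selected.subset(h.snp_id))

    estimates, heterogeneity = [], []
    pleiotropy = presso = steiger_res = loo = None
    i2gx = None

    if h.k < 3:
        warnings_log.append(
            f"only {h.k} instrument(s) survived selection: estimators requiring "
            "more instruments were skipped")
    if h.k >= 2:
        estimates.append(ivw(h, re_mode=config.re_mode))
        estimates.append(max_likelihood(h))
        heterogeneity.append(cochran_q(h, "ivw"))
        heterogeneity.append(cochran_q(h, "max_likelihood"))
    if h.k >= 3:
        egger_est, pleiotropy = mr_egger(h)
        estimates.insert(0, egger_est)
        estimates.append(weighted_median(h, n_boot=config.n_boot,
                                         seed=config.child_seed(1)))
        estimates.append(mr_raps(h, overdispersion=config.raps_overdispersion))
        heterogeneity.append(cochran_q(h, "egger"))
        i2gx = i2_gx(h)
        loo = leave_one_out(h, alpha=alpha)
    if h.k >= 4:
        presso = mr_presso(h, n_sim=config.n_sim, seed=config.child_seed(2))
        if presso.corrected is not None:
            estimates.append(presso.corrected)
    try:
        steiger_res = steiger(h)
    except ConfigurationError as exc:
        warnings_log.append(str(exc))

    scatter = pd.DataFrame({
        "snp_id": h.snp_id, "gamma": h.gamma, "sigma_x": h.sigma_x,
        "Gamma": h.Gamma, "sigma_y": h.sigma_y,
    })
    return MRReport(
        direction=direction, exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label, alpha=alpha,
        n_candidates=n_candidates, stage_counts=stage_counts,
        diagnostics=diagnostics, estimates=estimates, pleiotropy=pleiotropy,
        heterogeneity=heterogeneity, i2_gx=i2gx, presso=presso,
        steiger=steiger_res, loo=loo, confounder_flagged=flagged, drops=drops,
        scatter=scatter, config=config.to_dict(), warnings=warnings_log,
        version=__version__,
    )


def run_bidirectional(config: AnalysisConfig, trait_a: SummaryTable,
                      trait_b: SummaryTable,
                      third_trait: SummaryTable | None = None,
                      ld_forward: LDMatrix | None = None,
                      ld_reverse: LDMatrix | None = None,
                      proxy_table: dict | None = None) -> dict:
    """Forward (A → B) and reverse (B → A) analyses with a combined verdict.

    Forward significance uses the unadjusted ``alpha_forward``; reverse uses
    the Bonferroni family-wise ``alpha_reverse_family / m_reverse``.
    """
    out: dict = {"forward": None, "reverse": None, "verdict": None}
    if config.direction in ("forward", "both"):
        out["forward"] = run_direction(config, trait_a, trait_b, third_trait,
                                       ld_forward, proxy_table, "forward",
                                       alpha=config.alpha_forward)
    if config.direction in ("reverse", "both"):
        alpha_rev = bonferroni_threshold(config.alpha_reverse_family, config.m_reverse)
        out["reverse"] = run_direction(config, trait_b, trait_a, None,
                                       ld_reverse, proxy_table, "reverse",
                                       alpha=alpha_rev)
    fwd = out["forward"].significant if out["forward"] else False
    rev = out["reverse"].significant if out["reverse"] else False
    out["verdict"] = {(False, False): "neither", (True, False): "causal_forward",
                      (False, True): "causal_reverse", (True, True): "both"}[(fwd, rev)]
    return out


def run_from_config(config: AnalysisConfig, outdir=None) -> dict:
    """File-driven entry point used by the command line."""
    if not config.exposure_path or not config.outcome_path:
        raise ConfigurationError("config must set exposure_path and outcome_path")
    exposure = read_summary_table(config.exposure_path, config.column_map,
                                  config.exposure_label)
    outcome = read_summary_table(config.outcome_path, config.column_map,
                                 config.outcome_label)
    third = (read_summary_table(config.third_trait_path, config.column_map, "third_trait")
             if config.third_trait_path else None)
    ld = LDMatrix.from_tsv(config.ld_path) if config.ld_path else None
    proxy = None
    if config.proxy_path:
        pt = pd.read_csv(config.proxy_path, sep="\t")
        proxy = dict(zip(pt.iloc[:, 0].astype(str), pt.iloc[:, 1].astype(str)))
    result = run_bidirectional(config, exposure, outcome, third,
                               ld_forward=ld, ld_reverse=ld, proxy_table=proxy)
    if outdir is not None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("forward", "reverse"):
            if result[key] is not None:
                result[key].write(outdir)
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"verdict": result["verdict"],
                       "forward_significant": result["forward"].significant
                       if result["forward"] else None,
                       "reverse_significant": result["reverse"].significant
                       if result["reverse"] else None,
                       "version": __version__}, fh, indent=2)
    return result
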