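"""Batch orchestration across exposures and the candidate decision rule.

For every exposure the pipeline runs instrument selection, harmonization
against the outcome, the five estimators, and the sensitivity layer, then
applies the screening rule: an exposure is a *candidate* causal feature when
its IVW p-value is nominally significant (p < 0.05), at least three of the
five models are significant with IVW among them, and all five effect
estimates share a sign.  A Bonferroni threshold alpha / M (M = number of
exposures screened) marks the strong-evidence tier.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .exceptions import AnalysisError, InputError
from .instruments import (DEFAULT_MAX_IV, DEFAULT_MIN_IV, DEFAULT_P_THRESHOLD,
                          DEFAULT_R2_CUTOFF, DEFAULT_WINDOW_KB,
                          FilterTrace, read_exclusion_list, select_instruments)
from .io import (HarmonizedSet, LDPanel, SummaryTable, harmonize,
                 read_ld_panel, read_summary_stats)
from .sensitivity import SensitivityReport, sensitivity_report

log = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Multiple-testing adjusted p-value threshold alpha / m_tests."""
    if m_tests < 1:
        raise InputError(f"m_tests must be >= 1, got {m_tests}")
    return alpha / m_tests


def percent_risk_change(beta: float) -> float:
    """Percent change in odds per 1-SD exposure increase: (e^beta - 1) * 100."""
    return (np.exp(beta) - 1.0) * 100.0


@dataclass
class AnalysisConfig:
    """All tunable settings of a batch run; defaults are the screen's."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_cutoff: float = DEFAULT_R2_CUTOFF
    window_kb: float = DEFAULT_WINDOW_KB
    min_iv: int = DEFAULT_MIN_IV
    max_iv: int = DEFAULT_MAX_IV
    cross_exposure_min: int = 2
    palindromic_policy: str = "infer"
    maf_infer_threshold: float = 0.42
    alpha: float = 0.05
    bonferroni_m: int | None = None  # default: number of exposures supplied
    n_boot: int = 1000
    phi: float = 1.0
    presso_n_sim: int = 1000
    variance_model: str = "multiplicative_random"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class DecisionRecord:
    """Per-exposure multi-model summary and candidate flags."""

    exposure_id: str
    n_snp: int
    results: dict[str, est.MRResult]
    bonferroni_significant: bool
    nominal: bool
    n_models_significant: int
    directions_consistent: bool
    candidate: bool
    sensitivity: SensitivityReport | None = None

    @property
    def ivw(self) -> est.MRResult:
        return self.results[est.METHOD_IVW]


def decide_candidate(results: Mapping[str, est.MRResult],
                     alpha: float = 0.05,
                     bonferroni_p: float | None = None,
                     exposure_id: str = "") -> DecisionRecord:
    """Apply the multi-model candidate rule to one exposure's five results.

    candidate <=> IVW p < alpha, >= 3 of the 5 models with p < alpha
    (IVW among them), and all five betas sharing a sign.
    """
    missing = [m for m in est.ALL_METHODS if m not in results]
    if missing:
        raise InputError(f"missing method results: {missing}")
    n_snps = {results[m].n_snp for m in est.ALL_METHODS}
    if len(n_snps) != 1:
        raise InputError(f"methods disagree on n_snp: {sorted(n_snps)}")
    betas = np.array([results[m].beta for m in est.ALL_METHODS])
    pvals = np.array([results[m].pval for m in est.ALL_METHODS])
    ivw_p = results[est.METHOD_IVW].pval
    nominal = bool(ivw_p < alpha)
    n_sig = int((pvals < alpha).sum())
    consistent = bool(np.all(betas > 0) or np.all(betas < 0))
    candidate = nominal and n_sig >= 3 and consistent
    bonf = bool(bonferroni_p is not None and ivw_p < bonferroni_p)
    return DecisionRecord(exposure_id, n_snps.pop(), dict(results), bonf,
                          nominal, n_sig, consistent, candidate)


@dataclass
class BatchResult:
    records: list[DecisionRecord]          # sorted by IVW p ascending
    sensitivity: dict[str, SensitivityReport]
    traces: dict[str, FilterTrace]
    skipped: list[tuple[str, str]]         # (exposure_id, reason)
    harmonized: dict[str, HarmonizedSet]
    bonferroni_p: float

    @property
    def candidates(self) -> list[DecisionRecord]:
        return [r for r in self.records if r.candidate]


def run_batch(exposures: Sequence[SummaryTable],
              outcome: SummaryTable,
              panel: LDPanel | None = None,
              exclusion: Sequence[str] = (),
              config: AnalysisConfig | None = None) -> BatchResult:
    """Run the whole screen over every exposure; failures are skipped, not fatal."""
    if not exposures:
        raise InputError("need at least one exposure table")
    cfg = config or AnalysisConfig()
    exposures = sorted(exposures, key=lambda t: t.trait_id)
    by_id = {t.trait_id: t for t in exposures}
    m = cfg.bonferroni_m if cfg.bonferroni_m is not None else len(exposures)
    bonf_p = bonferroni_threshold(cfg.alpha, m)

    kept, traces, removed = select_instruments(
        exposures, panel=panel, exclusion=exclusion,
        p_threshold=cfg.p_threshold, r2_cutoff=cfg.r2_cutoff,
        window_kb=cfg.window_kb, min_iv=cfg.min_iv, max_iv=cfg.max_iv,
        cross_exposure_min=cfg.cross_exposure_min)
    skipped = [(eid, reason) for eid, reason in sorted(removed.items())]

    records: list[DecisionRecord] = []
    sens: dict[str, SensitivityReport] = {}
    harmonized: dict[str, HarmonizedSet] = {}
    for k, (eid, iset) in enumerate(sorted(kept.items())):
        sub_seed = int(np.random.SeedSequence(
            [cfg.seed, k]).generate_state(1)[0] % 2**31)
        try:
            h = harmonize(by_id[eid].subset(iset.snp_ids), outcome,
                          palindromic_policy=cfg.palindromic_policy,
                          maf_infer_threshold=cfg.maf_infer_threshold)
            if h.n_snp < max(3, cfg.min_iv):
                skipped.append((eid, f"only {h.n_snp} instruments after "
                                     "harmonization"))
                continue
            results = est.run_all(h, n_boot=cfg.n_boot, phi=cfg.phi,
                                  seed=sub_seed,
                                  variance_model=cfg.variance_model)
            record = decide_candidate(results, alpha=cfg.alpha,
                                      bonferroni_p=bonf_p, exposure_id=eid)
            record.sensitivity = sensitivity_report(
                h, presso_n_sim=cfg.presso_n_sim, seed=sub_seed,
                variance_model=cfg.variance_model)
        except AnalysisError as err:
            log.warning("skipping %s: %s", eid, err)
            skipped.append((eid, str(err)))
            continue
        harmonized[eid] = h
        sens[eid] = record.sensitivity
        records.append(record)

    records.sort(key=lambda r: (r.ivw.pval, r.exposure_id))
    return BatchResult(records, sens, traces, sorted(skipped), harmonized,
                       bonf_p)


# ---------------------------------------------------------------------------
# report tables (master results, candidate detail, sensitivity, skip log)
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    return f"{p:.2E}"


def _fmt_or_ci(r: est.MRResult) -> str:
    return f"{r.or_:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"


def results_table(batch: BatchResult) -> pd.DataFrame:
    """Master table sorted by IVW p: one row per exposure (IVW summary)."""
    rows = []
    for rec in batch.records:
        r = rec.ivw
        rows.append({
            "Metabolite": rec.exposure_id,
            "nSNP": rec.n_snp,
            "Beta": f"{r.beta:.2f}",
            "SE": f"{r.se:.2f}",
            "P": _fmt_p(r.pval),
            "OR (95%CI)": _fmt_or_ci(r),
            "Candidate": rec.candidate,
            "BonferroniSignificant": rec.bonferroni_significant,
        })
    return pd.DataFrame(rows)


def candidates_table(batch: BatchResult) -> pd.DataFrame:
    """Five rows (one per method) for each candidate exposure."""
    rows = []
    for rec in batch.candidates:
        s = batch.sensitivity.get(rec.exposure_id)
        for method in (est.METHOD_EGGER, est.METHOD_WMEDIAN, est.METHOD_IVW,
                       est.METHOD_SMODE, est.METHOD_WMODE):
            r = rec.results[method]
            row = {"Metabolite": rec.exposure_id, "Method": method,
                   "nSNP": r.n_snp, "P": _fmt_p(r.pval),
                   "OR (95%CI)": _fmt_or_ci(r),
                   "P_Heterogeneity": "", "P_HorizontalPleiotropy": ""}
            if s is not None:
                if method == est.METHOD_EGGER and s.q_egger is not None:
                    row["P_Heterogeneity"] = f"{s.q_egger.pval:.2f}"
                    if s.egger_intercept is not None:
                        row["P_HorizontalPleiotropy"] = \
                            f"{s.egger_intercept.pval:.2f}"
                elif method == est.METHOD_IVW:
                    row["P_Heterogeneity"] = f"{s.q_ivw.pval:.2f}"
            rows.append(row)
    return pd.DataFrame(rows, columns=["Metabolite", "Method", "nSNP", "P",
                                       "OR (95%CI)", "P_Heterogeneity",
                                       "P_HorizontalPleiotropy"])


def sensitivity_table(batch: BatchResult) -> pd.DataFrame:
    rows = []
    for rec in batch.records:
        s = batch.sensitivity.get(rec.exposure_id)
        if s is None:
            continue
        rows.append({
            "Metabolite": rec.exposure_id,
            "Q_IVW": f"{s.q_ivw.Q:.3f}",
            "P_Q_IVW": _fmt_p(s.q_ivw.pval),
            "Q_Egger": f"{s.q_egger.Q:.3f}" if s.q_egger else "",
            "P_Q_Egger": _fmt_p(s.q_egger.pval) if s.q_egger else "",
            "EggerIntercept": f"{s.egger_intercept.intercept:.4f}"
                              if s.egger_intercept else "",
            "P_Intercept": _fmt_p(s.egger_intercept.pval)
                           if s.egger_intercept else "",
            "P_PRESSO_Global": _fmt_p(s.presso.global_pval) if s.presso else "",
            "PRESSO_Outliers": ";".join(s.presso.outlier_snp_ids)
                               if s.presso else "",
            "HeterogeneityOK": s.heterogeneity_ok,
            "PleiotropyOK": s.pleiotropy_ok,
            "LOOStable": s.loo_stable,
        })
    return pd.DataFrame(rows)


def export_figure_data(batch: BatchResult, out_dir, exposures=None) -> None:
    """Per-exposure scatter/fit/forest/funnel data files (plot-ready TSVs)."""
    os.makedirs(out_dir, exist_ok=True)
    which = exposures if exposures is not None else \
        [r.exposure_id for r in batch.candidates]
    for eid in which:
        h = batch.harmonized.get(eid)
        rec = next((r for r in batch.records if r.exposure_id == eid), None)
        if h is None or rec is None:
            continue
        scatter = h.df[["snp_id", "gamma", "sigma_x", "Gamma", "sigma_y"]]
        scatter.to_csv(os.path.join(out_dir, f"{eid}_scatter.tsv"),
                       sep="\t", index=False)
        fits = pd.DataFrame(
            [{"method": m, "intercept": r.extra.get("intercept", 0.0),
              "slope": r.beta} for m, r in rec.results.items()])
        fits.to_csv(os.path.join(out_dir, f"{eid}_fits.tsv"),
                    sep="\t", index=False)
        theta = h.Gamma / h.gamma
        se = h.sigma_y / np.abs(h.gamma)
        funnel = pd.DataFrame({"snp_id": h.snp_ids, "theta": theta,
                               "se": se, "precision": 1.0 / se})
        funnel.to_csv(os.path.join(out_dir, f"{eid}_funnel.tsv"),
                      sep="\t", index=False)
        s = batch.sensitivity.get(eid)
        if s is not None and s.loo is not None:
            s.loo.table.to_csv(os.path.join(out_dir, f"{eid}_forest.tsv"),
                               sep="\t", index=False)


def write_outputs(batch: BatchResult, out_dir) -> None:
    """Write results.tsv, candidates.tsv, sensitivity.tsv, skipped.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    results_table(batch).to_csv(os.path.join(out_dir, "results.tsv"),
                                sep="\t", index=False)
    candidates_table(batch).to_csv(os.path.join(out_dir, "candidates.tsv"),
                                   sep="\t", index=False)
    sensitivity_table(batch).to_csv(os.path.join(out_dir, "sensitivity.tsv"),
                                    sep="\t", index=False)
    pd.DataFrame(batch.skipped, columns=["Metabolite", "Reason"]).to_csv(
        os.path.join(out_dir, "skipped.tsv"), sep="\t", index=False)
    export_figure_data(batch, os.path.join(out_dir, "figures"))


# ---------------------------------------------------------------------------
# study loading (file dialects of metabmr.io)
# ---------------------------------------------------------------------------

def load_study(config_path):
    """Load a batch study described by a YAML config (paths + thresholds).

    Keys: ``exposures_dir`` (directory of per-exposure summary files),
    ``outcome`` (file), optional ``ld_panel`` (pairwise file), optional
    ``exclusion`` (SNP list), plus any :class:`AnalysisConfig` field.
    Relative paths resolve against the config file's directory.
    """
    base = os.path.dirname(os.path.abspath(str(config_path)))
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)

    def _resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    exp_dir = _resolve(raw["exposures_dir"])
    exposures = [read_summary_stats(os.path.join(exp_dir, f),
                                    trait_role="exposure")
                 for f in sorted(os.listdir(exp_dir))
                 if f.endswith((".tsv", ".csv", ".txt"))]
    outcome = read_summary_stats(_resolve(raw["outcome"]), trait_role="outcome")
    panel = read_ld_panel(_resolve(raw["ld_panel"])) if raw.get("ld_panel") else None
    exclusion = read_exclusion_list(_resolve(raw["exclusion"])) \
        if raw.get("exclusion") else []
    cfg = AnalysisConfig.from_dict(raw)
    return exposures, outcome, panel, exclusion, cfg
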