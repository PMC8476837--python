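"""Heterogeneity, pleiotropy, outlier, and leave-one-out diagnostics.

The verdict flags mirror the screening rules used for metabolite-disease
candidates: heterogeneity is declared absent when Cochran's Q has P > 0.05
(for both the IVW and Egger fits), horizontal pleiotropy is declared absent
when the Egger intercept has |intercept| < 0.1 and P > 0.05, and the
leave-one-out analysis is stable when every reduced-set IVW confidence
interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, ivw, mr_egger
from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .io import HarmonizedSet

DEFAULT_INTERCEPT_CUT = 0.1
DEFAULT_PRESSO_NSIM = 1000
DEFAULT_OUTLIER_ALPHA = 0.05
DEFAULT_DISTORTION_DRAWS = 1000


class QResult(NamedTuple):
    Q: float
    df: int
    pval: float


class InterceptTest(NamedTuple):
    intercept: float
    se: float
    pval: float
    pleiotropy_ok: bool


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    rss_obs: float
    global_pval: float
    outlier_snp_ids: list[str]
    outlier_pvals: dict[str, float]  # Bonferroni-adjusted, per SNP
    distortion_pval: float | None
    beta_all: float
    beta_outlier_free: float | None
    n_sim: int


@dataclass
class LOOResult:
    table: pd.DataFrame  # snp_id, beta, se, pval, ci_low, ci_high, ci_excludes_zero
    loo_stable: bool
    sensitive_snps: list[str]


@dataclass
class SensitivityReport:
    """All §sensitivity diagnostics for one exposure-outcome pair."""

    exposure_id: str
    q_ivw: QResult
    q_egger: QResult | None
    egger_intercept: InterceptTest | None
    presso: PressoResult | None
    loo: LOOResult | None
    heterogeneity_ok: bool = field(default=False)
    pleiotropy_ok: bool = field(default=False)
    loo_stable: bool = field(default=False)


def cochran_q(h: HarmonizedSet, model: str = "ivw") -> QResult:
    """Cochran's Q heterogeneity statistic for the IVW or Egger fit.

    ``Q = sum_j w_j (theta_j - fitted_j)^2`` with ``w_j = gamma_j^2 /
    sigma_Yj^2``; df is J-1 (IVW) or J-2 (Egger, fitted from the
    free-intercept model on oriented data); p comes from the chi-squared
    upper tail.
    """
    J = h.n_snp
    if model == "ivw":
        if J < 2:
            raise InsufficientInstrumentsError("Q(IVW) needs >= 2 instruments")
        res = ivw(h)
        Q, df = res.extra["Q"], J - 1
    elif model == "egger":
        if J < 3:
            raise InsufficientInstrumentsError("Q(Egger) needs >= 3 instruments")
        res = mr_egger(h)
        Q, df = res.extra["Q"], J - 2
    else:
        raise ConfigurationError(f"unknown Q model {model!r}")
    return QResult(float(Q), df, float(stats.chi2.sf(Q, df)))


def egger_intercept_test(h: HarmonizedSet,
                         intercept_magnitude_cut: float = DEFAULT_INTERCEPT_CUT
                         ) -> InterceptTest:
    """Directional-pleiotropy test on the MR-Egger intercept.

    ``pleiotropy_ok`` requires both ``|intercept| < cut`` (strict) and
    intercept P > 0.05.
    """
    res = mr_egger(h)
    b0 = res.extra["intercept"]
    p0 = res.extra["intercept_pval"]
    ok = (abs(b0) < intercept_magnitude_cut) and (p0 > 0.05)
    return InterceptTest(b0, res.extra["intercept_se"], p0, ok)


def _loo_slopes(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes from per-SNP weighted numerators/denominators."""
    return (num.sum(axis=-1, keepdims=True) - num) / \
           (den.sum(axis=-1, keepdims=True) - den)


def mr_presso(h: HarmonizedSet, n_sim: int = DEFAULT_PRESSO_NSIM,
              outlier_alpha: float = DEFAULT_OUTLIER_ALPHA, seed: int = 0,
              n_distortion: int = DEFAULT_DISTORTION_DRAWS) -> PressoResult:
    """Simulation-based residual-sum-of-squares pleiotropy and outlier test.

    Global test: the observed ``RSS = sum_j w_j (Gamma_j - slope_{-j}
    gamma_j)^2`` (slope_{-j} = leave-one-out IVW slope) is referred to its
    distribution over ``n_sim`` datasets simulated from the no-pleiotropy
    model (``Gamma* ~ N(slope_{-j} gamma_j, sigma_Yj^2)``, ``gamma* ~
    N(gamma_j, sigma_Xj^2)``).  Outlier test: each SNP's observed weighted
    squared residual against its simulated distribution, Bonferroni-adjusted
    over J.  Distortion test: the IVW shift after outlier removal against
    shifts from random same-size removals.  Empirical p-values use the
    (1+k)/(1+n) correction.
    """
    J = h.n_snp
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {J}")
    if n_sim < 100:
        raise ConfigurationError("MR-PRESSO needs n_sim >= 100")
    g, G, sx, sy = h.gamma, h.Gamma, h.sigma_x, h.sigma_y
    inv_sy2 = 1.0 / sy ** 2
    num, den = g * G * inv_sy2, g ** 2 * inv_sy2
    slope_loo = _loo_slopes(num, den)
    w = g ** 2 * inv_sy2
    resid_obs = w * (G - slope_loo * g) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    Gs = rng.normal(slope_loo * g, sy, size=(n_sim, J))
    gs = rng.normal(g, sx, size=(n_sim, J))
    nums, dens = gs * Gs * inv_sy2, gs ** 2 * inv_sy2
    slopes = _loo_slopes(nums, dens)
    resid_sim = (gs ** 2 * inv_sy2) * (Gs - slopes * gs) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))

    p_raw = (1 + (resid_sim >= resid_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * J)
    snp_ids = np.asarray(h.snp_ids)
    out_mask = p_adj < outlier_alpha
    outliers = [str(s) for s in snp_ids[out_mask]]
    outlier_pvals = {str(s): float(p) for s, p in zip(snp_ids, p_adj)}

    beta_all = float(num.sum() / den.sum())
    beta_free, distortion_p = None, None
    k = int(out_mask.sum())
    if k and J - k >= 2:
        keep = ~out_mask
        beta_free = float(num[keep].sum() / den[keep].sum())
        d_obs = beta_free - beta_all
        d_rand = np.empty(n_distortion)
        for i in range(n_distortion):
            drop = rng.choice(J, size=k, replace=False)
            m = np.ones(J, dtype=bool)
            m[drop] = False
            d_rand[i] = num[m].sum() / den[m].sum() - beta_all
        distortion_p = float((1 + (np.abs(d_rand) >= abs(d_obs)).sum())
                             / (n_distortion + 1))
    return PressoResult(rss_obs, global_p, outliers, outlier_pvals,
                        distortion_p, beta_all, beta_free, n_sim)


def leave_one_out(h: HarmonizedSet,
                  variance_model: str = "multiplicative_random") -> LOOResult:
    """IVW on each J-1 subset; a row is sensitive when its CI includes zero.

    ``loo_stable`` is true when every reduced-set 95% CI excludes zero (the
    forest plot's "error lines do not pass through 0" rule).
    """
    J = h.n_snp
    if J < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs >= 3 instruments, got {J}")
    rows = []
    for j in range(J):
        mask = np.ones(J, dtype=bool)
        mask[j] = False
        res = ivw(h.subset(mask), variance_model=variance_model)
        lo, hi = res.beta - Z95 * res.se, res.beta + Z95 * res.se
        rows.append({"snp_id": h.snp_ids[j], "beta": res.beta, "se": res.se,
                     "pval": res.pval, "ci_low": lo, "ci_high": hi,
                     "ci_excludes_zero": bool(lo > 0 or hi < 0)})
    table = pd.DataFrame(rows)
    stable = bool(table["ci_excludes_zero"].all())
    sensitive = list(table.loc[~table["ci_excludes_zero"], "snp_id"])
    return LOOResult(table, stable, sensitive)


def sensitivity_report(h: HarmonizedSet,
                       presso_n_sim: int = DEFAULT_PRESSO_NSIM,
                       outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
                       intercept_cut: float = DEFAULT_INTERCEPT_CUT,
                       seed: int = 0,
                       variance_model: str = "multiplicative_random"
                       ) -> SensitivityReport:
    """Run every diagnostic that the instrument count permits."""
    q_ivw = cochran_q(h, "ivw")
    q_egger = cochran_q(h, "egger") if h.n_snp >= 3 else None
    intercept = egger_intercept_test(h, intercept_cut) if h.n_snp >= 3 else None
    presso = mr_presso(h, n_sim=presso_n_sim, outlier_alpha=outlier_alpha,
                       seed=seed) if h.n_snp >= 4 else None
    loo = leave_one_out(h, variance_model) if h.n_snp >= 3 else None
    het_ok = q_ivw.pval > 0.05 and (q_egger is None or q_egger.pval > 0.05)
    return SensitivityReport(
        exposure_id=h.exposure_id,
        q_ivw=q_ivw, q_egger=q_egger, egger_intercept=intercept,
        presso=presso, loo=loo,
        heterogeneity_ok=bool(het_ok),
        pleiotropy_ok=bool(intercept.pleiotropy_ok) if intercept else False,
        loo_stable=bool(loo.loo_stable) if loo else False,
    )
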