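"""The five causal-effect estimators for two-sample MR summary data.

Each instrument j contributes a Wald ratio theta_j = Gamma_j / gamma_j (SNP-
outcome effect over SNP-exposure effect, log-odds per SD for a binary
outcome) with first-order standard error sigma_Yj / |gamma_j| and inverse-
variance weight w_j = gamma_j^2 / sigma_Yj^2.  The estimators combine the
ratios under different identifying assumptions:

* IVW           - weighted mean of ratios; all instruments valid.
* MR-Egger      - weighted regression of Gamma on gamma with a free
                  intercept; valid under InSIDE, the intercept measures
                  average directional pleiotropy.
* Weighted median - median of the weighted empirical ratio distribution;
                  consistent when valid instruments carry >50% of the weight.
* Simple / weighted mode - kernel-density mode of the ratios; consistent
                  under the zero-modal-pleiotropy assumption (ZEMPA).

IVW and Egger standard errors use a multiplicative random-effects model by
default, with the residual dispersion floored at 1 so underdispersion is not
credited.  Median and mode standard errors come from a seeded parametric
bootstrap that resamples theta_j ~ Normal(theta_j, se_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, sqrt

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .io import HarmonizedSet

Z95 = 1.96

METHOD_IVW = "IVW"
METHOD_EGGER = "MR Egger"
METHOD_WMEDIAN = "Weighted median"
METHOD_SMODE = "Simple mode"
METHOD_WMODE = "Weighted mode"
ALL_METHODS = (METHOD_IVW, METHOD_EGGER, METHOD_WMEDIAN, METHOD_SMODE,
               METHOD_WMODE)


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and inverse-variance weight."""

    snp_id: str
    theta: float
    se: float
    weight: float


@dataclass
class MRResult:
    """One estimator's causal estimate on the log-odds-per-SD scale.

    ``or_`` and the CI bounds are exponentials of ``beta`` and
    ``beta -/+ 1.96 * se``, computed on access so the identity holds exactly.
    """

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return exp(self.beta)

    @property
    def ci_low(self) -> float:
        return exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return exp(self.beta + Z95 * self.se)


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _pval(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return _two_sided_normal_p(beta / se)


def wald_ratio(gamma: float, sigma_x: float, Gamma: float, sigma_y: float,
               snp_id: str = "") -> RatioEstimate:
    """Single-SNP causal ratio Gamma/gamma with first-order SE sigma_y/|gamma|."""
    if gamma == 0:
        raise UndefinedRatioError(f"zero exposure effect for {snp_id or 'SNP'}")
    se = sigma_y / abs(gamma)
    return RatioEstimate(snp_id, Gamma / gamma, se, 1.0 / se ** 2)


def _ratio_arrays(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(theta, se, weight) arrays; raises on any zero gamma."""
    g, G, sy = h.gamma, h.Gamma, h.sigma_y
    if np.any(g == 0):
        bad = np.asarray(h.snp_ids)[g == 0][0]
        raise UndefinedRatioError(f"zero exposure effect for {bad}")
    theta = G / g
    se = sy / np.abs(g)
    return theta, se, 1.0 / se ** 2


def ivw(h: HarmonizedSet,
        variance_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted estimate, the primary MR model.

    ``beta`` is the weighted mean of the Wald ratios (equivalently the
    zero-intercept weighted regression of Gamma on gamma).  Under
    ``multiplicative_random`` the fixed-effect SE is inflated by
    ``max(1, phi-hat)`` with ``phi-hat^2 = Q / (J - 1)``.
    """
    J = h.n_snp
    if J < 2:
        raise InsufficientInstrumentsError(f"IVW needs >= 2 instruments, got {J}")
    theta, _, w = _ratio_arrays(h)
    wsum = w.sum()
    beta = float((w * theta).sum() / wsum)
    se_fixed = float(wsum ** -0.5)
    Q = float((w * (theta - beta) ** 2).sum())
    phi2 = Q / (J - 1)
    if variance_model == "fixed":
        se = se_fixed
    elif variance_model == "multiplicative_random":
        se = se_fixed * max(1.0, sqrt(phi2))
    else:
        raise ValueError(f"unknown variance model {variance_model!r}")
    return MRResult(METHOD_IVW, J, beta, se, _pval(beta, se),
                    extra={"Q": Q, "Q_df": J - 1, "phi2": phi2,
                           "se_fixed": se_fixed, "variance_model": variance_model})


def _orient(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jointly negate (gamma, Gamma) so that every gamma >= 0."""
    sign = np.where(h.gamma < 0, -1.0, 1.0)
    return h.gamma * sign, h.Gamma * sign, h.sigma_y


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of Gamma on gamma with free intercept.

    Instruments are first oriented so every gamma >= 0 (the estimate must not
    depend on arbitrary allele orientation).  The slope is the causal
    estimate; the intercept, stored in ``extra``, measures average
    directional pleiotropy.  SEs carry a ``max(1, phi-hat)`` dispersion
    inflation with ``phi-hat^2 = Q' / (J - 2)`` and p-values use the t
    distribution with J - 2 df.
    """
    J = h.n_snp
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {J}")
    g, G, sy = _orient(h)
    w = 1.0 / sy ** 2
    fit = sm.WLS(G, sm.add_constant(g), weights=w).fit()
    b0, b1 = (float(v) for v in fit.params)
    phi2 = float(fit.scale)  # weighted RSS / (J - 2) = Q' / (J - 2)
    cov = np.asarray(fit.normalized_cov_params) * max(1.0, phi2)
    se0, se1 = (float(sqrt(v)) for v in np.diag(cov))
    df = J - 2
    p1 = float(2 * stats.t.sf(abs(b1 / se1), df)) if se1 > 0 else 0.0
    p0 = float(2 * stats.t.sf(abs(b0 / se0), df)) if se0 > 0 else 0.0
    return MRResult(METHOD_EGGER, J, b1, se1, p1,
                    extra={"intercept": b0, "intercept_se": se0,
                           "intercept_pval": p0, "Q": phi2 * df, "Q_df": df,
                           "phi2": phi2})


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated median of the weighted empirical distribution of ratios."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    ww = w[order] / w[order].sum()
    p = np.cumsum(ww) - ww / 2.0
    return float(np.interp(0.5, p, t))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted-median estimate; robust to <50% invalid weight.

    The SE is the standard deviation of the estimate over ``n_boot``
    parametric-bootstrap replicates (theta_j resampled from
    Normal(theta_j, se_j), weights held fixed).
    """
    J = h.n_snp
    if J < 2:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 2 instruments, got {J}")
    theta, se_j, w = _ratio_arrays(h)
    beta = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_j, size=(n_boot, J))
    boots = np.array([_weighted_median(d, w) for d in draws])
    se = float(boots.std(ddof=1))
    return MRResult(METHOD_WMEDIAN, J, beta, se, _pval(beta, se),
                    extra={"n_boot": n_boot})


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, a: float, b: float, n_iter: int = 60) -> float:
    """Golden-section maximization of a unimodal f on [a, b]."""
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _kde_mode(theta: np.ndarray, w: np.ndarray,
              phi: float) -> tuple[float, float]:
    """Argmax of a Gaussian-kernel density over the ratios; returns (mode, h).

    Bandwidth is a robust modified Silverman rule,
    ``h = phi * 1.06 * s * J^(-1/5)`` with ``s = min(sd, 1.4826 * MAD)``
    (a zero robust scale falls back to the other; all-equal ratios return
    that value directly).  The argmax is located on a 512-point grid over
    ``[min - 3h, max + 3h]`` and refined by golden-section search; grid ties
    resolve toward the smallest theta.
    """
    J = len(theta)
    sd = float(np.std(theta, ddof=1)) if J > 1 else 0.0
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return float(theta[0]), 0.0
    s = min(scales)
    bw = phi * 1.06 * s * J ** (-1.0 / 5.0)
    wn = w / w.sum()

    def density(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - theta[None, :]) / bw
        return (wn[None, :] * np.exp(-0.5 * z ** 2)).sum(axis=1)

    grid = np.linspace(theta.min() - 3 * bw, theta.max() + 3 * bw, 512)
    dens = density(grid)
    i = int(np.argmax(dens))  # first maximum = smallest theta on ties
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    mode = _golden_max(lambda x: float(density(x)[0]), float(a), float(b))
    return float(mode), float(bw)


def _mode_estimate(h: HarmonizedSet, weighted: bool, phi: float,
                   n_boot: int, seed: int, method: str) -> MRResult:
    J = h.n_snp
    if J < 3:
        raise InsufficientInstrumentsError(
            f"{method} needs >= 3 instruments, got {J}")
    theta, se_j, w_iv = _ratio_arrays(h)
    w = w_iv if weighted else np.ones(J)
    beta, bw = _kde_mode(theta, w, phi)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_j, size=(n_boot, J))
    boots = np.array([_kde_mode(d, w, phi)[0] for d in draws])
    se = float(boots.std(ddof=1))
    return MRResult(method, J, beta, se, _pval(beta, se),
                    extra={"bandwidth": bw, "phi": phi, "n_boot": n_boot})


def simple_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Unweighted mode-based estimate (largest cluster of similar ratios)."""
    return _mode_estimate(h, weighted=False, phi=bandwidth_factor,
                          n_boot=n_boot, seed=seed, method=METHOD_SMODE)


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Mode-based estimate with kernels scaled by inverse-variance weight."""
    return _mode_estimate(h, weighted=True, phi=bandwidth_factor,
                          n_boot=n_boot, seed=seed, method=METHOD_WMODE)


def run_all(h: HarmonizedSet, n_boot: int = 1000, phi: float = 1.0,
            seed: int = 0,
            variance_model: str = "multiplicative_random"
            ) -> dict[str, MRResult]:
    """All five estimators on one harmonized set, bootstrap seeds decoupled."""
    seeds = [int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)
             for k in range(3)]
    return {
        METHOD_IVW: ivw(h, variance_model=variance_model),
        METHOD_EGGER: mr_egger(h),
        METHOD_WMEDIAN: weighted_median(h, n_boot=n_boot, seed=seeds[0]),
        METHOD_SMODE: simple_mode(h, bandwidth_factor=phi, n_boot=n_boot,
                                  seed=seeds[1]),
        METHOD_WMODE: weighted_mode(h, bandwidth_factor=phi, n_boot=n_boot,
                                    seed=seeds[2]),
    }
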