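"""Univariable two-sample MR estimators on a harmonized variant set.

Implements the Wald ratio, inverse-variance weighted (IVW) meta-analysis
with fixed or multiplicative random effects, the weighted median with a
parametric bootstrap SE, and MR-Egger regression with its pleiotropy
intercept, plus Cochran's Q heterogeneity and unit-rescaling helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DataError, EstimationError
from .harmonize import HarmonizedSet

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "mr_egger",
    "cochran_q",
    "rescale_estimate",
    "to_odds_ratio",
]

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty and heterogeneity metadata.

    ``beta`` is on the log-odds (binary outcome) or outcome-unit scale per
    exposure unit; ``dispersion`` is the multiplicative overdispersion
    factor actually applied to the SE (1 under fixed effects).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q: float = float("nan")
    q_df: int = 0
    q_pvalue: float = float("nan")
    dispersion: float = 1.0
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    exposure_unit: str = "per_sd"
    seed: int | None = None
    n_boot: int | None = None
    exposure_id: str = ""
    outcome_id: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise EstimationError("estimate SE must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimationError("CI must bracket the point estimate")
        if self.dispersion < 1.0 - 1e-12:
            raise EstimationError("dispersion must be >= 1")

    def odds_ratio(self) -> tuple[float, float, float]:
        """Exponentiate the estimate and its normal 95% CI."""
        return (math.exp(self.beta), math.exp(self.ci_low),
                math.exp(self.ci_high))


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _finish(method: str, beta: float, se: float, n_snps: int, **kw) -> MREstimate:
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        pvalue=_normal_p(beta / se), n_snps=n_snps, **kw)


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               **meta) -> MREstimate:
    """Single-SNP causal estimate: ``beta_y / beta_x``.

    The SE uses the first-order delta method, ``se_y / |beta_x|``,
    ignoring the uncertainty of the SNP-exposure association.
    """
    if beta_x == 0:
        raise EstimationError("undefined ratio: beta_x = 0")
    if se_y <= 0:
        raise EstimationError("se_y must be positive")
    return _finish("wald", beta_y / beta_x, se_y / abs(beta_x), 1, **meta)


def ivw(hset: HarmonizedSet, effects: str = "multiplicative_random",
        **meta) -> MREstimate:
    """Inverse-variance weighted estimate over the Wald ratios.

    With weights ``w = 1/se_y^2``: ``theta = sum(w bx by) / sum(w bx^2)``;
    the fixed-effect SE is ``(sum w bx^2)^(-1/2)``.  Under multiplicative
    random effects the SE is inflated by ``sqrt(phi)`` with
    ``phi = max(1, Q/(L-1))`` so it never shrinks below the fixed-effect SE.
    A single retained variant reduces to the Wald ratio.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown effects {effects!r}")
    L = hset.n_snps
    if L == 0:
        raise EstimationError("empty harmonized set")
    meta.setdefault("exposure_id", hset.exposure_id)
    meta.setdefault("outcome_id", hset.outcome_id)
    if L == 1:
        v = hset.variants[0]
        est = wald_ratio(v.beta_x, v.se_x, v.beta_y, v.se_y, **meta)
        return replace(est, method="ivw_mre" if effects == "multiplicative_random"
                       else "ivw_fixed", dispersion=1.0)
    bx, by, sy = hset.beta_x, hset.beta_y, hset.se_y
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    if denom <= 0:
        raise EstimationError("all beta_x are zero")
    theta = float(np.sum(w * bx * by) / denom)
    se_fixed = float(denom ** -0.5)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    q_df = L - 1
    q_p = float(stats.chi2.sf(q, q_df))
    if effects == "multiplicative_random":
        phi = max(1.0, q / q_df)
        return _finish("ivw_mre", theta, se_fixed * math.sqrt(phi), L,
                       q=q, q_df=q_df, q_pvalue=q_p, dispersion=phi, **meta)
    return _finish("ivw_fixed", theta, se_fixed, L,
                   q=q, q_df=q_df, q_pvalue=q_p, dispersion=1.0, **meta)


def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted median via linear interpolation of the standardized
    cumulative weight ``s_k = (cum_k - w_k/2) / sum(w)`` at s = 0.5.

    Works on 1-D inputs or batched 2-D inputs (rows are replicates).
    """
    ratios = np.atleast_2d(ratios)
    weights = np.atleast_2d(np.broadcast_to(weights, ratios.shape))
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, -1)
    w = np.take_along_axis(weights, order, -1)
    tot = w.sum(axis=-1, keepdims=True)
    s = (np.cumsum(w, axis=-1) - 0.5 * w) / tot
    idx = np.sum(s < 0.5, axis=-1, keepdims=True)  # first index with s >= 0.5
    L = ratios.shape[-1]
    lo = np.clip(idx - 1, 0, L - 1)
    hi = np.clip(idx, 0, L - 1)
    s_lo = np.take_along_axis(s, lo, -1)
    s_hi = np.take_along_axis(s, hi, -1)
    r_lo = np.take_along_axis(r, lo, -1)
    r_hi = np.take_along_axis(r, hi, -1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s_hi > s_lo, (0.5 - s_lo) / (s_hi - s_lo), 0.0)
    return (r_lo + frac * (r_hi - r_lo)).ravel()


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None, **meta) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Consistent when at least 50% of the weight comes from valid
    instruments.  Weights are ``beta_x^2 / se_y^2``; the SE is the standard
    deviation of the estimate over ``n_boot`` parametric-bootstrap
    replicates resampling both the SNP-exposure and SNP-outcome betas.
    An explicit ``seed`` is required for reproducibility.
    """
    L = hset.n_snps
    if L < 3:
        raise EstimationError("weighted median requires at least 3 instruments")
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed")
    bx, sx, by, sy = hset.beta_x, hset.se_x, hset.beta_y, hset.se_y
    if np.any(bx == 0):
        raise EstimationError("beta_x = 0 gives an undefined ratio")
    w = bx**2 / sy**2
    keep = w > 0
    est = float(_weighted_median_core(by[keep] / bx[keep], w[keep])[0])

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, L))
    by_b = rng.normal(by, sy, size=(n_boot, L))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    boots = _weighted_median_core(by_b / bx_b, bx_b**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    if se <= 0:
        se = np.finfo(float).tiny
    meta.setdefault("exposure_id", hset.exposure_id)
    meta.setdefault("outcome_id", hset.outcome_id)
    return _finish("weighted_median", est, se, L, seed=seed, n_boot=n_boot,
                   **meta)


def mr_egger(hset: HarmonizedSet, fit_intercept: bool = True,
             **meta) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure betas.

    Each SNP is first oriented so ``beta_x >= 0``.  The slope estimates the
    causal effect under InSIDE; the intercept estimates average directional
    pleiotropy.  Residual overdispersion ``phi = max(1, Q'/(L-2))`` scales
    both SEs.  ``fit_intercept=False`` gives the nested no-intercept fit,
    which coincides with fixed/multiplicative IVW.
    """
    L = hset.n_snps
    if L < 3:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    sign = np.where(hset.beta_x < 0, -1.0, 1.0)
    bx = hset.beta_x * sign
    by = hset.beta_y * sign
    w = 1.0 / hset.se_y**2
    if fit_intercept and np.ptp(bx) < 1e-14 * max(1.0, np.abs(bx).max()):
        raise EstimationError("slope unidentifiable: no spread in beta_x")
    X = np.column_stack([np.ones(L), bx]) if fit_intercept else bx[:, None]
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    q_df = L - X.shape[1]
    phi = max(1.0, q / q_df) if q_df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * phi
    meta.setdefault("exposure_id", hset.exposure_id)
    meta.setdefault("outcome_id", hset.outcome_id)
    if fit_intercept:
        slope, slope_se = coef[1], math.sqrt(cov[1, 1])
        icpt, icpt_se = float(coef[0]), math.sqrt(cov[0, 0])
        return _finish("egger", slope, slope_se, L, q=q, q_df=q_df,
                       q_pvalue=float(stats.chi2.sf(q, q_df)), dispersion=phi,
                       intercept=icpt, intercept_se=icpt_se,
                       intercept_p=_normal_p(icpt / icpt_se), **meta)
    return _finish("egger_no_intercept", coef[0], math.sqrt(cov[0, 0]), L,
                   q=q, q_df=q_df, q_pvalue=float(stats.chi2.sf(q, q_df)),
                   dispersion=phi, **meta)


def cochran_q(hset: HarmonizedSet, theta: float) -> tuple[float, int, float]:
    """Cochran's Q for heterogeneity around a given causal effect.

    ``Q = sum w (by - theta*bx)^2`` with ``w = 1/se_y^2``; p-value from a
    chi-square with ``L - 1`` degrees of freedom.
    """
    L = hset.n_snps
    if L < 2:
        raise EstimationError("cochran_q requires at least 2 instruments")
    w = 1.0 / hset.se_y**2
    q = float(np.sum(w * (hset.beta_y - theta * hset.beta_x) ** 2))
    df = L - 1
    return q, df, float(stats.chi2.sf(q, df))


def rescale_estimate(est: MREstimate, phenotype_sd: float,
                     target_unit: float) -> MREstimate:
    """Re-express a per-SD estimate per ``target_unit`` raw phenotype units.

    Multiplies the point estimate, SE and CI bounds by
    ``target_unit / phenotype_sd``; the p-value is unchanged.
    """
    if phenotype_sd <= 0 or target_unit <= 0:
        raise DataError("phenotype_sd and target_unit must be positive")
    c = target_unit / phenotype_sd
    return replace(
        est, beta=est.beta * c, se=est.se * c,
        ci_low=est.ci_low * c if c > 0 else est.ci_high * c,
        ci_high=est.ci_high * c,
        exposure_unit=f"per_{target_unit:g}_unit")


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its 95% CI."""
    return est.odds_ratio()
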