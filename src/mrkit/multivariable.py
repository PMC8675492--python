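"""Multivariable MR: joint direct effects of several exposures.

Weighted least squares of outcome betas on a matrix of exposure betas,
with conditional instrument-strength (Sanderson-Windmeijer style) and a
modified Q statistic that propagates exposure-beta uncertainty and the
phenotypic correlation between exposures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DataError, EstimationError
from .estimators import MREstimate, Z95, _normal_p
from .harmonize import (PALINDROMIC_AMBIGUOUS, AlleleMismatch,
                        HarmonizeOptions, align_alleles, classify_palindromic)
from .sumstats import AssociationTable

__all__ = [
    "MVHarmonizedSet",
    "build_mv_set",
    "mv_ivw",
    "mv_egger",
    "conditional_f",
    "modified_q",
]


@dataclass
class MVHarmonizedSet:
    """Variants harmonized across K exposures and one outcome.

    ``beta_x``/``se_x`` have shape (L, K); ``pheno_corr`` is the K x K
    phenotypic correlation matrix among exposures.
    """

    exposure_ids: list[str]
    outcome_id: str
    variant_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    pheno_corr: np.ndarray = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        L, K = self.beta_x.shape
        if self.se_x.shape != (L, K) or len(self.beta_y) != L or len(self.se_y) != L:
            raise DataError("MV set shape mismatch")
        if len(self.exposure_ids) != K:
            raise DataError("exposure_ids length must match beta_x columns")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise DataError("SEs must be positive")
        if self.pheno_corr is None:
            self.pheno_corr = np.eye(K)
        self.pheno_corr = np.asarray(self.pheno_corr, dtype=float)
        if self.pheno_corr.shape != (K, K):
            raise DataError("pheno_corr must be K x K")
        if not np.allclose(self.pheno_corr, self.pheno_corr.T):
            raise DataError("pheno_corr must be symmetric")
        if not np.allclose(np.diag(self.pheno_corr), 1.0):
            raise DataError("pheno_corr diagonal must be 1")
        if np.any(np.abs(self.pheno_corr) > 1 + 1e-12):
            raise DataError("pheno_corr entries must be in [-1, 1]")

    @property
    def n_snps(self) -> int:
        return self.beta_x.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]


def build_mv_set(exposure_tables: list[AssociationTable],
                 outcome: AssociationTable,
                 instrument_lists: list[list[str]] | None = None,
                 pheno_corr=None, ld=None, drop_shared: bool = True,
                 options: HarmonizeOptions | None = None) -> MVHarmonizedSet:
    """Assemble a multivariable harmonized set from per-exposure tables.

    Takes the union of the per-exposure instrument lists (default: each
    table's own variants).  With ``drop_shared`` on, a variant appearing in
    more than one exposure's instrument list — or correlated at
    ``r2 >= 0.001`` with a variant of another list when an LD frame is
    supplied — is dropped as a shared predictor.  Every retained variant is
    aligned onto the first exposure's effect allele across all tables;
    ambiguous palindromic variants are dropped.
    """
    K = len(exposure_tables)
    if K < 2:
        raise DataError("multivariable MR needs at least 2 exposures")
    opts = options or HarmonizeOptions()
    lists = instrument_lists or [t.variant_ids for t in exposure_tables]
    if len(lists) != K:
        raise DataError("one instrument list per exposure required")

    union: list[str] = []
    seen: set[str] = set()
    for lst in lists:
        for vid in lst:
            if vid not in seen:
                seen.add(vid)
                union.append(vid)

    dropped: list[tuple[str, str]] = []
    shared: set[str] = set()
    if drop_shared and instrument_lists is not None:
        sets = [set(lst) for lst in lists]
        for i in range(K):
            for j in range(i + 1, K):
                shared |= sets[i] & sets[j]
                if ld is not None:
                    for a in sets[i]:
                        for b in sets[j]:
                            if a != b and a in ld.index and b in ld.columns \
                                    and float(ld.loc[a, b]) >= 0.001:
                                shared |= {a, b}

    rows_bx, rows_sx, rows_by, rows_sy, kept_ids = [], [], [], [], []
    for vid in union:
        if vid in shared:
            dropped.append((vid, "shared predictor"))
            continue
        recs = [t.get(vid) for t in exposure_tables]
        out_rec = outcome.get(vid)
        if any(r is None for r in recs) or out_rec is None:
            dropped.append((vid, "missing from a table"))
            continue
        ref = recs[0]
        if classify_palindromic(ref, opts.ambiguity_window) == PALINDROMIC_AMBIGUOUS:
            dropped.append((vid, "ambiguous palindromic"))
            continue
        try:
            bx, sx = [ref.beta], [ref.se]
            for rec in recs[1:]:
                a = align_alleles(ref, rec)
                bx.append(a.beta)
                sx.append(a.se)
            ay = align_alleles(ref, out_rec)
        except AlleleMismatch as exc:
            dropped.append((vid, str(exc)))
            continue
        rows_bx.append(bx)
        rows_sx.append(sx)
        rows_by.append(ay.beta)
        rows_sy.append(ay.se)
        kept_ids.append(vid)

    if len(kept_ids) < K + 1:
        raise DataError(
            f"underidentified: {len(kept_ids)} variants for {K} exposures")
    return MVHarmonizedSet(
        exposure_ids=[t.trait_id for t in exposure_tables],
        outcome_id=outcome.trait_id, variant_ids=kept_ids,
        beta_x=np.array(rows_bx), se_x=np.array(rows_sx),
        beta_y=np.array(rows_by), se_y=np.array(rows_sy),
        pheno_corr=pheno_corr, dropped=dropped)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.matrix_rank(xtwx) < X.shape[1]:
        raise EstimationError("rank-deficient design matrix")
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    return coef, q, np.linalg.inv(xtwx)


def _make_estimates(mvset, coef, cov, q, q_df, phi, method,
                    intercept=None) -> list[MREstimate]:
    out = []
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    for j, exp_id in enumerate(mvset.exposure_ids):
        beta, se = float(coef[j]), math.sqrt(cov[j, j])
        kw = {}
        if intercept is not None:
            kw = dict(intercept=intercept[0], intercept_se=intercept[1],
                      intercept_p=_normal_p(intercept[0] / intercept[1]))
        out.append(MREstimate(
            method=method, beta=beta, se=se, ci_low=beta - Z95 * se,
            ci_high=beta + Z95 * se, pvalue=_normal_p(beta / se),
            n_snps=mvset.n_snps, q=q, q_df=q_df, q_pvalue=q_p,
            dispersion=phi, exposure_id=exp_id, outcome_id=mvset.outcome_id,
            **kw))
    return out


def mv_ivw(mvset: MVHarmonizedSet, effects: str = "multiplicative_random"
           ) -> list[MREstimate]:
    """Multivariable IVW: WLS of outcome betas on all exposure betas.

    No intercept; weights ``1/se_y^2``.  Coefficient j is exposure j's
    direct effect.  Under multiplicative random effects, SEs are scaled by
    ``sqrt(max(1, Q/(L-K)))``.
    """
    L, K = mvset.n_snps, mvset.n_exposures
    if L <= K:
        raise EstimationError(f"need more variants ({L}) than exposures ({K})")
    w = 1.0 / mvset.se_y**2
    coef, q, xtwx_inv = _wls(mvset.beta_x, mvset.beta_y, w)
    q_df = L - K
    phi = max(1.0, q / q_df) if effects == "multiplicative_random" else 1.0
    cov = xtwx_inv * phi
    method = "mv_ivw_mre" if effects == "multiplicative_random" else "mv_ivw_fixed"
    return _make_estimates(mvset, coef, cov, q, q_df, phi, method)


def mv_egger(mvset: MVHarmonizedSet, fit_intercept: bool = True
             ) -> list[MREstimate]:
    """Multivariable MR-Egger: WLS with an intercept after orienting all
    variants so the first (primary) exposure's beta is non-negative.

    With ``fit_intercept=False`` the fit is the nested no-intercept model,
    which coincides with :func:`mv_ivw` (row sign flips cancel in the
    weighted normal equations).
    """
    if not fit_intercept:
        return mv_ivw(mvset)
    L, K = mvset.n_snps, mvset.n_exposures
    if L <= K + 1:
        raise EstimationError(f"need more variants ({L}) than exposures+1 ({K + 1})")
    sign = np.where(mvset.beta_x[:, 0] < 0, -1.0, 1.0)
    bx = mvset.beta_x * sign[:, None]
    by = mvset.beta_y * sign
    w = 1.0 / mvset.se_y**2
    X = np.column_stack([np.ones(L), bx])
    coef, q, xtwx_inv = _wls(X, by, w)
    q_df = L - K - 1
    phi = max(1.0, q / q_df)
    cov = xtwx_inv * phi
    intercept = (float(coef[0]), math.sqrt(cov[0, 0]))
    return _make_estimates(mvset, coef[1:], cov[1:, 1:], q, q_df, phi,
                           "mv_egger", intercept=intercept)


def conditional_f(mvset: MVHarmonizedSet, exposure_index: int = 0) -> float:
    """Conditional instrument strength of one exposure given the other.

    For exposure j and the other exposure m, minimizes over delta

    ``Q_j(delta) = sum_k (bxj_k - delta*bxm_k)^2 /
    (sxj_k^2 + delta^2*sxm_k^2 - 2*delta*rho_jm*sxj_k*sxm_k)``

    where ``rho_jm`` is the phenotypic correlation; the conditional F is
    ``Q_j(delta_hat) / (L - 1)``.  Only the two-exposure case is supported.
    """
    if mvset.n_exposures != 2:
        raise EstimationError("conditional_f supports exactly 2 exposures")
    L = mvset.n_snps
    if L < 3:
        raise EstimationError("conditional_f requires at least 3 variants")
    j = exposure_index
    m = 1 - j
    bxj, bxm = mvset.beta_x[:, j], mvset.beta_x[:, m]
    sxj, sxm = mvset.se_x[:, j], mvset.se_x[:, m]
    rho = float(mvset.pheno_corr[j, m])

    def q_of(delta: float) -> float:
        denom = sxj**2 + delta**2 * sxm**2 - 2.0 * delta * rho * sxj * sxm
        if np.any(denom <= 0):
            return np.inf
        return float(np.sum((bxj - delta * bxm) ** 2 / denom))

    res = optimize.minimize_scalar(q_of, bounds=(-10.0, 10.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success or not np.isfinite(res.fun):
        raise EstimationError(f"conditional_f minimization failed: {res}")
    return float(res.fun) / (L - 1)


def modified_q(mvset: MVHarmonizedSet, theta=None
               ) -> tuple[float, int, float]:
    """Modified Q statistic propagating exposure-beta uncertainty.

    ``Q_A(theta) = sum_k (by_k - theta1*bx1_k - theta2*bx2_k)^2 / v_k``
    with ``v_k = sy_k^2 + theta1^2 sx1_k^2 + theta2^2 sx2_k^2 +
    2 theta1 theta2 rho12 sx1_k sx2_k``.  When ``theta`` is omitted the
    statistic is reported at its minimizing theta.  df = L - K.
    """
    if mvset.n_exposures != 2:
        raise EstimationError("modified_q supports exactly 2 exposures")
    L = mvset.n_snps
    bx1, bx2 = mvset.beta_x[:, 0], mvset.beta_x[:, 1]
    sx1, sx2 = mvset.se_x[:, 0], mvset.se_x[:, 1]
    rho = float(mvset.pheno_corr[0, 1])

    def q_of(t) -> float:
        t1, t2 = t
        v = (mvset.se_y**2 + t1**2 * sx1**2 + t2**2 * sx2**2
             + 2.0 * t1 * t2 * rho * sx1 * sx2)
        if np.any(v <= 0):
            raise DataError("non-positive variance in modified Q denominator")
        return float(np.sum((mvset.beta_y - t1 * bx1 - t2 * bx2) ** 2 / v))

    if theta is None:
        start = np.array([e.beta for e in mv_ivw(mvset)])
        res = optimize.minimize(q_of, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        q = float(res.fun)
    else:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (2,):
            raise DataError("theta must have length 2")
        q = q_of(theta)
    df = L - 2
    return q, df, float(stats.chi2.sf(q, df))
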