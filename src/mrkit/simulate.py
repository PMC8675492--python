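"""Synthetic GWAS summary statistics with known ground truth.

Generates two-sample (and multivariable) exposure/outcome association
tables under a configurable generative model — known causal effect,
per-variant pleiotropy (balanced or directional, with optional InSIDE
violation), frequency-dependent standard errors, binary-outcome log-odds
scale — and runs calibration experiments (bias, coverage, rejection rate)
over replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import estimators
from .errors import DataError, EstimationError
from .harmonize import harmonize_dataset
from .sumstats import AssociationTable, VariantAssociation

__all__ = [
    "SimulationScenario",
    "CalibrationResult",
    "simulate_pair",
    "simulate_mv",
    "make_negative_control",
    "calibrate",
]

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SimulationScenario:
    """Generative parameters for one synthetic two-sample dataset.

    ``theta_true`` is the causal log-odds of outcome per SD of exposure.
    Pleiotropy applies to a fraction ``invalid_fraction`` of SNPs with mean
    ``pleiotropy_mean`` and SD ``pleiotropy_sd``; ``inside_violation_rho``
    correlates pleiotropy with instrument strength (0 = InSIDE holds).
    """

    n_snps: int = 100
    n_exposure: int = 450_000
    n_outcome: int = 400_000
    case_fraction: float = 0.09
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_r2: float = 0.026
    theta_true: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation_rho: float = 0.0
    invalid_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    #: lower truncation of the standardized half-normal effect draw; mimics
    #: the significance pre-selection of real instrument sets (every SNP
    #: clears a genome-wide threshold, so none has a near-zero true effect).
    #: 0 recovers an untruncated half-normal.
    min_effect_z: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise DataError("n_snps must be >= 3")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DataError("maf_range must lie within (0, 0.5]")
        for name in ("case_fraction",):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DataError(f"{name} must be in (0, 1)")
        for name in ("invalid_fraction", "palindromic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must be in [0, 1]")
        if not (-1.0 <= self.inside_violation_rho <= 1.0):
            raise DataError("inside_violation_rho must be in [-1, 1]")
        if self.target_r2 <= 0:
            raise DataError("target_r2 must be positive (rescaling infeasible)")


@dataclass
class CalibrationResult:
    """Aggregate over replicates for one estimator."""

    method: str
    n_reps: int
    mean_estimate: float
    bias: float
    empirical_se: float
    mean_model_se: float
    rmse: float
    coverage_95: float
    rejection_rate: float
    seed: int
    truth: float = 0.0
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_95 <= 1.0):
            raise DataError("coverage_95 outside [0, 1]")
        if not (0.0 <= self.rejection_rate <= 1.0):
            raise DataError("rejection_rate outside [0, 1]")

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of ``mean_estimate``."""
        return self.empirical_se / np.sqrt(self.n_reps)


def _draw_alleles(rng: np.random.Generator, L: int, palindromic_fraction: float):
    n_pal = int(round(palindromic_fraction * L))
    pal_idx = set(rng.choice(L, size=n_pal, replace=False).tolist()) if n_pal else set()
    pairs = []
    for k in range(L):
        pool = _PALINDROMIC_PAIRS if k in pal_idx else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs


def _half_normal(rng: np.random.Generator, L: int, z_min: float) -> np.ndarray:
    """Half-normal draw left-truncated at ``z_min`` via the inverse CDF."""
    if z_min <= 0:
        return np.abs(rng.standard_normal(L))
    lo = 2.0 * stats.norm.cdf(z_min) - 1.0
    v = lo + (1.0 - lo) * rng.uniform(size=L)
    return stats.norm.ppf((1.0 + v) / 2.0)


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _pleiotropy(rng, gamma, scenario) -> tuple[np.ndarray, np.ndarray]:
    L = scenario.n_snps
    alpha = np.zeros(L)
    n_invalid = int(round(scenario.invalid_fraction * L))
    idx = np.sort(rng.choice(L, size=n_invalid, replace=False)) if n_invalid \
        else np.array([], dtype=int)
    if n_invalid:
        z = rng.standard_normal(n_invalid)
        rho = scenario.inside_violation_rho
        alpha[idx] = scenario.pleiotropy_mean + scenario.pleiotropy_sd * (
            np.sqrt(1.0 - rho**2) * z + rho * _standardized(gamma[idx]))
    return alpha, idx


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, 5e-324)


def _table(trait_id, ids, pairs, eaf, beta, se, n, *, binary=False,
           n_cases=None, n_noncases=None, unit_sd=None) -> AssociationTable:
    p = _pvalues(beta, se)
    records = [
        VariantAssociation(
            variant_id=ids[k], effect_allele=pairs[k][0],
            other_allele=pairs[k][1], beta=float(beta[k]), se=float(se[k]),
            pvalue=float(p[k]), eaf=float(eaf[k]), n=int(n),
            trait_id=trait_id, unit_sd=unit_sd)
        for k in range(len(ids))
    ]
    return AssociationTable(
        trait_id=trait_id, records=records,
        trait_type="binary" if binary else "continuous",
        n_cases=n_cases, n_noncases=n_noncases)


def simulate_pair(scenario: SimulationScenario,
                  exposure_id: str = "exposure", outcome_id: str = "outcome"
                  ) -> tuple[AssociationTable, AssociationTable, dict]:
    """Generate one exposure/outcome summary-statistics pair.

    True standardized effects are drawn half-normal and rescaled so the
    instruments jointly explain ``target_r2`` of the (unit-SD) exposure;
    the half-normal orientation puts every true effect on the
    exposure-increasing allele, which keeps directional pleiotropy
    interpretable after the Egger sign convention.  SEs follow the analytic
    forms ``se_x = (2 maf (1-maf) n_exp)^(-1/2)`` and
    ``se_y = (2 maf (1-maf) n_out cf (1-cf))^(-1/2)``.  Deterministic given
    the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.n_snps
    maf = rng.uniform(*scenario.maf_range, size=L)
    het = 2.0 * maf * (1.0 - maf)
    g = _half_normal(rng, L, scenario.min_effect_z)
    gamma = g * np.sqrt(scenario.target_r2 / np.sum(het * g**2))
    se_x = 1.0 / np.sqrt(het * scenario.n_exposure)
    beta_x = gamma + rng.normal(0.0, se_x)
    alpha, invalid_idx = _pleiotropy(rng, gamma, scenario)
    cf = scenario.case_fraction
    se_y = 1.0 / np.sqrt(het * scenario.n_outcome * cf * (1.0 - cf))
    beta_y = scenario.theta_true * gamma + alpha + rng.normal(0.0, se_y)
    pairs = _draw_alleles(rng, L, scenario.palindromic_fraction)
    ids = [f"rs{k + 1}" for k in range(L)]
    n_cases = int(round(cf * scenario.n_outcome))
    exposure = _table(exposure_id, ids, pairs, maf, beta_x, se_x,
                      scenario.n_exposure, unit_sd=1.0)
    outcome = _table(outcome_id, ids, pairs, maf, beta_y, se_y,
                     scenario.n_outcome, binary=True, n_cases=n_cases,
                     n_noncases=scenario.n_outcome - n_cases)
    truth = {
        "theta": scenario.theta_true, "gamma": gamma, "alpha": alpha,
        "maf": maf, "invalid_idx": invalid_idx, "seed": scenario.seed,
    }
    return exposure, outcome, truth


def simulate_mv(scenario: SimulationScenario, theta2: float,
                cross_corr: float = 0.5, target_r2_2: float | None = None,
                pheno_corr: float = 0.0,
                ) -> tuple[AssociationTable, AssociationTable,
                           AssociationTable, dict]:
    """Generate a two-exposure dataset with shared-instrument confounding.

    Exposure 2's true effects correlate with exposure 1's through
    ``cross_corr``, so every SNP carries a second causal pathway into the
    outcome (``theta2``); univariable MR on exposure 1 is then biased while
    multivariable MR is not.  ``pheno_corr`` is carried into the truth
    record for conditional-strength statistics (it does not enter the
    generative model, which assumes non-overlapping samples).
    """
    if not (0.0 <= cross_corr < 1.0):
        raise DataError("cross_corr must be in [0, 1)")
    rng = np.random.default_rng(scenario.seed)
    L = scenario.n_snps
    r2_2 = scenario.target_r2 if target_r2_2 is None else target_r2_2
    maf = rng.uniform(*scenario.maf_range, size=L)
    het = 2.0 * maf * (1.0 - maf)
    g1 = _half_normal(rng, L, scenario.min_effect_z)
    eta = _half_normal(rng, L, scenario.min_effect_z)
    g2 = cross_corr * g1 + np.sqrt(1.0 - cross_corr**2) * eta
    gamma1 = g1 * np.sqrt(scenario.target_r2 / np.sum(het * g1**2))
    gamma2 = g2 * np.sqrt(r2_2 / np.sum(het * g2**2))
    se_x = 1.0 / np.sqrt(het * scenario.n_exposure)
    beta_x1 = gamma1 + rng.normal(0.0, se_x)
    beta_x2 = gamma2 + rng.normal(0.0, se_x)
    alpha, invalid_idx = _pleiotropy(rng, gamma1, scenario)
    cf = scenario.case_fraction
    se_y = 1.0 / np.sqrt(het * scenario.n_outcome * cf * (1.0 - cf))
    beta_y = (scenario.theta_true * gamma1 + theta2 * gamma2 + alpha
              + rng.normal(0.0, se_y))
    pairs = _draw_alleles(rng, L, scenario.palindromic_fraction)
    ids = [f"rs{k + 1}" for k in range(L)]
    n_cases = int(round(cf * scenario.n_outcome))
    exp1 = _table("exposure1", ids, pairs, maf, beta_x1, se_x,
                  scenario.n_exposure, unit_sd=1.0)
    exp2 = _table("exposure2", ids, pairs, maf, beta_x2, se_x,
                  scenario.n_exposure, unit_sd=1.0)
    outcome = _table("outcome", ids, pairs, maf, beta_y, se_y,
                     scenario.n_outcome, binary=True, n_cases=n_cases,
                     n_noncases=scenario.n_outcome - n_cases)
    truth = {
        "theta1": scenario.theta_true, "theta2": theta2,
        "gamma1": gamma1, "gamma2": gamma2, "alpha": alpha,
        "invalid_idx": invalid_idx, "cross_corr": cross_corr,
        "pheno_corr": pheno_corr, "seed": scenario.seed,
    }
    return exp1, exp2, outcome, truth


def make_negative_control(exposure: AssociationTable, seed: int,
                          n_outcome: int = 400_000,
                          case_fraction: float = 0.1,
                          trait_id: str = "negative_control"
                          ) -> AssociationTable:
    """Null-outcome table for the same variants: theta = 0, no pleiotropy.

    The pipeline run on this table must yield CIs covering OR = 1 at the
    nominal rate.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    cf = case_fraction
    n_cases = int(round(cf * n_outcome))
    for r in exposure.records:
        if r.eaf is None or not (0.0 < r.eaf < 1.0):
            raise DataError(f"{r.variant_id}: eaf required for control outcome")
        maf = min(r.eaf, 1.0 - r.eaf)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_outcome * cf * (1.0 - cf))
        beta = float(rng.normal(0.0, se))
        records.append(VariantAssociation(
            variant_id=r.variant_id, effect_allele=r.effect_allele,
            other_allele=r.other_allele, beta=beta, se=float(se),
            pvalue=float(max(2.0 * stats.norm.sf(abs(beta / se)), 5e-324)),
            eaf=r.eaf, n=n_outcome, trait_id=trait_id))
    return AssociationTable(
        trait_id=trait_id, records=records, trait_type="binary",
        n_cases=n_cases, n_noncases=n_outcome - n_cases)


_METHOD_ALIASES = {
    "ivw": "ivw", "ivw_mre": "ivw", "ivw_fixed": "ivw_fixed",
    "median": "median", "weighted_median": "median",
    "egger": "egger", "egger_intercept": "egger_intercept",
}


def _run_method(method: str, hset, n_boot: int, seed: int):
    """Return (estimate_value, se, ci_low, ci_high, pvalue) for one rep."""
    if method == "ivw":
        e = estimators.ivw(hset)
    elif method == "ivw_fixed":
        e = estimators.ivw(hset, effects="fixed")
    elif method == "median":
        e = estimators.weighted_median(hset, n_boot=n_boot, seed=seed)
    elif method in ("egger", "egger_intercept"):
        e = estimators.mr_egger(hset)
        if method == "egger_intercept":
            lo = e.intercept - estimators.Z95 * e.intercept_se
            hi = e.intercept + estimators.Z95 * e.intercept_se
            return e.intercept, e.intercept_se, lo, hi, e.intercept_p
    else:
        raise DataError(f"unknown calibration method {method!r}")
    return e.beta, e.se, e.ci_low, e.ci_high, e.pvalue


def calibrate(scenario: SimulationScenario, methods, n_reps: int, seed: int,
              n_boot: int = 200, alpha: float = 0.05,
              stream_path=None) -> list[CalibrationResult]:
    """Run simulate -> harmonize -> estimate over ``n_reps`` replicates.

    Replicate random streams are spawned from the master ``seed`` so each
    rep is independent and individually reproducible.  For
    ``egger_intercept`` the truth is the expected mean pleiotropy
    ``invalid_fraction * pleiotropy_mean``; for all other methods it is
    ``theta_true``.  Estimator failures are recorded and the replicate
    excluded for that method.
    """
    methods = [_METHOD_ALIASES.get(m, m) for m in methods]
    for m in methods:
        if m not in _METHOD_ALIASES.values():
            raise DataError(f"unknown calibration method {m!r}")
    truth_map = {
        m: (scenario.invalid_fraction * scenario.pleiotropy_mean
            if m == "egger_intercept" else scenario.theta_true)
        for m in methods
    }
    per = {m: {"est": [], "se": [], "cover": 0, "reject": 0, "fail": 0}
           for m in methods}
    stream = open(stream_path, "w") if stream_path else None
    if stream:
        stream.write("rep\tmethod\testimate\tse\tci_low\tci_high\tpvalue\n")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    z_alpha = stats.norm.isf(alpha / 2.0)
    try:
        for rep, child in enumerate(children):
            s1, s2 = (int(v) for v in child.generate_state(2))
            rep_scn = dataclasses.replace(scenario, seed=s1)
            exposure, outcome, _ = simulate_pair(rep_scn)
            hset = harmonize_dataset(exposure, outcome)
            for m in methods:
                try:
                    est, se, lo, hi, p = _run_method(m, hset, n_boot, s2)
                except (EstimationError, DataError):
                    per[m]["fail"] += 1
                    continue
                t = truth_map[m]
                per[m]["est"].append(est)
                per[m]["se"].append(se)
                per[m]["cover"] += int(lo <= t <= hi)
                per[m]["reject"] += int(abs(est / se) > z_alpha)
                if stream:
                    stream.write(f"{rep}\t{m}\t{est:.17g}\t{se:.17g}"
                                 f"\t{lo:.17g}\t{hi:.17g}\t{p:.17g}\n")
    finally:
        if stream:
            stream.close()

    results = []
    for m in methods:
        est = np.asarray(per[m]["est"])
        n_ok = len(est)
        if n_ok == 0:
            raise EstimationError(f"method {m!r} failed in every replicate")
        t = truth_map[m]
        results.append(CalibrationResult(
            method=m, n_reps=n_ok,
            mean_estimate=float(est.mean()),
            bias=float(est.mean() - t),
            empirical_se=float(est.std(ddof=1)),
            mean_model_se=float(np.mean(per[m]["se"])),
            rmse=float(np.sqrt(np.mean((est - t) ** 2))),
            coverage_95=per[m]["cover"] / n_ok,
            rejection_rate=per[m]["reject"] / n_ok,
            seed=seed, truth=t, n_failed=per[m]["fail"]))
    return results
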