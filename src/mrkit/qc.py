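"""Instrument selection and strength diagnostics.

Significance and LD filtering of candidate instruments, per-SNP and mean
F-statistics, heterogeneity of instrument strength (I2), variance explained,
and power approximations for binary-outcome MR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .sumstats import AssociationTable

__all__ = [
    "InstrumentDiagnostics",
    "PowerSpec",
    "significance_filter",
    "ld_clump",
    "read_ld_matrix",
    "per_snp_f",
    "i2_gx",
    "variance_explained",
    "mr_power_binary",
    "diagnose_instruments",
]


@dataclass
class InstrumentDiagnostics:
    """Per-set instrument-strength summary."""

    n_snps: int
    f_per_snp: np.ndarray
    f_mean: float
    f_min: float
    f_max: float
    i2_gx: float | None
    r2_explained: float | None

    def __post_init__(self) -> None:
        if not (self.f_min <= self.f_mean <= self.f_max):
            raise DataError("inconsistent F summary")


@dataclass
class PowerSpec:
    """Inputs to the binary-outcome MR power approximation."""

    n_total: int
    case_fraction: float
    r2: float
    alpha: float = 0.05
    power_target: float = 0.8

    def __post_init__(self) -> None:
        for name in ("case_fraction", "r2", "alpha", "power_target"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DataError(f"PowerSpec.{name} must be in (0, 1), got {v}")
        if self.n_total <= 0:
            raise DataError("PowerSpec.n_total must be positive")


def significance_filter(table: AssociationTable, p_max: float = 5e-8
                        ) -> AssociationTable:
    """Keep rows with p-value strictly below ``p_max``, preserving order."""
    kept = [r for r in table.records if r.pvalue < p_max]
    if not kept:
        warnings.warn(
            f"significance filter at {p_max} left no variants for "
            f"{table.trait_id}", stacklevel=2)
    return AssociationTable(
        trait_id=table.trait_id, records=kept, trait_type=table.trait_type,
        n_cases=table.n_cases, n_noncases=table.n_noncases)


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square LD (r2) matrix TSV whose header holds variant ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise DataError(f"{path}: LD matrix rows and columns disagree")
    return df


def ld_clump(table: AssociationTable, ld, r2_max: float = 0.001
             ) -> AssociationTable:
    """Greedy LD clumping: keep the most significant variant per LD block.

    Repeatedly selects the remaining variant with the smallest p-value
    (ties broken by lexicographically smaller variant id) and removes all
    others correlated with it at ``r2 >= r2_max``.
    """
    ids = table.variant_ids
    if isinstance(ld, pd.DataFrame):
        missing = [v for v in ids if v not in ld.index]
        if missing:
            raise DataError(f"LD matrix lacks variants {missing[:5]}")
        mat = ld.loc[ids, ids].to_numpy(dtype=float)
    else:
        mat = np.asarray(ld, dtype=float)
    L = len(ids)
    if mat.shape != (L, L):
        raise DataError(f"LD matrix shape {mat.shape} does not match {L} variants")
    if not np.allclose(np.diag(mat), 1.0):
        raise DataError("LD matrix diagonal must be 1")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise DataError("LD matrix must be symmetric")

    order = sorted(range(L), key=lambda i: (table.records[i].pvalue, ids[i]))
    alive = np.ones(L, dtype=bool)
    keep: set[int] = set()
    for i in order:
        if not alive[i]:
            continue
        keep.add(i)
        alive &= mat[i] < r2_max
        alive[i] = False
    kept = [table.records[i] for i in range(L) if i in keep]
    return AssociationTable(
        trait_id=table.trait_id, records=kept, trait_type=table.trait_type,
        n_cases=table.n_cases, n_noncases=table.n_noncases)


def per_snp_f(beta: float, se: float) -> float:
    """Approximate per-SNP F-statistic, ``(beta/se)^2``."""
    if se <= 0:
        raise DataError("se must be positive")
    return (beta / se) ** 2


def i2_gx(beta_x, se_x) -> float:
    """Heterogeneity of instrument strength (NOME diagnostic).

    ``Q_GX`` is the inverse-variance-weighted sum of squared deviations of
    the SNP-exposure betas from their weighted mean; returns
    ``max(0, (Q_GX - (L-1)) / Q_GX)``.
    """
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    L = len(beta_x)
    if L < 2:
        raise DataError("i2_gx requires at least 2 instruments")
    if np.any(se_x <= 0):
        raise DataError("se_x must be positive")
    w = 1.0 / se_x**2
    bbar = np.sum(w * beta_x) / np.sum(w)
    q_gx = np.sum(w * (beta_x - bbar) ** 2)
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (L - 1)) / q_gx)


def variance_explained(beta, eaf, phenotype_sd: float) -> float:
    """Phenotypic variance explained by an instrument set.

    Per SNP: ``(beta/sd)^2 * 2 * MAF * (1 - MAF)`` with
    ``MAF = min(eaf, 1 - eaf)``; summed over SNPs.
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if phenotype_sd <= 0:
        raise DataError("phenotype_sd must be positive")
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise DataError("eaf must be strictly inside (0, 1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    return float(np.sum((beta / phenotype_sd) ** 2 * 2.0 * maf * (1.0 - maf)))


def mr_power_binary(spec: PowerSpec, mode: str = "detectable_or",
                    or_value: float | None = None) -> float:
    """Power approximation for binary-outcome MR.

    Non-centrality ``NCP = n * r2 * cf*(1-cf) * ln(OR)^2``.

    mode ``"power_at_or"``
        Returns ``Phi(sqrt(NCP) - z_{1-alpha/2})`` for the supplied
        ``or_value``.
    mode ``"detectable_or"``
        Solves for the OR (> 1) detectable at ``power_target``:
        ``ln OR = (z_{1-alpha/2} + z_power) / sqrt(n * r2 * cf*(1-cf))``.
    """
    if spec.r2 == 0:
        raise DataError("r2 = 0: infinite sample size required")
    cf = spec.case_fraction
    denom = spec.n_total * spec.r2 * cf * (1.0 - cf)
    z_alpha = stats.norm.isf(spec.alpha / 2.0)
    if mode == "power_at_or":
        if or_value is None or or_value <= 0:
            raise DataError("power_at_or requires a positive or_value")
        ncp = denom * np.log(or_value) ** 2
        return float(stats.norm.cdf(np.sqrt(ncp) - z_alpha))
    if mode == "detectable_or":
        z_power = stats.norm.ppf(spec.power_target)
        return float(np.exp((z_alpha + z_power) / np.sqrt(denom)))
    raise DataError(f"unknown power mode {mode!r}")


def diagnose_instruments(table: AssociationTable,
                         phenotype_sd: float | None = None
                         ) -> InstrumentDiagnostics:
    """Compute the full diagnostics bundle for an instrument table."""
    if len(table) == 0:
        raise DataError("empty instrument table")
    f = np.array([per_snp_f(r.beta, r.se) for r in table.records])
    i2 = i2_gx([r.beta for r in table.records],
               [r.se for r in table.records]) if len(table) >= 2 else None
    r2 = None
    sd = phenotype_sd or next(
        (r.unit_sd for r in table.records if r.unit_sd is not None), None)
    eafs = [r.eaf for r in table.records]
    if sd is not None and all(e is not None for e in eafs):
        r2 = variance_explained([r.beta for r in table.records], eafs, sd)
    return InstrumentDiagnostics(
        n_snps=len(table), f_per_snp=f, f_mean=float(f.mean()),
        f_min=float(f.min()), f_max=float(f.max()), i2_gx=i2, r2_explained=r2)
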