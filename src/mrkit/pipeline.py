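"""Orchestration of a full exposure x outcome MR study from a YAML config.

For every exposure/outcome cell: harmonize, run the main (IVW with
multiplicative random effects) and sensitivity (weighted median, MR-Egger)
estimators, rescale to custom phenotype units when configured, attach
instrument diagnostics and power, apply the multiplicity correction, and
write result tables plus a run log.  Cell failures are isolated so one bad
file cannot kill the run.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, DataError, MRKitError
from .estimators import ivw, mr_egger, rescale_estimate, weighted_median
from .harmonize import HarmonizeOptions, ProxyMap, harmonize_dataset, read_proxy_map
from .multivariable import build_mv_set, conditional_f, mv_ivw
from .qc import PowerSpec, diagnose_instruments, mr_power_binary, significance_filter
from .sumstats import read_association_table, write_results_table

__all__ = ["StudyConfig", "StudyResults", "bonferroni_threshold",
           "load_config", "run_study"]


def bonferroni_threshold(alpha: float, n_exposures: int, n_outcomes: int
                         ) -> float:
    """Family-wise corrected threshold: ``alpha / (n_exposures * n_outcomes)``."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ConfigError("exposure and outcome counts must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")
    return alpha / (n_exposures * n_outcomes)


@dataclass
class StudyConfig:
    """Validated study configuration (see README for the YAML schema)."""

    exposures: list[dict]
    outcomes: list[dict]
    covariates: list[dict] = field(default_factory=list)
    pheno_corr: list | None = None
    proxy_map: str | None = None
    alpha: float = 0.05
    correction: str = "bonferroni"
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "mr_results"
    power_target: float = 0.8
    base_dir: str = "."

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigError("at least one exposure and one outcome required")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ConfigError(f"unknown correction {self.correction!r}")

    def resolve(self, path: str) -> str:
        return path if os.path.isabs(path) else os.path.join(self.base_dir, path)

    @property
    def threshold(self) -> float:
        if self.correction == "bonferroni":
            return bonferroni_threshold(self.alpha, len(self.exposures),
                                        len(self.outcomes))
        return self.alpha


def load_config(path) -> StudyConfig:
    """Load and validate a study YAML; relative paths resolve against it."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f for f in StudyConfig.__dataclass_fields__} - {"base_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(base_dir=os.path.dirname(os.path.abspath(path)), **raw)


@dataclass
class StudyResults:
    estimates: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    failures: list[tuple[str, str, str]] = field(default_factory=list)
    output_dir: str = ""


def _read_instruments(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _load_exposure(cfg: StudyConfig, spec: dict):
    table = read_association_table(
        cfg.resolve(spec["path"]), column_map=spec.get("column_map"),
        trait_meta={"trait_id": spec["trait_id"],
                    "unit_sd": spec.get("phenotype_sd")})
    if "instruments" in spec:
        ids = _read_instruments(cfg.resolve(spec["instruments"]))
        table = table.subset(ids)
    elif spec.get("p_threshold") is not None:
        table = significance_filter(table, float(spec["p_threshold"]))
    if len(table) == 0:
        raise DataError(f"{spec['trait_id']}: no instruments after selection")
    return table


def _load_outcome(cfg: StudyConfig, spec: dict):
    return read_association_table(
        cfg.resolve(spec["path"]), column_map=spec.get("column_map"),
        trait_meta={"trait_id": spec["trait_id"],
                    "trait_type": spec.get("trait_type", "binary"),
                    "n_cases": spec.get("n_cases"),
                    "n_noncases": spec.get("n_noncases")},
        or_scale=bool(spec.get("or_scale", False)))


def run_study(config: StudyConfig) -> StudyResults:
    """Execute the configured exposure x outcome grid.

    Writes, under ``output_dir``: one results TSV per outcome, a combined
    TSV, an instrument-diagnostics TSV, a power TSV for binary outcomes
    with case counts, and a plain-text run log with the package version,
    seed and config hash.  Returns the in-memory bundle.
    """
    outdir = config.resolve(config.output_dir)
    os.makedirs(outdir, exist_ok=True)
    results = StudyResults(output_dir=outdir)
    proxy_map = read_proxy_map(config.resolve(config.proxy_map)) \
        if config.proxy_map else ProxyMap()
    threshold = config.threshold

    exposures, diags = {}, {}
    for spec in config.exposures:
        tid = spec["trait_id"]
        table = _load_exposure(config, spec)
        exposures[tid] = (spec, table)
        diags[tid] = diagnose_instruments(table, spec.get("phenotype_sd"))
    covariate_tables = {}
    for spec in config.covariates:
        covariate_tables[spec["trait_id"]] = (spec, _load_exposure(config, spec))
    results.diagnostics = diags

    per_outcome: dict[str, list] = {}
    power_rows = []
    for ospec in config.outcomes:
        oid = ospec["trait_id"]
        try:
            outcome = _load_outcome(config, ospec)
        except (MRKitError, OSError) as exc:
            for eid in exposures:
                results.failures.append((eid, oid, str(exc)))
            continue
        for eid, (espec, exp_table) in exposures.items():
            try:
                cell = _run_cell(config, espec, exp_table, ospec, outcome,
                                 proxy_map, covariate_tables)
                results.estimates.extend(cell)
                per_outcome.setdefault(oid, []).extend(cell)
            except (MRKitError, OSError) as exc:
                results.failures.append((eid, oid, str(exc)))
            d = diags[eid]
            if d.r2_explained and ospec.get("n_cases") and ospec.get("n_noncases"):
                n_tot = ospec["n_cases"] + ospec["n_noncases"]
                spec = PowerSpec(n_total=n_tot,
                                 case_fraction=ospec["n_cases"] / n_tot,
                                 r2=d.r2_explained, alpha=config.alpha,
                                 power_target=config.power_target)
                power_rows.append((eid, oid, mr_power_binary(spec)))

    if not results.estimates:
        raise DataError("every study cell failed; see failures")

    for oid, ests in per_outcome.items():
        write_results_table(ests, os.path.join(outdir, f"results_{oid}.tsv"),
                            significance_threshold=threshold)
    write_results_table(results.estimates,
                        os.path.join(outdir, "results_combined.tsv"),
                        significance_threshold=threshold)
    _write_diagnostics(diags, os.path.join(outdir, "diagnostics.tsv"))
    if power_rows:
        with open(os.path.join(outdir, "power.tsv"), "w") as fh:
            fh.write("exposure\toutcome\tdetectable_or_at_target_power\n")
            for eid, oid, orv in power_rows:
                fh.write(f"{eid}\t{oid}\t{orv:.6g}\n")
    _write_run_log(config, results, os.path.join(outdir, "run_log.txt"))
    return results


def _run_cell(config, espec, exp_table, ospec, outcome, proxy_map,
              covariate_tables):
    hset = harmonize_dataset(exp_table, outcome, proxy_map,
                             HarmonizeOptions())
    ests = [ivw(hset, effects="multiplicative_random")]
    if hset.n_snps >= 3:
        ests.append(weighted_median(hset, n_boot=config.n_boot,
                                    seed=config.seed))
        ests.append(mr_egger(hset))
    sd, unit = espec.get("phenotype_sd"), espec.get("rescale_unit")
    if sd and unit:
        ests.append(rescale_estimate(ests[0], sd, unit))
    for cid, (cspec, cov_table) in covariate_tables.items():
        try:
            mvset = build_mv_set(
                [exp_table, cov_table], outcome,
                instrument_lists=[exp_table.variant_ids, cov_table.variant_ids],
                pheno_corr=np.asarray(config.pheno_corr)
                if config.pheno_corr is not None else None)
            mv_ests = mv_ivw(mvset)
            primary = mv_ests[0]
            primary.method = f"mv_ivw_mre|{cid}"
            ests.append(primary)
        except MRKitError:
            continue  # MV cell failure must not kill the univariable cell
    return ests


def _write_diagnostics(diags, path) -> None:
    with open(path, "w") as fh:
        fh.write("exposure\tn_snps\tf_mean\tf_min\tf_max\ti2_gx\tr2_explained\n")
        for tid, d in diags.items():
            i2 = "" if d.i2_gx is None else f"{d.i2_gx:.6g}"
            r2 = "" if d.r2_explained is None else f"{d.r2_explained:.6g}"
            fh.write(f"{tid}\t{d.n_snps}\t{d.f_mean:.6g}\t{d.f_min:.6g}"
                     f"\t{d.f_max:.6g}\t{i2}\t{r2}\n")


def _config_hash(config: StudyConfig) -> str:
    payload = {k: v for k, v in config.__dict__.items() if k != "base_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _write_run_log(config, results, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"mrkit version: {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config hash: {_config_hash(config)}\n")
        fh.write(f"significance threshold: {config.threshold:.17g}\n")
        fh.write(f"estimates: {len(results.estimates)}\n")
        fh.write(f"failed cells: {len(results.failures)}\n")
        for eid, oid, reason in results.failures:
            fh.write(f"  FAILED {eid} x {oid}: {reason}\n")
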