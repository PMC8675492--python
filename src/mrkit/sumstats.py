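"""Reading, validating and writing GWAS summary-association tables.

The on-disk dialect is a delimited text table with a header row.  Fields are
mapped onto a standard vocabulary (``variant_id``, ``effect_allele``,
``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``, ``z``) via a
column map, so heterogeneous source files all funnel through one reader.
Missing values are encoded as ``.``, empty string, ``NA`` or ``nan``.

Standard errors absent from a source are reconstructed from the p-value via
:func:`se_from_pvalue`; below ``p = 1e-300`` a ``z`` column must be supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "VariantAssociation",
    "AssociationTable",
    "ReadLog",
    "se_from_pvalue",
    "read_association_table",
    "write_association_table",
    "write_results_table",
    "read_results_table",
]

#: Canonical field names understood by the reader.
STANDARD_FIELDS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "z",
)

_MISSING_TOKENS = {"", ".", "NA", "na", "NaN", "nan", "None"}

#: Smallest p-value recoverable from a float without a z column.
MIN_PVALUE_FOR_SE = 1e-300

_VALID_BASES = frozenset("ACGT")


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is in phenotype units per effect allele for continuous traits
    and log-odds per effect allele for binary traits.  ``unit_sd`` carries
    the phenotypic standard deviation when the trait is measured in raw
    units (e.g. mm Hg).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    trait_id: str = ""
    unit_sd: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if not self.variant_id:
            raise ValueError("empty variant_id")
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if not (set(self.effect_allele) <= _VALID_BASES
                and set(self.other_allele) <= _VALID_BASES):
            raise ValueError(f"{self.variant_id}: alleles must be over A/C/G/T")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.variant_id}: se must be positive")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")
        if self.unit_sd is not None and self.unit_sd <= 0:
            raise ValueError(f"{self.variant_id}: unit_sd must be positive")

    @property
    def is_snp(self) -> bool:
        """True when both alleles are single bases."""
        return len(self.effect_allele) == 1 and len(self.other_allele) == 1


@dataclass
class ReadLog:
    """Row-level accounting produced by :func:`read_association_table`."""

    n_accepted: int = 0
    n_rejected: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row: int, reason: str) -> None:
        self.n_rejected += 1
        self.rejects.append((row, reason))


@dataclass
class AssociationTable:
    """An ordered collection of :class:`VariantAssociation` for one trait."""

    trait_id: str
    records: list[VariantAssociation]
    trait_type: str = "continuous"
    n_cases: int | None = None
    n_noncases: int | None = None
    read_log: ReadLog | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise DataError(f"duplicate variant_id {dup!r} in table {self.trait_id!r}")
        self._index = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index.get(variant_id)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    @property
    def n_total(self) -> int | None:
        if self.n_cases is not None and self.n_noncases is not None:
            return self.n_cases + self.n_noncases
        return None

    def subset(self, variant_ids) -> "AssociationTable":
        """Restrict to the given variants, preserving this table's order."""
        wanted = set(variant_ids)
        return AssociationTable(
            trait_id=self.trait_id,
            records=[r for r in self.records if r.variant_id in wanted],
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_noncases=self.n_noncases,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": np.nan if r.n is None else r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                           "other_allele", "eaf", "beta",
                                           "se", "pvalue", "n"])


def se_from_pvalue(beta: float, pvalue: float) -> float:
    """Reconstruct a standard error from an effect size and its p-value.

    Inverts the two-sided normal test: ``se = |beta| / z`` with
    ``z = Phi^-1(1 - p/2)``.  Recomputing the two-sided p from ``beta`` and
    the returned SE reproduces the input to 1e-10 relative.

    Raises
    ------
    DataError
        If ``beta`` is zero (SE not recoverable) or ``pvalue`` lies outside
        the open interval (0, 1), or below :data:`MIN_PVALUE_FOR_SE`.
    """
    if not (0.0 < pvalue < 1.0):
        raise DataError(f"pvalue {pvalue} outside (0, 1)")
    if pvalue < MIN_PVALUE_FOR_SE:
        raise DataError(
            f"pvalue {pvalue} below {MIN_PVALUE_FOR_SE}; supply a z-score instead"
        )
    if beta == 0:
        raise DataError("SE not recoverable from beta = 0")
    z = stats.norm.isf(pvalue / 2.0)
    return abs(beta) / z


def _parse_float(token) -> float | None:
    if token is None:
        return None
    s = str(token).strip()
    if s in _MISSING_TOKENS:
        return None
    return float(s)


def _parse_str(token) -> str | None:
    if token is None:
        return None
    s = str(token).strip()
    if s in _MISSING_TOKENS:
        return None
    return s


def read_association_table(
    path,
    column_map: dict[str, str] | None = None,
    trait_meta: dict | None = None,
    *,
    delimiter: str = "\t",
    or_scale: bool = False,
) -> AssociationTable:
    """Read and validate a GWAS summary-association table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping of standard field name -> source column name.  Unmapped
        standard fields default to their own name when that column exists.
        ``variant_id``, ``effect_allele``, ``other_allele`` and ``beta`` are
        required; ``se`` may be absent if ``pvalue`` (or ``z``) allows
        reconstruction.
    trait_meta
        Optional dict with ``trait_id``, ``trait_type``, ``n_cases``,
        ``n_noncases``, ``unit_sd``.
    or_scale
        When True the ``beta`` column holds odds ratios and is
        log-transformed on read (the SE is assumed to already be on the
        log-odds scale, or is reconstructed from the p-value).

    Rows violating record invariants are rejected with row-level diagnostics
    collected in the returned table's ``read_log``; they never crash the read.
    """
    meta = dict(trait_meta or {})
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - malformed file shapes vary
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"{path}: table has no data rows")

    cmap = dict(column_map or {})
    for f in STANDARD_FIELDS:
        if f not in cmap and f in df.columns:
            cmap[f] = f
    for required in ("variant_id", "effect_allele", "other_allele", "beta"):
        if required not in cmap:
            raise ConfigError(f"no column mapped for required field {required!r}")
    for f, col in cmap.items():
        if col not in df.columns:
            raise ConfigError(f"mapped column {col!r} (field {f!r}) not in {path}")

    trait_id = meta.get("trait_id") or str(meta.get("name") or "") or _stem(path)
    unit_sd = meta.get("unit_sd")
    log = ReadLog()
    records: list[VariantAssociation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = {f: row[df.columns.get_loc(c)] for f, c in cmap.items()}
        try:
            beta = _parse_float(rowd.get("beta"))
            if beta is None:
                raise ValueError("missing beta")
            if or_scale:
                if beta <= 0:
                    raise ValueError("odds ratio must be positive")
                beta = math.log(beta)
            se = _parse_float(rowd.get("se"))
            pvalue = _parse_float(rowd.get("pvalue"))
            zval = _parse_float(rowd.get("z"))
            if se is None:
                if pvalue is not None and pvalue >= MIN_PVALUE_FOR_SE \
                        and pvalue < 1.0 and beta != 0:
                    se = se_from_pvalue(beta, pvalue)
                elif zval is not None and zval != 0:
                    se = abs(beta / zval)
                else:
                    raise ValueError("missing se and not recoverable from p or z")
            if pvalue is None:
                pvalue = float(2.0 * stats.norm.sf(abs(beta / se)))
                pvalue = max(pvalue, 5e-324)
            nval = _parse_float(rowd.get("n"))
            rec = VariantAssociation(
                variant_id=_parse_str(rowd.get("variant_id")) or "",
                effect_allele=_parse_str(rowd.get("effect_allele")) or "",
                other_allele=_parse_str(rowd.get("other_allele")) or "",
                beta=beta,
                se=se,
                pvalue=pvalue,
                eaf=_parse_float(rowd.get("eaf")),
                n=None if nval is None else int(nval),
                trait_id=trait_id,
                unit_sd=unit_sd,
            )
        except (ValueError, DataError) as exc:
            log.reject(i, str(exc))
            continue
        records.append(rec)
        log.n_accepted += 1

    if not records:
        raise DataError(f"{path}: no valid rows ({log.n_rejected} rejected)")
    return AssociationTable(
        trait_id=trait_id,
        records=records,
        trait_type=meta.get("trait_type", "continuous"),
        n_cases=meta.get("n_cases"),
        n_noncases=meta.get("n_noncases"),
        read_log=log,
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def _fmt(x) -> str:
    """Serialize a float so that re-parsing reproduces it bit-exactly."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "."
    return format(float(x), ".17g")


def write_association_table(table: AssociationTable, path) -> None:
    """Write a table in the standard TSV dialect read by the reader."""
    with open(path, "w") as fh:
        fh.write("variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n")
        for r in table.records:
            n = "." if r.n is None else str(r.n)
            fh.write(
                f"{r.variant_id}\t{r.effect_allele}\t{r.other_allele}\t"
                f"{_fmt(r.eaf)}\t{_fmt(r.beta)}\t{_fmt(r.se)}\t{_fmt(r.pvalue)}\t{n}\n"
            )


RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n_snps", "beta", "se",
    "ci_low", "ci_high", "or", "or_ci_low", "or_ci_high", "pvalue",
    "Q", "Q_pvalue", "egger_intercept", "egger_intercept_p",
    "passes_bonferroni",
]


def write_results_table(estimates, path, significance_threshold: float | None = None) -> None:
    """Write MR estimates as a TSV with a fixed column schema.

    Floats are serialized with 17 significant digits so a read-back
    reproduces every value exactly.  ``passes_bonferroni`` is filled when a
    ``significance_threshold`` is supplied.
    """
    estimates = list(estimates)
    if not estimates:
        raise DataError("no estimates to write")
    rows = []
    for e in estimates:
        orv, orlo, orhi = e.odds_ratio()
        passes = ""
        if significance_threshold is not None:
            passes = str(bool(e.pvalue < significance_threshold))
        rows.append([
            e.exposure_id, e.outcome_id, e.method, str(e.n_snps),
            _fmt(e.beta), _fmt(e.se), _fmt(e.ci_low), _fmt(e.ci_high),
            _fmt(orv), _fmt(orlo), _fmt(orhi), _fmt(e.pvalue),
            _fmt(e.q), _fmt(e.q_pvalue),
            _fmt(e.intercept) if e.intercept is not None else ".",
            _fmt(e.intercept_p) if e.intercept_p is not None else ".",
            passes,
        ])
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["."],
                     float_precision="round_trip")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing result columns {missing}")
    return df
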