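"""Allele harmonization of exposure and outcome summary statistics.

Aligns every outcome association onto the exposure's effect allele,
resolving allele swaps, strand flips, palindromic (A/T, C/G) ambiguity and
proxy substitution for variants missing from the outcome table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .sumstats import AssociationTable, VariantAssociation

__all__ = [
    "Alignment",
    "AlleleMismatch",
    "HarmonizedVariant",
    "HarmonizedSet",
    "ProxyEntry",
    "ProxyMap",
    "HarmonizeOptions",
    "align_alleles",
    "classify_palindromic",
    "substitute_proxies",
    "harmonize_dataset",
    "read_proxy_map",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Actions recorded per retained variant.
ACTIONS = ("direct", "swapped", "strand_flipped", "swapped_and_flipped",
           "proxy_substituted")

NOT_PALINDROMIC = "not_palindromic"
PALINDROMIC_INFERABLE = "palindromic_inferable"
PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"


class AlleleMismatch(DataError):
    """The outcome record's alleles cannot be reconciled with the exposure's."""


@dataclass
class Alignment:
    """An outcome association expressed on the exposure's effect allele."""

    beta: float
    se: float
    eaf: float | None
    action: str


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    if len(effect_allele) != 1 or len(other_allele) != 1:
        return False
    return _COMPLEMENT.get(effect_allele) == other_allele


def align_alleles(exposure_rec: VariantAssociation,
                  outcome_rec: VariantAssociation) -> Alignment:
    """Express ``outcome_rec`` on ``exposure_rec``'s effect allele.

    Four resolutions: identical allele pair -> ``direct``; swapped alleles
    -> ``swapped`` (beta negated, eaf complemented); reverse-complement pair
    -> ``strand_flipped`` (values unchanged); reverse-complement of the
    swapped pair -> ``swapped_and_flipped``.  Any other combination raises
    :class:`AlleleMismatch`.  Only biallelic single-base SNPs are accepted.
    """
    if not (exposure_rec.is_snp and outcome_rec.is_snp):
        raise AlleleMismatch(f"{exposure_rec.variant_id}: non-SNP alleles")
    ea, oa = exposure_rec.effect_allele, exposure_rec.other_allele
    yea, yoa = outcome_rec.effect_allele, outcome_rec.other_allele
    if (yea, yoa) == (ea, oa):
        return Alignment(outcome_rec.beta, outcome_rec.se, outcome_rec.eaf,
                         "direct")
    if (yea, yoa) == (oa, ea):
        eaf = None if outcome_rec.eaf is None else 1.0 - outcome_rec.eaf
        return Alignment(-outcome_rec.beta, outcome_rec.se, eaf, "swapped")
    cea, coa = _complement(ea), _complement(oa)
    if (yea, yoa) == (cea, coa):
        return Alignment(outcome_rec.beta, outcome_rec.se, outcome_rec.eaf,
                         "strand_flipped")
    if (yea, yoa) == (coa, cea):
        eaf = None if outcome_rec.eaf is None else 1.0 - outcome_rec.eaf
        return Alignment(-outcome_rec.beta, outcome_rec.se, eaf,
                         "swapped_and_flipped")
    raise AlleleMismatch(
        f"{exposure_rec.variant_id}: allele mismatch "
        f"({ea}/{oa} vs {yea}/{yoa})"
    )


def classify_palindromic(rec: VariantAssociation,
                         ambiguity_window: tuple[float, float] = (0.42, 0.58)
                         ) -> str:
    """Classify a record's palindromic status by allele pair and EAF.

    Palindromic variants with EAF strictly inside the open ambiguity window
    (defaults: 0.42-0.58, endpoints exclusive) cannot be oriented by
    frequency and are ``palindromic_ambiguous``; outside the window they
    are ``palindromic_inferable``.  Missing EAF on a palindromic variant is
    treated as ambiguous.
    """
    if not is_palindromic(rec.effect_allele, rec.other_allele):
        return NOT_PALINDROMIC
    lo, hi = ambiguity_window
    if rec.eaf is None:
        return PALINDROMIC_AMBIGUOUS
    if lo < rec.eaf < hi:
        return PALINDROMIC_AMBIGUOUS
    return PALINDROMIC_INFERABLE


@dataclass
class ProxyEntry:
    proxy_id: str
    r2: float
    allele_map: dict[str, str]  # missing-variant allele -> proxy allele

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise DataError(f"proxy {self.proxy_id}: r2 {self.r2} outside [0, 1]")


@dataclass
class ProxyMap:
    """Candidate proxies for variants missing from an outcome dataset."""

    entries: dict[str, list[ProxyEntry]] = field(default_factory=dict)

    def candidates(self, missing_id: str) -> list[ProxyEntry]:
        """Candidates for a missing variant, best r2 first."""
        return sorted(self.entries.get(missing_id, []),
                      key=lambda e: (-e.r2, e.proxy_id))

    def __len__(self) -> int:
        return len(self.entries)


def read_proxy_map(path) -> ProxyMap:
    """Read a proxy-map TSV: missing_id, proxy_id, r2, allele_map.

    ``allele_map`` pairs missing-variant alleles with proxy alleles, e.g.
    ``A=G,C=T``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["missing_id", "proxy_id", "r2", "allele_map"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: proxy map missing columns {missing_cols}")
    pm = ProxyMap()
    for row in df.itertuples(index=False):
        amap = {}
        for pair in str(row.allele_map).split(","):
            a, _, b = pair.strip().partition("=")
            amap[a.strip().upper()] = b.strip().upper()
        pm.entries.setdefault(str(row.missing_id), []).append(
            ProxyEntry(proxy_id=str(row.proxy_id), r2=float(row.r2),
                       allele_map=amap)
        )
    return pm


@dataclass
class SubstitutionPlan:
    substitutions: dict[str, ProxyEntry] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)


def substitute_proxies(requested, available, proxy_map: ProxyMap,
                       r2_min: float = 0.8, validator=None) -> SubstitutionPlan:
    """Plan proxy substitutions for requested variants not in ``available``.

    Each missing variant maps to its highest-r2 proxy with ``r2 >= r2_min``
    that is present in ``available`` and (when a ``validator`` callable is
    given) passes validation; invalid candidates are skipped and the next
    tried.  Variants with no acceptable proxy are dropped with reason
    ``"no proxy"``.
    """
    available = set(available)
    plan = SubstitutionPlan()
    for vid in requested:
        if vid in available:
            continue
        chosen = None
        for cand in proxy_map.candidates(vid):
            if cand.r2 < r2_min or cand.proxy_id not in available:
                continue
            if validator is not None and not validator(vid, cand):
                continue
            chosen = cand
            break
        if chosen is None:
            plan.dropped.append((vid, "no proxy"))
        else:
            plan.substitutions[vid] = chosen
    return plan


@dataclass
class HarmonizedVariant:
    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None
    action: str


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect vectors ready for estimation."""

    exposure_id: str
    outcome_id: str
    variants: list[HarmonizedVariant]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    audit: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([v.beta_x for v in self.variants])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([v.se_x for v in self.variants])

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([v.beta_y for v in self.variants])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([v.se_y for v in self.variants])

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @classmethod
    def from_arrays(cls, beta_x, se_x, beta_y, se_y, variant_ids=None,
                    exposure_id="exposure", outcome_id="outcome",
                    eaf=None) -> "HarmonizedSet":
        beta_x = np.asarray(beta_x, dtype=float)
        se_x = np.asarray(se_x, dtype=float)
        beta_y = np.asarray(beta_y, dtype=float)
        se_y = np.asarray(se_y, dtype=float)
        L = len(beta_x)
        if not (len(se_x) == len(beta_y) == len(se_y) == L):
            raise DataError("from_arrays: length mismatch")
        if np.any(se_x <= 0) or np.any(se_y <= 0):
            raise DataError("from_arrays: SEs must be positive")
        ids = variant_ids if variant_ids is not None else [f"v{i}" for i in range(L)]
        eafs = eaf if eaf is not None else [None] * L
        variants = [
            HarmonizedVariant(ids[i], beta_x[i], se_x[i], beta_y[i], se_y[i],
                              eafs[i], "direct")
            for i in range(L)
        ]
        return cls(exposure_id, outcome_id, variants)


@dataclass
class HarmonizeOptions:
    ambiguity_window: tuple[float, float] = (0.42, 0.58)
    #: orient inferable palindromic variants by EAF matching; if False they
    #: are kept only when alleles already identify the orientation.
    infer_palindromic: bool = True
    r2_min: float = 0.8


def _remap_proxy_record(exposure_rec: VariantAssociation,
                        proxy_rec: VariantAssociation,
                        entry: ProxyEntry) -> VariantAssociation | None:
    """Translate a proxy outcome record back into the missing variant's
    allele space using the entry's allele correspondence.

    Returns None when the correspondence is inconsistent with the proxy
    record's alleles.
    """
    inverse = {v: k for k, v in entry.allele_map.items()}
    if len(inverse) != len(entry.allele_map):
        return None
    ea = inverse.get(proxy_rec.effect_allele)
    oa = inverse.get(proxy_rec.other_allele)
    if ea is None or oa is None or ea == oa:
        return None
    try:
        return VariantAssociation(
            variant_id=exposure_rec.variant_id,
            effect_allele=ea,
            other_allele=oa,
            beta=proxy_rec.beta,
            se=proxy_rec.se,
            pvalue=proxy_rec.pvalue,
            eaf=proxy_rec.eaf,
            n=proxy_rec.n,
            trait_id=proxy_rec.trait_id,
        )
    except ValueError:
        return None


def _freq_orient(exposure_rec: VariantAssociation,
                 aligned: Alignment) -> Alignment:
    """Orient an inferable palindromic alignment by frequency matching.

    Chooses between keeping the alignment and flipping it (negated beta,
    complemented EAF), picking whichever brings the outcome EAF closer to
    the exposure EAF.
    """
    if aligned.eaf is None or exposure_rec.eaf is None:
        return aligned
    keep = abs(aligned.eaf - exposure_rec.eaf)
    flip = abs((1.0 - aligned.eaf) - exposure_rec.eaf)
    if flip < keep:
        return Alignment(-aligned.beta, aligned.se, 1.0 - aligned.eaf,
                         aligned.action)
    return aligned


def harmonize_dataset(exposure: AssociationTable, outcome: AssociationTable,
                      proxy_map: ProxyMap | None = None,
                      options: HarmonizeOptions | None = None) -> HarmonizedSet:
    """Harmonize an instrument (exposure) table against an outcome table.

    Proxy substitution is attempted first for variants missing from the
    outcome and for ambiguous palindromic variants; allele alignment and
    palindromic classification follow.  Ambiguous palindromic variants
    without an acceptable proxy are dropped.  Ordering of retained variants
    follows the exposure table.  Every decision is recorded in the audit
    log; ``retained + dropped`` always partitions the exposure variants.
    """
    opts = options or HarmonizeOptions()
    pmap = proxy_map or ProxyMap()
    window = opts.ambiguity_window

    def needs_proxy(exp_rec: VariantAssociation) -> str | None:
        """Return the reason a proxy is required, or None."""
        out_rec = outcome.get(exp_rec.variant_id)
        if out_rec is None:
            return "missing from outcome"
        if classify_palindromic(exp_rec, window) == PALINDROMIC_AMBIGUOUS \
                or classify_palindromic(out_rec, window) == PALINDROMIC_AMBIGUOUS:
            return "ambiguous palindromic"
        return None

    def proxy_ok(missing_id: str, cand: ProxyEntry) -> bool:
        exp_rec = exposure.get(missing_id)
        proxy_rec = outcome.get(cand.proxy_id)
        if proxy_rec is None:
            return False
        if classify_palindromic(proxy_rec, window) == PALINDROMIC_AMBIGUOUS:
            return False  # ambiguous proxies are skipped (next candidate tried)
        mapped = _remap_proxy_record(exp_rec, proxy_rec, cand)
        if mapped is None:
            return False
        try:
            align_alleles(exp_rec, mapped)
        except AlleleMismatch:
            return False
        return True

    proxy_needed = {}
    for rec in exposure:
        reason = needs_proxy(rec)
        if reason is not None:
            proxy_needed[rec.variant_id] = reason
    plan = substitute_proxies(
        list(proxy_needed), set(outcome.variant_ids) - set(proxy_needed),
        pmap, r2_min=opts.r2_min, validator=proxy_ok,
    )

    variants: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []
    audit: list[str] = []
    for rec in exposure:
        vid = rec.variant_id
        if vid in proxy_needed:
            entry = plan.substitutions.get(vid)
            if entry is None:
                dropped.append((vid, proxy_needed[vid]))
                audit.append(f"{vid}\tdropped\t{proxy_needed[vid]}")
                continue
            out_rec = _remap_proxy_record(rec, outcome.get(entry.proxy_id), entry)
            aligned = align_alleles(rec, out_rec)
            variants.append(HarmonizedVariant(
                vid, rec.beta, rec.se, aligned.beta, aligned.se,
                rec.eaf if rec.eaf is not None else aligned.eaf,
                "proxy_substituted"))
            audit.append(f"{vid}\tproxy_substituted\t{entry.proxy_id}"
                         f"\tr2={entry.r2}")
            continue
        out_rec = outcome.get(vid)
        try:
            aligned = align_alleles(rec, out_rec)
        except AlleleMismatch as exc:
            dropped.append((vid, str(exc)))
            audit.append(f"{vid}\tdropped\tallele mismatch")
            continue
        status = classify_palindromic(rec, window)
        if status == PALINDROMIC_INFERABLE:
            if opts.infer_palindromic:
                aligned = _freq_orient(rec, aligned)
                audit.append(f"{vid}\t{aligned.action}\tpalindromic "
                             f"oriented by frequency")
            else:
                dropped.append((vid, "palindromic (inference disabled)"))
                audit.append(f"{vid}\tdropped\tpalindromic")
                continue
        else:
            audit.append(f"{vid}\t{aligned.action}")
        variants.append(HarmonizedVariant(
            vid, rec.beta, rec.se, aligned.beta, aligned.se,
            rec.eaf if rec.eaf is not None else aligned.eaf, aligned.action))

    if not variants:
        raise DataError(
            f"no usable instruments for {exposure.trait_id} on {outcome.trait_id}"
        )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, variants,
                         dropped, audit)
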