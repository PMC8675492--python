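import numpy as np
import pytest

from mrkit.harmonize import HarmonizedSet
from mrkit.sumstats import AssociationTable, VariantAssociation


def make_record(variant_id="rs1", effect_allele="A", other_allele="G",
                beta=0.05, se=0.005, pvalue=1e-20, eaf=0.3, n=450_000,
                trait_id="exposure", unit_sd=None):
    return VariantAssociation(
        variant_id=variant_id, effect_allele=effect_allele,
        other_allele=other_allele, beta=beta, se=se, pvalue=pvalue,
        eaf=eaf, n=n, trait_id=trait_id, unit_sd=unit_sd)


def make_table(records, trait_id="trait", trait_type="continuous", **kw):
    return AssociationTable(trait_id=trait_id, records=records,
                            trait_type=trait_type, **kw)


@pytest.fixture
def worked_example_set():
    """The two-SNP hand-computed example: theta=0.3, Q=2, phi=2."""
    return HarmonizedSet.from_arrays(
        beta_x=[0.1, 0.1], se_x=[0.01, 0.01],
        beta_y=[0.02, 0.04], se_y=[0.01, 0.01])


@pytest.fixture
def random_hset():
    """A well-conditioned random harmonized set (L = 8)."""
    rng = np.random.default_rng(42)
    L = 8
    bx = rng.uniform(0.02, 0.1, L) * rng.choice([-1, 1], L)
    return HarmonizedSet.from_arrays(
        beta_x=bx, se_x=rng.uniform(0.002, 0.01, L),
        beta_y=0.3 * bx + rng.normal(0, 0.01, L),
        se_y=rng.uniform(0.005, 0.02, L))


@pytest.fixture
def concordant_pair():
    """Three variants with identical allele coding in both tables."""
    exp = make_table(
        [make_record("rs1", "A", "G", beta=0.05),
         make_record("rs2", "T", "C", beta=0.04),
         make_record("rs3", "G", "C", beta=0.03, eaf=0.2)],
        trait_id="bp")
    out = make_table(
        [make_record("rs1", "A", "G", beta=0.01, se=0.004, trait_id="cancer"),
         make_record("rs2", "T", "C", beta=0.02, se=0.004, trait_id="cancer"),
         make_record("rs3", "G", "C", beta=0.005, se=0.004, eaf=0.2,
                     trait_id="cancer")],
        trait_id="cancer", trait_type="binary")
    return exp, out
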