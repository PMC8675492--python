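import pytest

from mrkit.errors import DataError
from mrkit.harmonize import (PALINDROMIC_AMBIGUOUS, PALINDROMIC_INFERABLE,
                             NOT_PALINDROMIC, AlleleMismatch, HarmonizeOptions,
                             ProxyEntry, ProxyMap, align_alleles,
                             classify_palindromic, harmonize_dataset,
                             read_proxy_map, substitute_proxies)

from conftest import make_record, make_table


class TestAlignAlleles:
    def test_direct(self):
        exp = make_record("rs1", "A", "G", beta=0.05)
        out = make_record("rs1", "A", "G", beta=0.02, eaf=0.3)
        a = align_alleles(exp, out)
        assert a.action == "direct"
        assert a.beta == 0.02
        assert a.eaf == 0.3

    def test_swapped(self):
        exp = make_record("rs1", "A", "G")
        out = make_record("rs1", "G", "A", beta=0.02, eaf=0.3)
        a = align_alleles(exp, out)
        assert a.action == "swapped"
        assert a.beta == -0.02
        assert a.eaf == pytest.approx(0.7)

    def test_strand_flipped(self):
        # reverse complement of A/G is T/C
        exp = make_record("rs1", "A", "G")
        out = make_record("rs1", "T", "C", beta=0.02)
        a = align_alleles(exp, out)
        assert a.action == "strand_flipped"
        assert a.beta == 0.02

    def test_swapped_and_flipped(self):
        exp = make_record("rs1", "A", "G")
        out = make_record("rs1", "C", "T", beta=0.02, eaf=0.25)
        a = align_alleles(exp, out)
        assert a.action == "swapped_and_flipped"
        assert a.beta == -0.02
        assert a.eaf == pytest.approx(0.75)

    def test_mismatch(self):
        exp = make_record("rs1", "A", "G")
        out = make_record("rs1", "A", "C", beta=0.02)
        with pytest.raises(AlleleMismatch, match="mismatch"):
            align_alleles(exp, out)

    def test_non_snp_rejected(self):
        exp = make_record("rs1", "AT", "G")
        out = make_record("rs1", "AT", "G", beta=0.02)
        with pytest.raises(AlleleMismatch, match="non-SNP"):
            align_alleles(exp, out)

    def test_swap_involution(self):
        """Aligning a swapped record then re-swapping restores it."""
        exp = make_record("rs1", "A", "G")
        out = make_record("rs1", "G", "A", beta=0.02, eaf=0.3)
        a = align_alleles(exp, out)
        back = make_record("rs1", "G", "A", beta=-a.beta, eaf=1 - a.eaf)
        assert back.beta == 0.02 and back.eaf == pytest.approx(0.3)


class TestClassifyPalindromic:
    @pytest.mark.parametrize("ea,oa,eaf,expected", [
        ("A", "G", 0.50, NOT_PALINDROMIC),
        ("A", "T", 0.50, PALINDROMIC_AMBIGUOUS),
        ("C", "G", 0.30, PALINDROMIC_INFERABLE),
        ("T", "A", 0.43, PALINDROMIC_AMBIGUOUS),
        # window endpoints are exclusive: exactly 0.42 / 0.58 is inferable
        ("A", "T", 0.42, PALINDROMIC_INFERABLE),
        ("A", "T", 0.58, PALINDROMIC_INFERABLE),
        ("G", "C", 0.70, PALINDROMIC_INFERABLE),
    ])
    def test_cases(self, ea, oa, eaf, expected):
        assert classify_palindromic(make_record("rs1", ea, oa, eaf=eaf)) == expected

    def test_missing_eaf_is_ambiguous(self):
        assert classify_palindromic(
            make_record("rs1", "A", "T", eaf=None)) == PALINDROMIC_AMBIGUOUS

    def test_custom_window(self):
        rec = make_record("rs1", "A", "T", eaf=0.45)
        assert classify_palindromic(rec, (0.49, 0.51)) == PALINDROMIC_INFERABLE


class TestSubstituteProxies:
    def test_best_r2_chosen(self):
        pm = ProxyMap({"rs2": [ProxyEntry("rs8", 0.85, {"A": "A", "G": "G"}),
                               ProxyEntry("rs9", 0.92, {"A": "A", "G": "G"})]})
        plan = substitute_proxies(["rs2"], {"rs8", "rs9"}, pm)
        assert plan.substitutions["rs2"].proxy_id == "rs9"

    def test_below_threshold_dropped(self):
        pm = ProxyMap({"rs2": [ProxyEntry("rs9", 0.7, {"A": "A", "G": "G"})]})
        plan = substitute_proxies(["rs2"], {"rs9"}, pm)
        assert plan.dropped == [("rs2", "no proxy")]

    def test_present_variant_skipped(self):
        pm = ProxyMap({"rs1": [ProxyEntry("rs9", 0.95, {"A": "A", "G": "G"})]})
        plan = substitute_proxies(["rs1"], {"rs1", "rs9"}, pm)
        assert plan.substitutions == {} and plan.dropped == []

    def test_absent_proxy_falls_through(self):
        pm = ProxyMap({"rs2": [ProxyEntry("rs9", 0.95, {"A": "A", "G": "G"}),
                               ProxyEntry("rs8", 0.85, {"A": "A", "G": "G"})]})
        plan = substitute_proxies(["rs2"], {"rs8"}, pm)
        assert plan.substitutions["rs2"].proxy_id == "rs8"

    def test_validator_rejects_candidate(self):
        pm = ProxyMap({"rs2": [ProxyEntry("rs9", 0.95, {"A": "A", "G": "G"}),
                               ProxyEntry("rs8", 0.85, {"A": "A", "G": "G"})]})
        plan = substitute_proxies(["rs2"], {"rs8", "rs9"}, pm,
                                  validator=lambda v, c: c.proxy_id != "rs9")
        assert plan.substitutions["rs2"].proxy_id == "rs8"

    def test_bad_r2_rejected(self):
        with pytest.raises(DataError):
            ProxyEntry("rs9", 1.2, {"A": "A"})


class TestHarmonizeDataset:
    def test_concordant(self, concordant_pair):
        exp, out = concordant_pair
        h = harmonize_dataset(exp, out)
        assert h.n_snps == 3
        assert all(v.action == "direct" for v in h.variants)
        assert h.dropped == []

    def test_ambiguous_palindromic_dropped(self):
        exp = make_table(
            [make_record("rs1", "A", "G"),
             make_record("rs2", "A", "T", eaf=0.5),
             make_record("rs3", "G", "C", eaf=0.2)],
            trait_id="bp")
        out = make_table(
            [make_record("rs1", "A", "G", beta=0.01, trait_id="c"),
             make_record("rs2", "A", "T", beta=0.01, eaf=0.5, trait_id="c"),
             make_record("rs3", "G", "C", beta=0.01, eaf=0.2, trait_id="c")],
            trait_id="c")
        h = harmonize_dataset(exp, out)
        assert h.n_snps == 2
        assert h.dropped == [("rs2", "ambiguous palindromic")]

    def test_partition_invariant(self, concordant_pair):
        exp, out = concordant_pair
        h = harmonize_dataset(exp, out)
        assert h.n_snps + len(h.dropped) == len(exp)

    def test_idempotent(self, concordant_pair):
        """Harmonizing an already-harmonized pair changes nothing."""
        exp, out = concordant_pair
        h1 = harmonize_dataset(exp, out)
        # rebuild tables from the harmonized set, same allele coding
        exp2 = make_table(
            [make_record(v.variant_id, exp.get(v.variant_id).effect_allele,
                         exp.get(v.variant_id).other_allele, beta=v.beta_x,
                         se=v.se_x, eaf=v.eaf) for v in h1.variants],
            trait_id="bp")
        out2 = make_table(
            [make_record(v.variant_id, exp.get(v.variant_id).effect_allele,
                         exp.get(v.variant_id).other_allele, beta=v.beta_y,
                         se=v.se_y, eaf=v.eaf, trait_id="c")
             for v in h1.variants],
            trait_id="c")
        h2 = harmonize_dataset(exp2, out2)
        assert [v.beta_y for v in h2.variants] == [v.beta_y for v in h1.variants]
        assert all(v.action == "direct" for v in h2.variants)

    def test_missing_variant_uses_proxy(self):
        exp = make_table([make_record("rs1", "A", "G", beta=0.05)],
                         trait_id="bp")
        out = make_table(
            [make_record("rs9", "T", "C", beta=0.02, eaf=0.3, trait_id="c")],
            trait_id="c")
        pm = ProxyMap({"rs1": [ProxyEntry("rs9", 0.95,
                                          {"A": "T", "G": "C"})]})
        h = harmonize_dataset(exp, out, pm)
        assert h.n_snps == 1
        v = h.variants[0]
        assert v.action == "proxy_substituted"
        assert v.variant_id == "rs1"
        assert v.beta_y == 0.02  # direct orientation after allele remapping

    def test_proxy_swapped_orientation(self):
        # proxy record's effect allele maps to the exposure's OTHER allele
        exp = make_table([make_record("rs1", "A", "G", beta=0.05)],
                         trait_id="bp")
        out = make_table(
            [make_record("rs9", "C", "T", beta=0.02, eaf=0.3, trait_id="c")],
            trait_id="c")
        pm = ProxyMap({"rs1": [ProxyEntry("rs9", 0.95,
                                          {"A": "T", "G": "C"})]})
        h = harmonize_dataset(exp, out, pm)
        assert h.variants[0].beta_y == -0.02

    def test_no_proxy_dropped(self):
        exp = make_table([make_record("rs1", "A", "G"),
                          make_record("rs2", "T", "C")], trait_id="bp")
        out = make_table([make_record("rs1", "A", "G", beta=0.01,
                                      trait_id="c")], trait_id="c")
        h = harmonize_dataset(exp, out)
        assert h.n_snps == 1
        assert h.dropped == [("rs2", "missing from outcome")]

    def test_ambiguous_proxy_skipped(self):
        """A proxy that is itself ambiguous palindromic is not used."""
        exp = make_table([make_record("rs1", "A", "G")], trait_id="bp")
        out = make_table(
            [make_record("rs9", "A", "T", beta=0.02, eaf=0.5, trait_id="c")],
            trait_id="c")
        pm = ProxyMap({"rs1": [ProxyEntry("rs9", 0.95, {"A": "A", "G": "T"})]})
        with pytest.raises(DataError, match="no usable"):
            harmonize_dataset(exp, out, pm)

    def test_inferable_palindromic_frequency_orientation(self):
        exp = make_table([make_record("rs1", "A", "T", eaf=0.1),
                          make_record("rs2", "A", "G", eaf=0.5)],
                         trait_id="bp")
        out = make_table(
            [make_record("rs1", "A", "T", beta=0.02, eaf=0.9, trait_id="c"),
             make_record("rs2", "A", "G", beta=0.01, eaf=0.5, trait_id="c")],
            trait_id="c")
        h = harmonize_dataset(exp, out)
        v = h.variants[0]
        # outcome EAF 0.9 matches exposure 0.1 only after flipping
        assert v.beta_y == -0.02
        assert v.eaf == pytest.approx(0.1)

    def test_inference_disabled_drops_palindromic(self):
        exp = make_table([make_record("rs1", "A", "T", eaf=0.1),
                          make_record("rs2", "A", "G", eaf=0.5)],
                         trait_id="bp")
        out = make_table(
            [make_record("rs1", "A", "T", beta=0.02, eaf=0.9, trait_id="c"),
             make_record("rs2", "A", "G", beta=0.01, eaf=0.5, trait_id="c")],
            trait_id="c")
        h = harmonize_dataset(exp, out,
                              options=HarmonizeOptions(infer_palindromic=False))
        assert h.variant_ids == ["rs2"]

    def test_empty_retained_errors(self):
        exp = make_table([make_record("rs1", "A", "G")], trait_id="bp")
        out = make_table([make_record("rs2", "A", "G", beta=0.01,
                                      trait_id="c")], trait_id="c")
        with pytest.raises(DataError, match="no usable instruments"):
            harmonize_dataset(exp, out)

    def test_audit_log_written(self, concordant_pair):
        exp, out = concordant_pair
        h = harmonize_dataset(exp, out)
        assert len(h.audit) == 3


def test_read_proxy_map(tmp_path):
    p = tmp_path / "proxies.tsv"
    p.write_text("missing_id\tproxy_id\tr2\tallele_map\n"
                 "rs1\trs9\t0.95\tA=G,C=T\n"
                 "rs1\trs8\t0.85\tA=A,C=C\n")
    pm = read_proxy_map(p)
    cands = pm.candidates("rs1")
    assert [c.proxy_id for c in cands] == ["rs9", "rs8"]
    assert cands[0].allele_map == {"A": "G", "C": "T"}


def test_read_proxy_map_missing_columns(tmp_path):
    p = tmp_path / "proxies.tsv"
    p.write_text("missing_id\tproxy_id\n" "rs1\trs9\n")
    with pytest.raises(DataError, match="missing columns"):
        read_proxy_map(p)
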