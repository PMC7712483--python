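"""Variant normalization, KB lookup, and genotype parsing."""

import re

import pytest

from pompe_nbs.errors import MalformedGenotypeError, VariantParseError
from pompe_nbs.variants import (SPLICE_VARIANT, Genotype, VariantClass,
                                build_kb, classify_variant,
                                normalize_variant_string, parse_genotype)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("c.32-13T>G", "c.-32-13T>G"),     # splice spelled without leading "-"
        ("c.-32-13 T>G", "c.-32-13T>G"),   # internal space removed
        ("c. 1655 T>C", "c.1655T>C"),
        ("c.2238G>C", "c.2238G>C"),        # identity
        ("  c.546G>A ", "c.546G>A"),
        ("1655T>C", "1655T>C"),            # bare spellings stay verbatim
    ],
)
def test_normalize_variant_string(raw, expected):
    assert normalize_variant_string(raw) == expected


@pytest.mark.parametrize("bad", ["", "   ", None])
def test_normalize_rejects_empty(bad):
    with pytest.raises(VariantParseError):
        normalize_variant_string(bad)


class TestClassify:
    def test_known_entries(self, kb):
        assert classify_variant("c.-32-13T>G", kb) is VariantClass.PATHOGENIC
        assert classify_variant("c.2238G>C", kb) is VariantClass.PATHOGENIC
        assert classify_variant("c.2065G>A", kb) is VariantClass.PSEUDODEFICIENCY
        assert classify_variant("c.1726G>A", kb) is VariantClass.PSEUDODEFICIENCY

    def test_absent_is_unknown_never_pathogenic(self, kb):
        assert classify_variant("c.999X>Y", kb) is VariantClass.UNKNOWN

    def test_lookup_is_pure(self, kb):
        first = classify_variant("c.692+3G>C", kb)
        assert all(classify_variant("c.692+3G>C", kb) is first for _ in range(3))

    def test_verbatim_spelling_precedes_normalized(self, kb):
        # the same position was reported with conflicting classes under two
        # spellings; the spaced verbatim spelling keeps its own class
        _, via_verbatim = kb.classify_token("c.546 G>A")
        _, via_normalized = kb.classify_token("c.546G>A")
        assert via_verbatim is VariantClass.PATHOGENIC
        assert via_normalized is VariantClass.VUS


class TestParseGenotype:
    def test_splice_homozygote(self, kb):
        g = parse_genotype("c.-32-13T>G/c.-32-13T>G", kb)
        assert g.n_primary == 2
        assert g.is_homozygous_for(SPLICE_VARIANT)
        assert g.in_cis_extras == ()

    def test_pseudodeficiency_rider_in_slash_list(self, kb):
        g = parse_genotype("c.2238G>C/c.2281delGinsAT/ c.2065G>A", kb)
        assert [str(a) for a in g.primary_alleles] == ["c.2238G>C", "c.2281delGinsAT"]
        assert [v.hgvs_c for v in g.in_cis_extras] == ["c.2065G>A"]

    def test_semicolon_cis_riders(self, kb):
        g = parse_genotype("c.2238G>C; c.2065G>A /c.2238G>C; c.2065G>A", kb)
        assert g.n_primary == 2
        assert g.is_homozygous_for("c.2238G>C")
        assert len(g.in_cis_extras) == 2

    def test_cis_vus_pair_is_one_allele(self, kb):
        g = parse_genotype("c.-32-13T>G/c.266G>A;c.1377C>G", kb)
        assert g.n_primary == 2
        assert g.primary_alleles[1].classification is VariantClass.VUS
        assert len(g.primary_alleles[1].variants) == 2

    def test_parenthesized_pseudodeficiency_group(self, kb):
        g = parse_genotype("c.-32-13T>G/c.705G>A/c.(1726G>A;c.2065G>A)", kb)
        assert g.n_primary == 2
        assert sorted(v.hgvs_c for v in g.in_cis_extras) == ["c.1726G>A", "c.2065G>A"]
        assert g.has_pseudodeficiency

    def test_multiallelic_shorthand_is_opaque(self, kb):
        g = parse_genotype("c.2236T>C/c.700A>G/C", kb)
        assert g.n_primary == 2
        assert g.primary_alleles[1].variants[0].hgvs_c == "c.700A>G/C"
        assert g.primary_alleles[1].classification is VariantClass.VUS

    def test_empty_genotype(self, kb):
        g = parse_genotype("", kb)
        assert g == Genotype(raw="")
        assert g.is_empty

    def test_three_primary_alleles_rejected(self, kb):
        with pytest.raises(MalformedGenotypeError):
            parse_genotype("c.2238G>C/c.-32-13T>G/c.2560C>T", kb)

    def test_benign_rider_excluded_from_primaries(self, kb):
        g = parse_genotype("c.784G>A/c.859-19G>A/c.1392G>C", kb)
        assert g.n_primary == 2
        assert [v.hgvs_c for v in g.in_cis_extras] == ["c.859-19G>A"]


def _raw_tokens(raw: str) -> list[str]:
    """Independent tokenization of a genotype string for round-trip checks."""
    text = raw
    for m in re.finditer(r"c\.\(([^)]*)\)", raw):
        inner = ";".join(
            t if t.strip().startswith("c.") else "c." + t.strip()
            for t in m.group(1).split(";")
        )
        text = text.replace(m.group(0), inner)
    text = text.replace("A>G/C", "A>G|C")
    tokens = [t for seg in text.split("/") for t in seg.split(";") if t.strip()]
    return sorted(normalize_variant_string(t.replace("|", "/")) for t in tokens)


def test_fixture_genotypes_round_trip(fixtures, kb):
    """Every packaged genotype parses, and the parsed token multiset equals
    the raw string's token multiset."""
    for rec in fixtures.all_records:
        g = parse_genotype(rec.genotype_raw, kb)
        assert sorted(g.tokens()) == _raw_tokens(rec.genotype_raw), rec.id
        assert 1 <= g.n_primary <= 2


def test_splice_allele_counts_in_fixtures(fixtures, kb):
    """12/31 LOPD genotypes are splice-homozygous; 23/31 carry >=1 splice
    allele (74% of confirmed LOPD)."""
    lopd = [r for r in fixtures.table2 if not r.cardiomyopathy_or_symptoms]
    genos = [parse_genotype(r.genotype_raw, kb) for r in lopd]
    assert len(genos) == 31
    assert sum(g.is_homozygous_for(SPLICE_VARIANT) for g in genos) == 12
    assert sum(g.has_allele(SPLICE_VARIANT) for g in genos) == 23


def test_kb_covers_all_fixture_variants(fixtures, kb):
    for rec in fixtures.all_records:
        g = parse_genotype(rec.genotype_raw, kb)
        for v in g.all_variants():
            assert v.classification is not VariantClass.UNKNOWN, v.hgvs_c


def test_build_kb_rejects_bad_class():
    with pytest.raises(ValueError):
        build_kb({"c.1A>G": "definitely_bad"})
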