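"""SNV calling, substitution classification and the filter cascade."""

import itertools

import pandas as pd
import pytest

from estmarker import (
    FilterParams,
    ReadObservation,
    SNVCallParams,
    SNVKind,
    Substitution,
    Unigene,
    apply_filters,
    call_snvs,
    classify_substitution,
    select_candidates,
)
from estmarker.snv_pipeline import SNV


def _obs(uid, pos, genotype, allele, n, bq=30, mq=40, start=0):
    return [
        ReadObservation(uid, pos, genotype, f"r{start + i}", allele, bq, mq)
        for i in range(n)
    ]


UNIGENES = {"u1": Unigene(id="u1", seq="ACGT" * 250)}  # 1000 bp


def test_clean_biallelic_site_is_called():
    obs = _obs("u1", 500, "MU16", "A", 3) + _obs("u1", 500, "UPV196", "G", 3, start=3)
    [snv] = call_snvs(obs, UNIGENES)
    assert snv.kind is SNVKind.SNP
    assert snv.qualifying_alleles() == {"A", "G"}
    assert snv.alleles == {"MU16": {"A": (3, 90)}, "UPV196": {"G": (3, 90)}}


def test_singleton_allele_is_suppressed():
    obs = _obs("u1", 500, "MU16", "A", 10) + _obs("u1", 500, "UPV196", "T", 1, bq=20, start=10)
    assert call_snvs(obs, UNIGENES) == []


def test_accumulated_quality_threshold():
    # two reads at q15 each: count passes but accumulated 30 < 40
    obs = _obs("u1", 500, "MU16", "A", 5) + _obs("u1", 500, "UPV196", "G", 2, bq=15, start=5)
    assert call_snvs(obs, UNIGENES) == []
    # q20 each: accumulated 40 qualifies
    obs = _obs("u1", 500, "MU16", "A", 5) + _obs("u1", 500, "UPV196", "G", 2, bq=20, start=5)
    assert len(call_snvs(obs, UNIGENES)) == 1


def test_low_mapping_quality_reads_are_discarded():
    obs = _obs("u1", 500, "MU16", "A", 5) + _obs("u1", 500, "UPV196", "G", 5, mq=10, start=5)
    assert call_snvs(obs, UNIGENES) == []


def test_within_genotype_variability_feeds_nvsm():
    obs = (
        _obs("u1", 500, "MU16", "A", 5)
        + _obs("u1", 500, "MU16", "G", 5, start=5)
        + _obs("u1", 500, "UPV196", "A", 5, start=10)
    )
    [snv] = call_snvs(obs, UNIGENES)
    assert set(snv.alleles["MU16"]) == {"A", "G"}
    apply_filters([snv], UNIGENES)
    assert "NVSM2" in snv.filters and "NVSM1" not in snv.filters


def test_unsequenced_genotype_feeds_nvsm():
    obs = _obs("u1", 500, "MU16", "A", 5) + _obs("u1", 500, "MU16", "G", 5, start=5)
    [snv] = call_snvs(obs, UNIGENES)
    apply_filters([snv], UNIGENES)
    assert "NVSM1" in snv.filters  # UPV196 not sequenced here


def test_indel_token_gives_vks():
    obs = _obs("u1", 500, "MU16", "-", 3) + _obs("u1", 500, "UPV196", "G", 3, start=3)
    [snv] = call_snvs(obs, UNIGENES)
    assert snv.kind is SNVKind.DELETION
    apply_filters([snv], UNIGENES)
    assert "VKS" in snv.filters


def test_observation_beyond_unigene_length_is_an_error():
    with pytest.raises(ValueError, match="beyond"):
        call_snvs(_obs("u1", 1000, "MU16", "A", 2), UNIGENES)


def test_call_order_independence():
    obs = (
        _obs("u1", 500, "MU16", "A", 3)
        + _obs("u1", 500, "UPV196", "G", 3, start=3)
        + _obs("u1", 700, "MU16", "C", 3, start=6)
        + _obs("u1", 700, "UPV196", "T", 3, start=9)
    )
    base = call_snvs(obs, UNIGENES)
    shuffled = call_snvs(list(reversed(obs)), UNIGENES)
    assert [(s.unigene_id, s.pos, s.pooled) for s in base] == [
        (s.unigene_id, s.pos, s.pooled) for s in shuffled
    ]


def test_call_accepts_dataframe_and_stream_equally():
    obs = _obs("u1", 500, "MU16", "A", 3) + _obs("u1", 500, "UPV196", "G", 3, start=3)
    df = pd.DataFrame(
        [(o.unigene_id, o.pos, o.genotype, o.read_id, o.allele, o.base_quality, o.mapping_quality) for o in obs],
        columns=["unigene_id", "pos", "genotype", "read_id", "allele", "base_qual", "map_qual"],
    )
    assert [s.pooled for s in call_snvs(df, UNIGENES)] == [s.pooled for s in call_snvs(obs, UNIGENES)]


def test_classify_substitution_pairs_and_symmetry():
    assert classify_substitution("A", "G") is Substitution.TRANSITION
    assert classify_substitution("C", "T") is Substitution.TRANSITION
    assert classify_substitution("C", "G") is Substitution.TRANSVERSION
    transitions = 0
    for a, b in itertools.permutations("ACGT", 2):
        assert classify_substitution(a, b) is classify_substitution(b, a)
        transitions += classify_substitution(a, b) is Substitution.TRANSITION
    assert transitions == 4  # A<->G and C<->T, both orders
    with pytest.raises(ValueError):
        classify_substitution("A", "A")


def _bare_snv(uid, pos, kind=SNVKind.SNP, genotype_alleles=None, n_obs=None):
    ga = genotype_alleles or {"MU16": {"A": (3, 90)}, "UPV196": {"G": (3, 90)}}
    return SNV(
        unigene_id=uid, pos=pos, kind=kind, ref="A",
        alleles=ga, pooled={"A": (3, 90), "G": (3, 90)},
        n_obs=n_obs if n_obs is not None else {g: 3 for g in ga},
    )


def test_edge_filter_cl60():
    u = {"u": Unigene(id="u", seq="A" * 500)}
    snv = _bare_snv("u", 30)
    apply_filters([snv], u)
    assert snv.filters == {"CL60"}


def test_proximity_filter_cs60_tags_both():
    u = {"u": Unigene(id="u", seq="A" * 1000)}
    a, b = _bare_snv("u", 100), _bare_snv("u", 150)
    apply_filters([a, b], u)
    assert a.filters == {"CS60"} and b.filters == {"CS60"}
    # at exactly 60 bp the distance is not < 60
    c, d = _bare_snv("u", 400), _bare_snv("u", 460)
    apply_filters([c, d], u)
    assert "CS60" not in c.filters and "CS60" not in d.filters


def test_intron_filter_i60():
    u = {"u": Unigene(id="u", seq="A" * 1000, introns=[500])}
    near, far = _bare_snv("u", 459), _bare_snv("u", 700)
    apply_filters([near, far], u)
    assert "I60" in near.filters and "I60" not in far.filters


def test_hypervariable_unigene_tags_every_snv():
    u = {"u": Unigene(id="u", seq="A" * 100)}
    snvs = [_bare_snv("u", p) for p in (10, 30, 50, 70, 90)]  # 5 per 100 bp > 4
    apply_filters(snvs, u)
    assert all("HVR4" in s.filters for s in snvs)
    assert all("CL60" in s.filters for s in snvs)  # geometry of a 100 bp unigene


def test_sliding_window_hvr4_tags_only_the_dense_cluster():
    u = {"u": Unigene(id="u", seq="A" * 2000)}
    cluster = [500, 510, 520, 530, 540]  # 5 SNVs inside one 100 bp window
    lone = [1500]
    snvs = [_bare_snv("u", p) for p in cluster + lone]
    apply_filters(snvs, u, FilterParams(hv_window_bp=100))
    assert all("HVR4" in s.filters for s in snvs[:5])
    assert "HVR4" not in snvs[5].filters
    # unigene-level rule sees 6 SNVs over 2000 bp (0.3 per 100 bp): no tag
    apply_filters(snvs, u, FilterParams())
    assert not any("HVR4" in s.filters for s in snvs)


def test_filter_tagging_is_idempotent():
    u = {"u": Unigene(id="u", seq="A" * 500)}
    snv = _bare_snv("u", 30)
    apply_filters([snv], u)
    once = set(snv.filters)
    apply_filters([snv], u)
    assert snv.filters == once


def test_filter_monotonicity_under_threshold_sweep():
    """Growing the distance thresholds never shrinks the tagged set, and
    the Golden Gate survivor set never grows."""
    u = {"u": Unigene(id="u", seq="A" * 2000)}
    positions = [70, 200, 500, 900, 1500, 1930]
    prev_tagged, prev_golden = -1, None
    for bp in (10, 40, 60, 100, 200, 500):
        snvs = [_bare_snv("u", p) for p in positions]
        params = FilterParams(proximity_bp=bp, edge_bp=bp, intron_bp=bp)
        apply_filters(snvs, u, params)
        tagged = sum(1 for s in snvs if s.filters)
        golden, _ = select_candidates(snvs)
        assert tagged >= prev_tagged
        if prev_golden is not None:
            assert len(golden) <= prev_golden
        prev_tagged, prev_golden = tagged, len(golden)


def test_select_candidates_rules():
    u = "u"
    clean = _bare_snv(u, 1)
    cef_only = _bare_snv(u, 2)
    cef_only.filters = {"CEF"}
    rejected = _bare_snv(u, 3)
    rejected.filters = {"CS60"}
    golden, caps = select_candidates([clean, cef_only, rejected])
    assert golden == [clean, cef_only]
    assert caps == [clean]
    assert set(id(s) for s in caps) <= set(id(s) for s in golden)
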