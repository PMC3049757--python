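"""Restriction-site matching and CAPS detectability of SNPs."""

import numpy as np
import pytest

from estmarker import DEFAULT_ENZYMES, Enzyme, Unigene, annotate_cef, caps_evaluate, find_sites
from estmarker.snv_pipeline import SNV, SNVKind

from oracles import caps_oracle, revcomp, site_positions

ECORI = next(e for e in DEFAULT_ENZYMES if e.name == "EcoRI")
HINFI = next(e for e in DEFAULT_ENZYMES if e.name == "HinfI")


def test_find_sites_direct_match():
    assert find_sites("AAGAATTCAA", ECORI) == [2]


def test_find_sites_iupac_expansion():
    assert find_sites("TTGACTCTT", HINFI) == [2]  # GACTC matches GANTC


def test_find_sites_absent():
    assert find_sites("AAAAAAAAAA", ECORI) == []


def test_find_sites_reverse_strand_for_nonpalindromic():
    mboii = Enzyme("MboII", "GAAGA", 5)
    seq = "TT" + revcomp("GAAGA") + "TT"  # site only on the bottom strand
    assert find_sites(seq, mboii) == [2]


def test_find_sites_agrees_with_biopython_restriction():
    """Independent cross-check of site matching against Bio.Restriction."""
    from Bio import Restriction
    from Bio.Seq import Seq

    rng = np.random.default_rng(5)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        for enzyme in (ECORI, HINFI):
            bio = getattr(Restriction, enzyme.name)
            expected = sorted(p - 1 - enzyme.cut_offset for p in bio.search(Seq(seq)))
            assert find_sites(seq, enzyme) == expected


def _snp(uid, pos, ref, alt):
    return SNV(
        unigene_id=uid, pos=pos, kind=SNVKind.SNP, ref=ref,
        alleles={}, pooled={ref: (3, 90), alt: (3, 90)}, n_obs={},
    )


def test_caps_gain_of_site():
    # GAAT[C/T]C: the T allele completes GAATTC (EcoRI)
    seq = "ACGTG" * 12 + "GAATCC" + "TGCAT" * 12
    u = Unigene(id="u", seq=seq)
    snv = _snp("u", 64, "C", "T")
    hits = caps_evaluate(snv, u, [ECORI])
    assert [(h.enzyme, h.allele_with_site, h.site_position) for h in hits] == [("EcoRI", "T", 60)]
    # fragment lengths per allele sum to the window length
    for fr in hits[0].fragment_lengths.values():
        assert sum(fr) == 121


def test_caps_no_overlapping_site():
    seq = "ACGTG" * 30
    snv = _snp("u", 75, "G", "A")
    assert caps_evaluate(snv, Unigene(id="u", seq=seq), [ECORI]) == []


def test_caps_distant_shared_site_does_not_mask():
    # EcoRI site far from the SNP in both alleles; no site at the SNP
    seq = "A" * 20 + "GAATTC" + "A" * 40 + "C" + "A" * 40
    u = Unigene(id="u", seq=seq)
    snv = _snp("u", 66, "C", "G")
    assert caps_evaluate(snv, u, [ECORI]) == []


def test_caps_rejects_indels():
    snv = SNV("u", 5, SNVKind.DELETION, "A", {}, {"A": (3, 90), "-": (3, 90)}, {})
    with pytest.raises(ValueError):
        caps_evaluate(snv, Unigene(id="u", seq="A" * 200), DEFAULT_ENZYMES)


def test_caps_strand_symmetry():
    """Reverse-complementing the window (and the alleles) gives the same
    set of distinguishing enzymes."""
    rng = np.random.default_rng(17)
    for _ in range(40):
        seq = "".join(rng.choice(list("ACGT"), size=121))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        seq = seq[:60] + ref + seq[61:]
        fwd = Unigene(id="u", seq=seq)
        rev = Unigene(id="u", seq=revcomp(seq))
        comp = dict(zip("ACGT", "TGCA"))
        hits_f = {h.enzyme for h in caps_evaluate(_snp("u", 60, ref, alt), fwd, DEFAULT_ENZYMES)}
        hits_r = {h.enzyme for h in caps_evaluate(_snp("u", 60, comp[ref], comp[alt]), rev, DEFAULT_ENZYMES)}
        assert hits_f == hits_r


def test_caps_matches_digestion_oracle_sample():
    rng = np.random.default_rng(23)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=121))
        ref, alt = (str(b) for b in rng.choice(list("ACGT"), size=2, replace=False))
        seq = seq[:60] + ref + seq[61:]
        u = Unigene(id="u", seq=seq)
        hits = {h.enzyme for h in caps_evaluate(_snp("u", 60, ref, alt), u, DEFAULT_ENZYMES)}
        assert hits == caps_oracle(seq, 60, (ref, alt), DEFAULT_ENZYMES)


def test_annotate_cef_rules():
    seq = "ACGTG" * 12 + "GAATCC" + "TGCAT" * 12
    u = {"u": Unigene(id="u", seq=seq)}
    detectable = _snp("u", 64, "C", "T")
    hidden = _snp("u", 30, "G", "A")
    indel = SNV("u", 40, SNVKind.DELETION, "T", {}, {"T": (3, 90), "-": (3, 90)}, {}, {"VKS"})
    annotate_cef([detectable, hidden, indel], u, [ECORI])
    assert "CEF" not in detectable.filters
    assert "CEF" in hidden.filters
    assert indel.filters == {"VKS"}  # indels never receive CEF


def test_empty_enzyme_table_tags_everything():
    u = {"u": Unigene(id="u", seq="ACGT" * 50)}
    snvs = [_snp("u", p, "G", "A") for p in (50, 100, 150)]
    annotate_cef(snvs, u, [])
    assert all("CEF" in s.filters for s in snvs)


def test_bigger_enzyme_table_never_increases_cef_count():
    rng = np.random.default_rng(31)
    snvs, unigenes = [], {}
    for i in range(30):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        ref = seq[100]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        uid = f"u{i}"
        unigenes[uid] = Unigene(id=uid, seq=seq)
        snvs.append(_snp(uid, 100, ref, alt))
    counts = []
    for n_enzymes in (0, 5, 12, len(DEFAULT_ENZYMES)):
        annotate_cef(snvs, unigenes, DEFAULT_ENZYMES[:n_enzymes])
        counts.append(sum(1 for s in snvs if "CEF" in s.filters))
    assert counts == sorted(counts, reverse=True)


def test_enzyme_validation():
    with pytest.raises(ValueError):
        Enzyme("bad", "GAT", 1)  # too short
    with pytest.raises(ValueError):
        Enzyme("bad", "GAXTC", 1)  # not IUPAC
    assert ECORI.is_palindromic and not Enzyme("MboII", "GAAGA", 5).is_palindromic
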