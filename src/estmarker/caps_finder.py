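"""CAPS detectability of SNPs via allele-differential restriction sites.

A SNP can be scored as a CAPS (cleaved amplified polymorphic sequence)
marker when one of its alleles creates or destroys a restriction-enzyme
recognition site spanning the SNP, so that digesting the amplicon yields
allele-distinguishable fragment patterns on a gel.  SNPs for which no
enzyme in the panel produces such an allele-specific site receive the
CEF tag and drop out of the CAPS candidate set.

Recognition sites are IUPAC strings matched on both strands; only sites
*overlapping* the SNP position count as allele-specific, so shared
distant sites never mask detectability.  The scan window defaults to
60 bp each side of the SNP, matching the 60 bp flank-cleanliness logic
of the filter cascade.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping

from .io_formats import Unigene
from .snv_pipeline import SNV, SNVKind

__all__ = [
    "Enzyme",
    "CAPSHit",
    "DEFAULT_ENZYMES",
    "find_sites",
    "caps_evaluate",
    "annotate_cef",
    "load_enzymes_tsv",
]

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclasses.dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ValueError(f"{self.name}: site must be >= 4 bp")
        if set(site) - set(_IUPAC):
            raise ValueError(f"{self.name}: non-IUPAC site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.name}: cut offset outside site")
        object.__setattr__(self, "site", site)

    @property
    def is_palindromic(self) -> bool:
        rc = self.site.translate(_IUPAC_COMPLEMENT)[::-1]
        return rc == self.site


@dataclasses.dataclass(frozen=True)
class CAPSHit:
    """One enzyme whose digestion distinguishes the two alleles of a SNP."""

    unigene_id: str
    pos: int
    enzyme: str
    allele_with_site: str
    site_position: int
    fragment_lengths: dict[str, tuple[int, ...]]


#: Common inexpensive 4-6-cutters; user-extensible via :func:`load_enzymes_tsv`.
DEFAULT_ENZYMES: tuple[Enzyme, ...] = (
    Enzyme("EcoRI", "GAATTC", 1),
    Enzyme("HindIII", "AAGCTT", 1),
    Enzyme("BamHI", "GGATCC", 1),
    Enzyme("EcoRV", "GATATC", 3),
    Enzyme("PstI", "CTGCAG", 5),
    Enzyme("KpnI", "GGTACC", 5),
    Enzyme("SalI", "GTCGAC", 1),
    Enzyme("XbaI", "TCTAGA", 1),
    Enzyme("SpeI", "ACTAGT", 1),
    Enzyme("DraI", "TTTAAA", 3),
    Enzyme("SspI", "AATATT", 3),
    Enzyme("TaqI", "TCGA", 1),
    Enzyme("MseI", "TTAA", 1),
    Enzyme("MboI", "GATC", 0),
    Enzyme("MspI", "CCGG", 1),
    Enzyme("HhaI", "GCGC", 3),
    Enzyme("AluI", "AGCT", 2),
    Enzyme("RsaI", "GTAC", 2),
    Enzyme("HaeIII", "GGCC", 2),
    Enzyme("HinfI", "GANTC", 1),
    Enzyme("DdeI", "CTNAG", 1),
    Enzyme("ScrFI", "CCNGG", 2),
)


def _site_regex(site: str) -> re.Pattern:
    pattern = "".join(f"[{_IUPAC[c]}]" if len(_IUPAC[c]) > 1 else _IUPAC[c] for c in site)
    return re.compile(f"(?=({pattern}))")


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """All top-strand start positions where the enzyme site occurs.

    IUPAC codes are expanded; overlapping occurrences are all reported.
    Palindromic sites are matched once; non-palindromic sites are also
    matched on the reverse complement and reported in top-strand
    coordinates (leftmost base of the matched segment).
    """
    seq = seq.upper()
    positions = {m.start() for m in _site_regex(enzyme.site).finditer(seq)}
    if not enzyme.is_palindromic:
        rc_site = enzyme.site.translate(_IUPAC_COMPLEMENT)[::-1]
        positions |= {m.start() for m in _site_regex(rc_site).finditer(seq)}
    return sorted(positions)


def _digest(window: str, enzyme: Enzyme) -> tuple[int, ...]:
    """Fragment lengths after cutting the window at every enzyme site."""
    cuts = sorted({p + enzyme.cut_offset for p in find_sites(window, enzyme)})
    cuts = [c for c in cuts if 0 < c < len(window)]
    bounds = [0, *cuts, len(window)]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


def caps_evaluate(
    snv: SNV,
    unigene: Unigene,
    enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES,
    window_bp: int = 60,
) -> list[CAPSHit]:
    """Evaluate one biallelic SNP for CAPS detectability.

    Builds the two allele sequences of the window (``window_bp`` each
    side of the SNP, clipped to the unigene) and reports a hit for every
    enzyme whose set of sites *overlapping the SNP position* differs
    between alleles.  Fragment lengths come from digesting the whole
    window with all sites of that enzyme.
    """
    if snv.kind is not SNVKind.SNP:
        raise ValueError("CAPS evaluation is defined for SNPs only")
    alleles = sorted(snv.qualifying_alleles())
    if len(alleles) != 2:
        raise ValueError("CAPS evaluation requires a biallelic SNP")
    seq = unigene.seq
    lo = max(0, snv.pos - window_bp)
    hi = min(len(seq), snv.pos + window_bp + 1)
    offset = snv.pos - lo
    windows = {a: seq[lo : snv.pos] + a + seq[snv.pos + 1 : hi] for a in alleles}

    hits = []
    for enzyme in enzymes:
        k = len(enzyme.site)
        over = {
            a: {
                p
                for p in find_sites(w, enzyme)
                if p <= offset < p + k
            }
            for a, w in windows.items()
        }
        a1, a2 = alleles
        if over[a1] == over[a2]:
            continue
        gained, other = (a1, a2) if over[a1] - over[a2] else (a2, a1)
        site_pos = min(over[gained] - over[other])
        hits.append(
            CAPSHit(
                unigene_id=snv.unigene_id,
                pos=snv.pos,
                enzyme=enzyme.name,
                allele_with_site=gained,
                site_position=lo + site_pos,
                fragment_lengths={a: _digest(w, enzyme) for a, w in windows.items()},
            )
        )
    return hits


def annotate_cef(
    snvs: Iterable[SNV],
    unigenes: Mapping[str, Unigene],
    enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES,
    window_bp: int = 60,
) -> list[SNV]:
    """Tag every CAPS-incapable biallelic SNP with CEF.

    Indels never receive CEF (they already carry VKS); multi-allelic
    SNPs are left untagged as CAPS scoring is defined pairwise on a
    biallelic site.
    """
    enzymes = tuple(enzymes)
    out = []
    for snv in snvs:
        snv.filters.discard("CEF")
        if snv.kind is SNVKind.SNP and len(snv.qualifying_alleles()) == 2:
            if not caps_evaluate(snv, unigenes[snv.unigene_id], enzymes, window_bp):
                snv.filters.add("CEF")
        out.append(snv)
    return out


def load_enzymes_tsv(path: str | Path) -> list[Enzyme]:
    """Load an enzyme panel from a TSV with columns ``name site cut_offset``."""
    enzymes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            enzymes.append(Enzyme(fields[0], fields[1], int(fields[2])))
    return enzymes
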