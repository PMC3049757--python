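"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the implementation's code paths: the SSR oracle
tests every (position, unit) pair directly on the string, and the CAPS
oracle expands IUPAC sites into concrete strings and uses plain substring
comparison on both strands.
"""

from __future__ import annotations

import functools
import itertools

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _is_power(unit: str) -> bool:
    k = len(unit)
    return any(k % d == 0 and unit == unit[:d] * (k // d) for d in range(1, k))


def ssr_oracle(seq: str, min_units: int = 4, min_total: int = 17) -> list[tuple[int, int, int]]:
    """All maximal perfect tandem repeats passing thresholds, after the
    longer-locus-wins overlap resolution.  Returns (start, end, unit_len)."""
    n = len(seq)
    cands = []
    for k in (2, 3, 4):
        for i in range(n - k):
            unit = seq[i : i + k]
            if "N" in unit or _is_power(unit):
                continue
            # must be the start of a maximal run of period k
            if i > 0 and seq[i - 1] != "N" and seq[i - 1] == seq[i - 1 + k]:
                continue
            if seq[i : i + 2 * k] != unit * 2:
                continue
            j = i + k
            while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
                j += 1
            total = j - i
            if total // k >= min_units and total >= min_total:
                cands.append((i, j, k))
    kept: list[tuple[int, int, int]] = []
    for s, e, k in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[2], c[0])):
        if all(e <= ks or s >= ke for ks, ke, _ in kept):
            kept.append((s, e, k))
    return sorted(kept)


@functools.lru_cache(maxsize=None)
def concrete_sites(site: str) -> set[str]:
    """All concrete DNA strings matching an IUPAC site, on either strand."""
    expansions = {"".join(p) for p in itertools.product(*(IUPAC[c] for c in site))}
    return expansions | {revcomp(s) for s in expansions}


def site_positions(seq: str, site: str) -> set[int]:
    """Start positions of any strand-insensitive occurrence of the site."""
    words = concrete_sites(site)
    k = len(site)
    return {i for i in range(len(seq) - k + 1) if seq[i : i + k] in words}


def caps_oracle(window: str, snp_offset: int, alleles: tuple[str, str], enzymes) -> set[str]:
    """Enzymes whose spanning-site sets differ between the two allele windows.

    An enzyme distinguishes the alleles iff some recognition site that
    overlaps the SNP offset is present in one allele window and not the
    other (distant shared sites are ignored).
    """
    hits = set()
    w = {a: window[:snp_offset] + a + window[snp_offset + 1 :] for a in alleles}
    for enzyme in enzymes:
        k = len(enzyme.site)
        spanning = {
            a: {
                p
                for p in site_positions(w[a], enzyme.site)
                if p <= snp_offset < p + k
            }
            for a in alleles
        }
        if spanning[alleles[0]] != spanning[alleles[1]]:
            hits.add(enzyme.name)
    return hits
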