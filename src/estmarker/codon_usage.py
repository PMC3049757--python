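"""Codon-usage statistics from full-length ORFs.

Works on ORFs that start with ATG, end with a stop codon and contain no
internal stop (the mechanical equivalent of screening predicted coding
regions for frame-shift errors).  Provides the codon count table, GC
content at the third codon position (GC3), the XCG/XCC CpG-suppression
ratio, and stop-codon usage fractions.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

__all__ = [
    "CodonTable",
    "STOP_CODONS",
    "ALL_CODONS",
    "validate_full_orf",
    "build_codon_table",
    "gc3",
    "xcg_xcc_ratio",
    "stop_usage",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple("".join(c) for c in itertools.product("ACGT", repeat=3))


@dataclasses.dataclass
class CodonTable:
    """Codon counts over a set of full-length ORFs.

    Every one of the 64 codons is present as a key (zero counts allowed);
    terminal stop codons are included in the counts.
    """

    counts: dict[str, int]
    n_codons: int
    n_orfs: int


def validate_full_orf(seq: str) -> bool:
    """True iff the sequence is a complete, frame-intact coding region."""
    seq = seq.upper()
    if len(seq) < 6 or len(seq) % 3 != 0:
        return False
    if not seq.startswith("ATG") or seq[-3:] not in STOP_CODONS:
        return False
    if set(seq) - set("ACGT"):
        return False
    return all(seq[i : i + 3] not in STOP_CODONS for i in range(0, len(seq) - 3, 3))


def _codons(seq: str) -> Iterable[str]:
    return (seq[i : i + 3] for i in range(0, len(seq), 3))


def build_codon_table(orfs: Iterable[str]) -> CodonTable:
    """Count every codon (terminal stop included) across the given ORFs."""
    counts = dict.fromkeys(ALL_CODONS, 0)
    n_orfs = 0
    for orf in orfs:
        orf = orf.upper()
        if not validate_full_orf(orf):
            raise ValueError(f"not a full-length ORF: {orf[:30]}...")
        n_orfs += 1
        for codon in _codons(orf):
            counts[codon] += 1
    return CodonTable(counts=counts, n_codons=sum(counts.values()), n_orfs=n_orfs)


def gc3(table: CodonTable, include_stops: bool = False) -> float:
    """Fraction of codons whose third base is G or C.

    Stop codons are excluded by default (they are fixed by termination,
    not by synonymous-site drift); pass ``include_stops=True`` to count
    them too.
    """
    total = gc = 0
    for codon, n in table.counts.items():
        if not include_stops and codon in STOP_CODONS:
            continue
        total += n
        if codon[2] in "GC":
            gc += n
    if total == 0:
        raise ValueError("no codons to compute GC3 over")
    return gc / total


def xcg_xcc_ratio(table: CodonTable) -> float:
    """CpG-suppression ratio: counts of NCG codons over NCC codons.

    A CG dinucleotide at codon positions 2-3 is a methylation-prone CpG;
    its depletion relative to NCC is the standard suppression measure.
    No stop codon has the NCG/NCC shape, so stops never contribute.
    """
    ncg = sum(table.counts[b + "CG"] for b in "ACGT")
    ncc = sum(table.counts[b + "CC"] for b in "ACGT")
    if ncc == 0:
        raise ValueError("no NCC codons: XCG/XCC ratio undefined")
    return ncg / ncc


def stop_usage(orfs: Iterable[str]) -> dict[str, float]:
    """Fraction of ORFs terminating with each stop codon (sums to 1)."""
    counts = dict.fromkeys(STOP_CODONS, 0)
    n = 0
    for orf in orfs:
        orf = orf.upper()
        if not validate_full_orf(orf):
            raise ValueError(f"not a full-length ORF: {orf[:30]}...")
        counts[orf[-3:]] += 1
        n += 1
    if n == 0:
        raise ValueError("no ORFs given")
    return {stop: c / n for stop, c in counts.items()}
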