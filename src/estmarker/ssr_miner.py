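"""Microsatellite (SSR) detection in unigene sequences.

Scans for maximal perfect tandem repeats of di-, tri- and tetra-nucleotide
units, normalises each repeat unit to its canonical motif (the
lexicographic minimum over cyclic rotations and the reverse complement),
and classifies each locus relative to the annotated ORF (5'-UTR / ORF /
3'-UTR / other).

Only perfect repeats are considered.  A run may end mid-unit: the partial
final unit counts toward the total length but not toward the unit count.
Overlapping candidate runs of different unit lengths are resolved
deterministically (longer locus wins; on equal length the shorter unit
wins; remaining ties broken by start coordinate).
"""

from __future__ import annotations

import dataclasses
from enum import Enum

from .io_formats import Unigene

__all__ = [
    "SSRParams",
    "SSRLocus",
    "Location",
    "canonical_motif",
    "is_degenerate",
    "find_ssrs",
    "localize_ssr",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class Location(str, Enum):
    """Position of an SSR locus relative to the unigene's ORF."""

    FIVE_UTR = "FIVE_UTR"
    ORF = "ORF"
    THREE_UTR = "THREE_UTR"
    OTHER = "OTHER"


@dataclasses.dataclass(frozen=True)
class SSRParams:
    """Selection thresholds for SSR mining.

    ``min_units`` counts complete repeat units; ``min_total_length`` is the
    span of the locus in bp including any partial final unit.
    """

    unit_lengths: frozenset[int] = frozenset({2, 3, 4})
    min_units: int = 4
    min_total_length: int = 17

    def __post_init__(self) -> None:
        if not self.unit_lengths <= {2, 3, 4}:
            raise ValueError("unit_lengths must be a subset of {2, 3, 4}")
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        if self.min_total_length < 2 * self.min_units:
            raise ValueError("min_total_length must be >= 2 * min_units")


@dataclasses.dataclass(frozen=True)
class SSRLocus:
    unigene_id: str
    start: int
    end: int
    motif_found: str
    motif_canonical: str
    unit_length: int
    n_units: float
    total_length: int
    location: Location = Location.OTHER


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(unit: str) -> str:
    """Normalise a repeat unit to its canonical motif.

    The canonical motif is the lexicographically smallest string among all
    cyclic rotations of the unit and of its reverse complement, so that
    e.g. GA, AG, TC and CT all map to AG.  Idempotent by construction.
    """
    unit = unit.upper()
    if not 2 <= len(unit) <= 4:
        raise ValueError(f"unit length must be 2-4, got {unit!r}")
    if set(unit) - set("ACGT"):
        raise ValueError(f"ambiguous or non-DNA unit {unit!r}")
    rc = reverse_complement(unit)
    k = len(unit)
    candidates = [unit[i:] + unit[:i] for i in range(k)]
    candidates += [rc[i:] + rc[:i] for i in range(k)]
    return min(candidates)


def is_degenerate(unit: str) -> bool:
    """True iff the unit is a whole-number power of a shorter unit.

    Degenerate units (AA, ACAC, TTT, ...) are suppressed so each repeat is
    reported once, under its shortest period.
    """
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return True
    return False


def _maximal_runs(seq: str, k: int) -> list[tuple[int, int]]:
    """All maximal runs of period ``k``: (start, end) 0-based half-open.

    ``seq[i] == seq[i+k]`` for every i in [start, end-k); N never matches.
    Only runs spanning at least 2k bases (one full repetition) are yielded.
    """
    n = len(seq)
    runs = []
    i = 0
    while i < n - k:
        if seq[i] != "N" and seq[i] == seq[i + k]:
            j = i
            while j < n - k and seq[j] != "N" and seq[j] == seq[j + k]:
                j += 1
            # periodic region is [i, j + k)
            runs.append((i, j + k))
            i = j + 1
        else:
            i += 1
    return [(s, e) for s, e in runs if e - s >= 2 * k]


def _resolve_overlaps(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Keep the longer locus among overlapping candidates; on equal length
    the shorter unit wins, then the leftmost."""
    order = sorted(loci, key=lambda L: (-L.total_length, L.unit_length, L.start))
    kept: list[SSRLocus] = []
    for loc in order:
        if all(loc.end <= k.start or loc.start >= k.end for k in kept):
            kept.append(loc)
    return sorted(kept, key=lambda L: L.start)


def find_ssrs(unigene: Unigene, params: SSRParams = SSRParams()) -> list[SSRLocus]:
    """Detect SSR loci in one unigene.

    Every maximal perfect tandem run of a non-degenerate 2-4 bp unit with
    at least ``min_units`` complete units and at least ``min_total_length``
    bp total span is reported exactly once.  Runs containing N are split at
    the N (N matches nothing).  Localisation is filled in when the unigene
    carries an ORF annotation.
    """
    seq = unigene.seq
    candidates: list[SSRLocus] = []
    for k in sorted(params.unit_lengths):
        for start, end in _maximal_runs(seq, k):
            unit = seq[start : start + k]
            if is_degenerate(unit):
                continue
            total = end - start
            if total // k < params.min_units or total < params.min_total_length:
                continue
            candidates.append(
                SSRLocus(
                    unigene_id=unigene.id,
                    start=start,
                    end=end,
                    motif_found=unit,
                    motif_canonical=canonical_motif(unit),
                    unit_length=k,
                    n_units=total / k,
                    total_length=total,
                )
            )
    resolved = _resolve_overlaps(candidates)
    return [
        dataclasses.replace(loc, location=localize_ssr(loc, unigene)) for loc in resolved
    ]


def localize_ssr(locus: SSRLocus, unigene: Unigene) -> Location:
    """Classify a locus relative to the unigene's ORF.

    A locus entirely upstream of the ORF (in coding orientation) is
    FIVE_UTR, entirely inside is ORF, entirely downstream is THREE_UTR;
    anything straddling a boundary, or any locus on a unigene without an
    annotated ORF, is OTHER.  For a minus-strand ORF the UTR labels follow
    the coding orientation.
    """
    if unigene.orf is None:
        return Location.OTHER
    orf_start, orf_end, strand = unigene.orf
    if locus.end <= orf_start:
        return Location.FIVE_UTR if strand == "+" else Location.THREE_UTR
    if locus.start >= orf_end:
        return Location.THREE_UTR if strand == "+" else Location.FIVE_UTR
    if orf_start <= locus.start and locus.end <= orf_end:
        return Location.ORF
    return Location.OTHER
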