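"""SNV calling and the filter cascade.

Variants are called from per-position, per-genotype read evidence pooled
across genotypes: an allele *qualifies* at a position when it is seen in
at least ``min_reads_per_allele`` reads (after discarding observations
below ``min_mapping_quality``) and its accumulated phred base quality
reaches ``min_allele_quality``.  A position with two or more qualifying
alleles yields an SNV (a SNP when all qualifying alleles are single
bases, otherwise an insertion/deletion).

Each called SNV is then annotated with the selection cascade:

========  ==========================================================
VKS       not a SNP (the variant is an indel)
HVR4      the unigene has more than ``hv_density`` SNVs per 100 bp
CS60      another SNV lies closer than ``proximity_bp``
I60       an intron junction lies closer than ``intron_bp``
CL60      the unigene edge lies closer than ``edge_bp``
NVSM1     variable within, or not sequenced in, the second genotype
NVSM2     variable within, or not sequenced in, the first genotype
CEF       no allele-specific restriction target (set by caps_finder)
========  ==========================================================

All distances are strict (<), centre-to-centre, in unigene coordinates.
"Not sequenced" means zero observations of that genotype passing the
mapping-quality threshold at the position.
"""

from __future__ import annotations

import dataclasses
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import OBSERVATION_COLUMNS, ReadObservation, Unigene

__all__ = [
    "SNVCallParams",
    "FilterParams",
    "SNV",
    "SNVKind",
    "Substitution",
    "call_snvs",
    "classify_substitution",
    "apply_filters",
    "select_candidates",
]


class SNVKind(str, Enum):
    SNP = "SNP"
    INSERTION = "INSERTION"
    DELETION = "DELETION"


class Substitution(str, Enum):
    TRANSITION = "TRANSITION"
    TRANSVERSION = "TRANSVERSION"


@dataclasses.dataclass(frozen=True)
class SNVCallParams:
    """Quality thresholds for allele qualification.

    ``min_allele_quality`` is an *accumulated* phred score: the sum of the
    base qualities of all reads supporting the allele.
    """

    min_allele_quality: int = 40
    min_reads_per_allele: int = 2
    min_mapping_quality: int = 20

    def __post_init__(self) -> None:
        if min(self.min_allele_quality, self.min_reads_per_allele, self.min_mapping_quality) < 0:
            raise ValueError("calling thresholds must be >= 0")


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """Thresholds and genotype labels for the filter cascade.

    ``genotype_labels`` is the ordered pair (first, second); NVSM2 reports
    variability in the first genotype, NVSM1 in the second.

    ``hv_window_bp``: when None (default) the hypervariable-region rule is
    evaluated at the whole-unigene level (total SNVs x 100 / length); when
    set, an SNV is tagged HVR4 iff some window of that many bp containing
    it holds more than ``hv_density x hv_window_bp / 100`` SNVs.
    """

    proximity_bp: int = 60
    edge_bp: int = 60
    intron_bp: int = 60
    hv_density: float = 4.0
    hv_window_bp: int | None = None
    genotype_labels: tuple[str, str] = ("MU16", "UPV196")

    def __post_init__(self) -> None:
        if min(self.proximity_bp, self.edge_bp, self.intron_bp) <= 0 or self.hv_density <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclasses.dataclass
class SNV:
    """A called variant.

    ``alleles`` maps genotype -> {allele token: (read count, accumulated
    quality)} restricted to alleles qualifying *within* that genotype;
    ``pooled`` holds the position-level qualifying alleles (pooled over
    genotypes), which determine the variant's existence and its ALT set.
    ``n_obs`` counts observations per genotype passing mapping quality.
    """

    unigene_id: str
    pos: int
    kind: SNVKind
    ref: str
    alleles: dict[str, dict[str, tuple[int, int]]]
    pooled: dict[str, tuple[int, int]]
    n_obs: dict[str, int]
    filters: set[str] = dataclasses.field(default_factory=set)

    def qualifying_alleles(self) -> set[str]:
        return set(self.pooled)


_INDEL_TOKENS = ("-", "+")


def _is_indel(allele: str) -> bool:
    return allele.startswith(_INDEL_TOKENS)


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    rows = [
        (o.unigene_id, o.pos, o.genotype, o.read_id, o.allele, o.base_quality, o.mapping_quality)
        for o in observations
    ]
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def call_snvs(
    observations: pd.DataFrame | Iterable[ReadObservation],
    unigenes: Mapping[str, Unigene],
    call_params: SNVCallParams = SNVCallParams(),
) -> list[SNV]:
    """Call SNVs from the evidence table.

    Accepts the observation DataFrame (columns as in the TSV dialect) or
    any iterable of :class:`ReadObservation`.  The result is sorted by
    (unigene, position) and is independent of input row order.
    """
    df = _as_frame(observations)
    if df.empty:
        return []
    unknown = set(df["unigene_id"].unique()) - set(unigenes)
    if unknown:
        raise ValueError(f"observations reference unknown unigenes: {sorted(unknown)}")
    lengths = df.groupby("unigene_id")["pos"].max()
    for uid, maxpos in lengths.items():
        if maxpos >= len(unigenes[uid]):
            raise ValueError(
                f"observation at {uid}:{maxpos} beyond unigene length {len(unigenes[uid])}"
            )

    df = df[df["map_qual"] >= call_params.min_mapping_quality]
    if df.empty:
        return []

    per_gt = (
        df.groupby(["unigene_id", "pos", "genotype", "allele"], sort=True)["base_qual"]
        .agg(["count", "sum"])
        .rename(columns={"count": "n", "sum": "q"})
        .reset_index()
    )
    pooled = (
        per_gt.groupby(["unigene_id", "pos", "allele"], sort=True)[["n", "q"]]
        .sum()
        .reset_index()
    )
    pooled_ok = pooled[
        (pooled["n"] >= call_params.min_reads_per_allele)
        & (pooled["q"] >= call_params.min_allele_quality)
    ]
    n_alleles = pooled_ok.groupby(["unigene_id", "pos"])["allele"].nunique()
    variant_keys = set(n_alleles[n_alleles >= 2].index)
    if not variant_keys:
        return []

    per_gt_ok = per_gt[
        (per_gt["n"] >= call_params.min_reads_per_allele)
        & (per_gt["q"] >= call_params.min_allele_quality)
    ]
    obs_counts = df.groupby(["unigene_id", "pos", "genotype"]).size()

    snvs = []
    pooled_by_key: dict[tuple, dict] = {}
    for row in pooled_ok.itertuples(index=False):
        key = (row.unigene_id, row.pos)
        if key in variant_keys:
            pooled_by_key.setdefault(key, {})[row.allele] = (int(row.n), int(row.q))
    gt_by_key: dict[tuple, dict] = {}
    for row in per_gt_ok.itertuples(index=False):
        key = (row.unigene_id, row.pos)
        if key in variant_keys:
            gt_by_key.setdefault(key, {}).setdefault(row.genotype, {})[row.allele] = (
                int(row.n),
                int(row.q),
            )
    nobs_by_key: dict[tuple, dict] = {}
    for (uid, pos, gt), n in obs_counts.items():
        key = (uid, pos)
        if key in variant_keys:
            nobs_by_key.setdefault(key, {})[gt] = int(n)

    for uid, pos in sorted(variant_keys):
        pool = pooled_by_key[(uid, pos)]
        indels = [a for a in pool if _is_indel(a)]
        if any(a.startswith("+") for a in indels):
            kind = SNVKind.INSERTION
        elif indels:
            kind = SNVKind.DELETION
        else:
            kind = SNVKind.SNP
        snvs.append(
            SNV(
                unigene_id=uid,
                pos=int(pos),
                kind=kind,
                ref=unigenes[uid].seq[pos],
                alleles=gt_by_key.get((uid, pos), {}),
                pooled=pool,
                n_obs=nobs_by_key.get((uid, pos), {}),
            )
        )
    return snvs


_TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})


def classify_substitution(a: str, b: str) -> Substitution:
    """Classify a base substitution as transition or transversion."""
    a, b = a.upper(), b.upper()
    if a == b:
        raise ValueError("alleles must differ")
    if a not in "ACGT" or b not in "ACGT" or len(a) != 1 or len(b) != 1:
        raise ValueError(f"not single bases: {a!r}, {b!r}")
    return (
        Substitution.TRANSITION if {a, b} in _TRANSITION_PAIRS else Substitution.TRANSVERSION
    )


def apply_filters(
    snvs: list[SNV],
    unigenes: Mapping[str, Unigene],
    filter_params: FilterParams = FilterParams(),
) -> list[SNV]:
    """Annotate SNVs with the cascade tags (all but CEF).

    Tagging is idempotent and independent of input order; the input list
    is modified in place and returned sorted by (unigene, position).
    """
    snvs = sorted(snvs, key=lambda s: (s.unigene_id, s.pos))
    by_unigene: dict[str, list[SNV]] = {}
    for snv in snvs:
        by_unigene.setdefault(snv.unigene_id, []).append(snv)

    first_gt, second_gt = filter_params.genotype_labels
    for uid, group in by_unigene.items():
        unigene = unigenes[uid]
        length = len(unigene)
        positions = [s.pos for s in group]
        if filter_params.hv_window_bp is None:
            hv = [len(group) * 100.0 / length > filter_params.hv_density] * len(group)
        else:
            hv = _sliding_hv(positions, filter_params.hv_window_bp, filter_params.hv_density)
        for i, snv in enumerate(group):
            snv.filters.discard("VKS")
            if snv.kind is not SNVKind.SNP:
                snv.filters.add("VKS")
            _set(snv.filters, "HVR4", hv[i])
            near = any(
                abs(snv.pos - p) < filter_params.proximity_bp
                for j, p in enumerate(positions)
                if j != i
            )
            _set(snv.filters, "CS60", near)
            _set(
                snv.filters,
                "I60",
                any(abs(snv.pos - j) < filter_params.intron_bp for j in unigene.introns),
            )
            _set(
                snv.filters,
                "CL60",
                min(snv.pos, length - 1 - snv.pos) < filter_params.edge_bp,
            )
            _set(snv.filters, "NVSM1", _nvsm(snv, second_gt))
            _set(snv.filters, "NVSM2", _nvsm(snv, first_gt))
    return snvs


def _sliding_hv(positions: list[int], window_bp: int, density: float) -> list[bool]:
    """Per-SNV hypervariable flags: any window of ``window_bp`` containing
    the SNV holds more SNVs than the density allows (positions sorted)."""
    max_in_window = density * window_bp / 100.0
    flags = [False] * len(positions)
    b = 0
    for a in range(len(positions)):
        if b < a:
            b = a
        while b + 1 < len(positions) and positions[b + 1] - positions[a] < window_bp:
            b += 1
        if (b - a + 1) > max_in_window:
            for i in range(a, b + 1):
                flags[i] = True
    return flags


def _set(tags: set[str], code: str, on: bool) -> None:
    (tags.add if on else tags.discard)(code)


def _nvsm(snv: SNV, genotype: str) -> bool:
    """Variable within the genotype, or not sequenced in it."""
    if snv.n_obs.get(genotype, 0) == 0:
        return True
    return len(snv.alleles.get(genotype, {})) >= 2


def select_candidates(snvs: Iterable[SNV]) -> tuple[list[SNV], list[SNV]]:
    """Split filtered SNVs into the two marker candidate sets.

    Returns ``(golden_gate_set, caps_set)``: the Golden Gate set holds
    SNVs whose tag set is empty or {CEF} (clean flanks, suitable for
    array genotyping); the CAPS set holds SNVs with an empty tag set
    (additionally detectable as CAPS).  The CAPS set is always a subset
    of the Golden Gate set.
    """
    golden, caps = [], []
    for snv in snvs:
        if snv.filters <= {"CEF"}:
            golden.append(snv)
            if not snv.filters:
                caps.append(snv)
    return golden, caps
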