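"""Summary tables for SSR and SNV marker sets.

Produces, at any dataset scale, the standard survey statistics of an
EST marker study: SSR class shares and motif tables, the SSR/ORF
localisation cross-tab, the transition/transversion spectrum, per-filter
attrition counts, and per-unigene variation density.

The table builders are pure functions of count dictionaries, so they can
be fed either counts derived from pipeline objects or externally printed
counts; the ``summarize_*`` entry points derive the counts from pipeline
objects first.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import FILTER_ORDER
from .snv_pipeline import SNV, SNVKind, Substitution, classify_substitution
from .ssr_miner import Location, SSRLocus

__all__ = [
    "percent",
    "ssr_class_table",
    "ssr_motif_table",
    "ssr_localization_table",
    "snv_spectrum",
    "attrition_table",
    "variation_density",
    "summarize_ssrs",
    "summarize_snvs",
]

_CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra"}
_LOCATION_ROWS = (Location.FIVE_UTR, Location.ORF, Location.THREE_UTR, Location.OTHER)


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``decimals``."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, decimals)


# ---------------------------------------------------------------------------
# pure table builders (count dictionaries in, DataFrames out)
# ---------------------------------------------------------------------------


def ssr_class_table(class_counts: Mapping[int, int], decimals: int = 1) -> pd.DataFrame:
    """Counts and percentages per repeat-unit length (2/3/4)."""
    total = sum(class_counts.values())
    rows = [
        {
            "class": _CLASS_NAMES[k],
            "unit_length": k,
            "count": class_counts.get(k, 0),
            "percent": percent(class_counts.get(k, 0), total, decimals),
        }
        for k in (2, 3, 4)
    ]
    return pd.DataFrame(rows)


def ssr_motif_table(motif_counts: Mapping[str, int], decimals: int = 0) -> pd.DataFrame:
    """Per-class motif table: canonical motif, count, percent of class.

    Motifs are sorted by descending count then lexicographically, within
    each unit-length class.
    """
    rows = []
    for k in (2, 3, 4):
        in_class = {m: c for m, c in motif_counts.items() if len(m) == k}
        class_total = sum(in_class.values())
        for motif, count in sorted(in_class.items(), key=lambda mc: (-mc[1], mc[0])):
            rows.append(
                {
                    "class": _CLASS_NAMES[k],
                    "motif": motif,
                    "count": count,
                    "percent_of_class": percent(count, class_total, decimals),
                }
            )
    return pd.DataFrame(rows, columns=["class", "motif", "count", "percent_of_class"])


def ssr_localization_table(
    loc_counts: Mapping[tuple[int, Location], int], decimals: int = 0
) -> pd.DataFrame:
    """Localisation cross-tab (rows: 5'-UTR/ORF/3'-UTR/other + total,
    columns per class and all-SSRs, with counts and column percentages)."""
    classes = (2, 3, 4)
    col_totals = {
        k: sum(loc_counts.get((k, loc), 0) for loc in _LOCATION_ROWS) for k in classes
    }
    grand = sum(col_totals.values())
    rows = []
    for loc in _LOCATION_ROWS:
        row: dict = {"location": loc.value}
        all_count = 0
        for k in classes:
            n = loc_counts.get((k, loc), 0)
            all_count += n
            row[f"{_CLASS_NAMES[k]}_count"] = n
            row[f"{_CLASS_NAMES[k]}_percent"] = percent(n, col_totals[k], decimals)
        row["all_count"] = all_count
        row["all_percent"] = percent(all_count, grand, decimals)
        rows.append(row)
    total_row: dict = {"location": "total"}
    for k in classes:
        total_row[f"{_CLASS_NAMES[k]}_count"] = col_totals[k]
        total_row[f"{_CLASS_NAMES[k]}_percent"] = percent(col_totals[k], col_totals[k], decimals)
    total_row["all_count"] = grand
    total_row["all_percent"] = percent(grand, grand, decimals)
    rows.append(total_row)
    return pd.DataFrame(rows)


_PAIRS = tuple(
    frozenset(p) for p in (("A", "G"), ("C", "T"), ("A", "T"), ("G", "T"), ("C", "G"), ("A", "C"))
)


def snv_spectrum(pair_counts: Mapping[frozenset, int], decimals: int = 0) -> dict:
    """Transition/transversion spectrum from substitution-pair counts.

    Returns per-pair counts, subtotals and their percentages of all
    classified substitutions.
    """
    ts = sum(
        n
        for pair, n in pair_counts.items()
        if classify_substitution(*sorted(pair)) is Substitution.TRANSITION
    )
    tv = sum(
        n
        for pair, n in pair_counts.items()
        if classify_substitution(*sorted(pair)) is Substitution.TRANSVERSION
    )
    total = ts + tv
    return {
        "pairs": {"<->".join(sorted(p)): pair_counts.get(p, 0) for p in _PAIRS},
        "transitions": ts,
        "transversions": tv,
        "transitions_percent": percent(ts, total, decimals),
        "transversions_percent": percent(tv, total, decimals),
        "total": total,
    }


def attrition_table(
    filter_counts: Mapping[str, int], total_snvs: int, decimals: int = 1
) -> pd.DataFrame:
    """Per-filter counts and their percentage of all SNVs."""
    rows = [
        {
            "filter": code,
            "count": filter_counts.get(code, 0),
            "percent": percent(filter_counts.get(code, 0), total_snvs, decimals),
        }
        for code in FILTER_ORDER
    ]
    return pd.DataFrame(rows)


def variation_density(
    n_variants: int, n_variable_unigenes: int, n_unigenes: int
) -> dict:
    """Per-unigene variation summary: mean variants per variable unigene
    (1 decimal) and the variable fraction of all unigenes."""
    mean = round(n_variants / n_variable_unigenes, 1) if n_variable_unigenes else 0.0
    return {
        "n_variants": n_variants,
        "n_variable_unigenes": n_variable_unigenes,
        "variable_unigene_percent": percent(n_variable_unigenes, n_unigenes, 1),
        "mean_variants_per_variable_unigene": mean,
    }


# ---------------------------------------------------------------------------
# summaries from pipeline objects
# ---------------------------------------------------------------------------


def summarize_ssrs(ssrs: Iterable[SSRLocus], decimals: int = 1) -> dict:
    """Class, motif and localisation tables from detected SSR loci."""
    ssrs = list(ssrs)
    class_counts: dict[int, int] = {}
    motif_counts: dict[str, int] = {}
    loc_counts: dict[tuple[int, Location], int] = {}
    for locus in ssrs:
        class_counts[locus.unit_length] = class_counts.get(locus.unit_length, 0) + 1
        motif_counts[locus.motif_canonical] = motif_counts.get(locus.motif_canonical, 0) + 1
        key = (locus.unit_length, locus.location)
        loc_counts[key] = loc_counts.get(key, 0) + 1
    lengths = [locus.total_length for locus in ssrs]
    return {
        "n_ssrs": len(ssrs),
        "n_unigenes_with_ssr": len({locus.unigene_id for locus in ssrs}),
        "length_min": min(lengths) if lengths else 0,
        "length_max": max(lengths) if lengths else 0,
        "length_mean": round(sum(lengths) / len(lengths), 1) if lengths else 0.0,
        "class_table": ssr_class_table(class_counts, decimals),
        "motif_table": ssr_motif_table(motif_counts),
        "localization_table": ssr_localization_table(loc_counts),
    }


def _segregating_pairs(snv: SNV) -> Iterable[frozenset]:
    """Base pairs segregating at a SNP; each unordered pair counted once.

    Multi-allelic SNPs contribute one entry per allele pair.
    """
    bases = sorted(a for a in snv.qualifying_alleles() if len(a) == 1 and a in "ACGT")
    return (frozenset(p) for p in itertools.combinations(bases, 2))


def summarize_snvs(
    snvs: Iterable[SNV],
    unigene_count: int,
    est_counts: Mapping[str, int] | None = None,
    decimals: int = 0,
) -> dict:
    """Spectrum, attrition and density summaries from called SNVs.

    ``est_counts`` is an optional per-unigene read-count table used to
    report the mean number of ESTs per unigene (assembly metadata that
    cannot be derived from the variant calls themselves).
    """
    snvs = list(snvs)
    pair_counts: dict[frozenset, int] = {}
    filter_counts: dict[str, int] = {}
    for snv in snvs:
        if snv.kind is SNVKind.SNP:
            for pair in _segregating_pairs(snv):
                pair_counts[pair] = pair_counts.get(pair, 0) + 1
        for code in snv.filters:
            filter_counts[code] = filter_counts.get(code, 0) + 1
    n_snps = sum(1 for s in snvs if s.kind is SNVKind.SNP)
    variable_unigenes = {s.unigene_id for s in snvs}
    out = {
        "n_snvs": len(snvs),
        "n_snps": n_snps,
        "n_indels": len(snvs) - n_snps,
        "spectrum": snv_spectrum(pair_counts, decimals),
        "attrition": attrition_table(filter_counts, len(snvs)),
        "density": variation_density(len(snvs), len(variable_unigenes), unigene_count),
    }
    if est_counts is not None and len(est_counts):
        out["ests_per_unigene_mean"] = round(sum(est_counts.values()) / len(est_counts), 1)
    return out
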