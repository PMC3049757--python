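"""Synthetic unigene sets and two-genotype read evidence with known truth.

Emulates the design of a two-cultivar normalized-EST survey: a set of
assembled consensus transcripts (mean length 626 bp) mostly carrying a
single ORF and occasionally spliced-out intron junctions; planted di-,
tri- and tetra-nucleotide microsatellites; planted between-genotype
variants with a transition-biased spectrum and a configurable fraction
of indels and of within-genotype variability; and per-position,
per-genotype read observations with phred base/mapping qualities and a
uniform miscall rate.

Every planted feature is recorded in a :class:`TruthSet`, including the
filter-cascade tags each planted variant is expected to receive, which
are computed from the planted geometry alone (edge/intron/neighbour
distances, per-unigene density, within-genotype status).

Determinism: one seed fixes the full output byte-for-byte; every unigene
draws from its own counter-derived substream so outputs are stable under
reordering.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import OBSERVATION_COLUMNS, Unigene
from .snv_pipeline import SNV, SNVKind
from .ssr_miner import canonical_motif

__all__ = [
    "SimulationConfig",
    "PlantedSSR",
    "PlantedSNV",
    "TruthSet",
    "gen_unigenes",
    "gen_read_observations",
    "truth_snvs",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
# stop-codon usage weights of the emulated transcriptome (TAA, TAG, TGA)
_STOP_WEIGHTS = (0.414, 0.175, 0.411)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# motif catalogues (canonical motifs with approximate observed weights in
# EST-SSR surveys of cucurbits: AG-rich di, AAG-rich tri, AT-rich tetra)
_DI_MOTIFS = (("AG", 0.76), ("AT", 0.20), ("AC", 0.04))
_TRI_MOTIFS = (
    ("AAG", 0.50),
    ("AGC", 0.10),
    ("ATC", 0.08),
    ("AGG", 0.07),
    ("AAT", 0.06),
    ("AAC", 0.05),
    ("ACC", 0.05),
    ("ACG", 0.03),
    ("CCG", 0.03),
    ("ACT", 0.03),
)
_TETRA_MOTIFS = (
    ("AAAT", 0.21),
    ("AAAG", 0.19),
    ("AATG", 0.16),
    ("AATC", 0.13),
    ("ATCC", 0.11),
    ("AAAC", 0.11),
    ("ACAT", 0.09),
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the emulated two-genotype EST dataset.

    The defaults reproduce the study conditions of a normalized-library
    454 survey of two squash cultivars: unigenes of 626 +/- 250 bp, 96%
    with an ORF, ~33% with at least one intron junction, ~4% carrying an
    SSR, 0.7 planted variants per kb with transition:transversion odds
    2.1, 5.5% indels, 55% of variant sites additionally variable within
    one genotype, and a mean read depth per genotype and position of 2.4
    (9.3 reads of ~320 bp per 626 bp unigene, split between genotypes).
    """

    n_unigenes: int = 200
    length_mean: float = 626.0
    length_sd: float = 250.0
    gc_content: float = 0.42
    orf_fraction: float = 0.96
    intron_rate: float = 0.4
    ssr_plant_spec: Sequence[tuple[str, int, str]] | None = None
    ssr_unigene_rate: float = 0.04
    snv_rate: float = 0.7
    ts_tv_ratio: float = 2.1
    indel_fraction: float = 0.055
    within_genotype_het_rate: float = 0.55
    coverage_mean: float = 2.4
    base_error_rate: float = 0.001
    base_quality_mean: float = 32.0
    mapq_mean: float = 40.0
    genotypes: tuple[str, str] = ("MU16", "UPV196")
    frame_protect: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "orf_fraction",
            "ssr_unigene_rate",
            "indel_fraction",
            "within_genotype_het_rate",
            "base_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_unigenes < 1:
            raise ConfigError("n_unigenes must be >= 1")
        if self.ts_tv_ratio < 0 or self.snv_rate < 0 or self.coverage_mean < 0:
            raise ConfigError("rates must be non-negative")
        if self.ssr_plant_spec is not None:
            if len(self.ssr_plant_spec) > self.n_unigenes:
                raise ConfigError("more SSR plant entries than unigenes")
            for motif, units, region in self.ssr_plant_spec:
                if not 2 <= len(motif) <= 4 or set(motif.upper()) - set(_BASES):
                    raise ConfigError(f"bad SSR motif {motif!r}")
                if units < 2:
                    raise ConfigError("SSR unit count must be >= 2")
                if region == "ORF" and self.frame_protect:
                    if len(motif) != 3:
                        raise ConfigError(
                            f"non-tri motif {motif!r} in ORF breaks the reading frame"
                        )
                    if motif.upper() in _STOPS:
                        raise ConfigError(f"motif {motif!r} is a stop codon")


@dataclasses.dataclass(frozen=True)
class PlantedSSR:
    unigene_id: str
    start: int
    end: int
    motif: str
    motif_canonical: str
    region: str


@dataclasses.dataclass(frozen=True)
class PlantedSNV:
    """A planted variant with per-genotype alleles and expected tags.

    ``genotype_alleles`` maps genotype -> tuple of alleles it carries (two
    entries for a within-genotype variable site).  ``expected_filters``
    holds the cascade tags recomputable from planted geometry (never CEF,
    which depends on the enzyme panel).
    """

    unigene_id: str
    pos: int
    kind: SNVKind
    ref: str
    alt: str
    genotype_alleles: dict[str, tuple[str, ...]]
    expected_filters: frozenset[str]


@dataclasses.dataclass
class TruthSet:
    planted_ssrs: list[PlantedSSR]
    planted_snvs: list[PlantedSNV]


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(list(_BASES), size=n, p=_base_probs(gc)))


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    codons = []
    while len(codons) < n:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    return codons


def _pick_ssr(rng: np.random.Generator) -> tuple[str, int]:
    """Draw (motif, unit count) from the catalogue; always above thresholds."""
    klass = rng.choice([2, 3, 4], p=[0.153, 0.717, 0.13])
    catalogue = {2: _DI_MOTIFS, 3: _TRI_MOTIFS, 4: _TETRA_MOTIFS}[klass]
    motifs, weights = zip(*catalogue)
    w = np.array(weights) / sum(weights)
    motif = str(rng.choice(list(motifs), p=w))
    min_units = {2: 9, 3: 6, 4: 5}[klass]  # >= 17 bp and >= 4 units
    units = int(rng.integers(min_units, min_units + 6))
    return motif, units


def _fix_flank(
    seq: list[str], idx: int, avoid: str, orf: tuple[int, int, str] | None, rng: np.random.Generator
) -> None:
    """Replace seq[idx] with a base != avoid, keeping any ORF stop-free."""
    for b in rng.permutation(list(_BASES)):
        if b == avoid:
            continue
        if orf is not None and orf[0] <= idx < orf[1]:
            codon_start = orf[0] + ((idx - orf[0]) // 3) * 3
            codon = list(seq[codon_start : codon_start + 3])
            codon[idx - codon_start] = b
            if "".join(codon) in _STOPS:
                continue
        seq[idx] = b
        return
    raise AssertionError("unreachable: no safe flank base")


def _make_maximal(
    seq: list[str], start: int, end: int, k: int, orf, rng: np.random.Generator
) -> None:
    """Break period-k extension of the planted run at both flanks."""
    if start > 0 and seq[start - 1] == seq[start - 1 + k]:
        _fix_flank(seq, start - 1, seq[start - 1 + k], orf, rng)
    if end < len(seq) and seq[end] == seq[end - k]:
        _fix_flank(seq, end, seq[end - k], orf, rng)


def _plant_positions(rng: np.random.Generator, n: int, length: int, forbidden: set[int]) -> list[int]:
    allowed = np.array(sorted(set(range(length)) - forbidden))
    if allowed.size == 0 or n == 0:
        return []
    n = min(n, allowed.size)
    return sorted(int(p) for p in rng.choice(allowed, size=n, replace=False))


def _expected_tags(
    positions: list[int],
    kinds: list[SNVKind],
    het_genotypes: list[str | None],
    length: int,
    introns: list[int],
    genotypes: tuple[str, str],
) -> list[frozenset[str]]:
    """Cascade tags implied by planted geometry (same rules as apply_filters)."""
    n = len(positions)
    hypervariable = n * 100.0 / length > 4.0
    tags = []
    for i in range(n):
        t = set()
        if kinds[i] is not SNVKind.SNP:
            t.add("VKS")
        if hypervariable:
            t.add("HVR4")
        if any(abs(positions[i] - positions[j]) < 60 for j in range(n) if j != i):
            t.add("CS60")
        if any(abs(positions[i] - j) < 60 for j in introns):
            t.add("I60")
        if min(positions[i], length - 1 - positions[i]) < 60:
            t.add("CL60")
        if het_genotypes[i] == genotypes[1]:
            t.add("NVSM1")
        if het_genotypes[i] == genotypes[0]:
            t.add("NVSM2")
        tags.append(frozenset(t))
    return tags


def gen_unigenes(config: SimulationConfig) -> tuple[list[Unigene], TruthSet]:
    """Generate the unigene set with planted SSRs, variants and annotations."""
    unigenes: list[Unigene] = []
    truth = TruthSet(planted_ssrs=[], planted_snvs=[])
    explicit = config.ssr_plant_spec

    for i in range(config.n_unigenes):
        rng = np.random.default_rng((config.seed, i))
        uid = f"UG{i:05d}"
        length = max(150, int(round(rng.normal(config.length_mean, config.length_sd))))
        has_orf = rng.random() < config.orf_fraction

        # decide SSR planting before assembly
        plant: tuple[str, int, str] | None = None
        if explicit is not None:
            if i < len(explicit):
                motif, units, region = explicit[i]
                plant = (motif.upper(), units, region)
        elif rng.random() < config.ssr_unigene_rate:
            motif, units = _pick_ssr(rng)
            if len(motif) == 3 and has_orf:
                region = "ORF"
            elif has_orf:
                region = "FIVE_UTR" if rng.random() < 0.5 else "THREE_UTR"
            else:
                region = "OTHER"
            plant = (motif, units, region)
        if plant is not None:
            if plant[2] in ("FIVE_UTR", "ORF", "THREE_UTR"):
                has_orf = True  # an explicit region request implies an ORF
            elif plant[2] == "OTHER":
                has_orf = False  # OTHER means no ORF annotation on this unigene

        if has_orf:
            utr5 = _random_bases(rng, max(25, int(rng.uniform(0.08, 0.25) * length)), config.gc_content)
            utr3 = _random_bases(rng, max(25, int(rng.uniform(0.08, 0.25) * length)), config.gc_content)
            n_codons = max(10, (length - len(utr5) - len(utr3)) // 3)
            stop = str(rng.choice(list(_STOPS), p=_STOP_WEIGHTS))
            orf_seq = "ATG" + "".join(_random_codons(rng, n_codons - 2, config.gc_content)) + stop
        else:
            utr5 = utr3 = ""
            orf_seq = ""
        plain = _random_bases(rng, length, config.gc_content) if not has_orf else ""

        ssr_span: tuple[int, int, str, str] | None = None
        if plant is not None:
            motif, units, region = plant
            insert = motif * units
            if region == "ORF":
                if config.frame_protect and (len(motif) != 3 or motif in _STOPS):
                    raise ConfigError(f"cannot plant {motif!r} inside an ORF")
                codon_idx = int(rng.integers(2, len(orf_seq) // 3 - 2))
                at = 3 * codon_idx
                orf_seq = orf_seq[:at] + insert + orf_seq[at:]
                abs_start = len(utr5) + at
            elif region == "FIVE_UTR":
                at = int(rng.integers(5, len(utr5) - 5))
                utr5 = utr5[:at] + insert + utr5[at:]
                abs_start = at
            elif region == "THREE_UTR":
                at = int(rng.integers(5, len(utr3) - 5))
                utr3 = utr3[:at] + insert + utr3[at:]
                abs_start = len(utr5) + len(orf_seq) + at
            else:  # no ORF on this unigene
                at = int(rng.integers(10, len(plain) - 10))
                plain = plain[:at] + insert + plain[at:]
                abs_start = at
            ssr_span = (abs_start, abs_start + len(insert), motif, region)

        seq = list(utr5 + orf_seq + utr3 if has_orf else plain)
        orf = (len(utr5), len(utr5) + len(orf_seq), "+") if has_orf else None
        if ssr_span is not None:
            s, e, motif, region = ssr_span
            _make_maximal(seq, s, e, len(motif), orf, rng)
            truth.planted_ssrs.append(
                PlantedSSR(uid, s, e, motif, canonical_motif(motif), region)
            )

        final_len = len(seq)
        n_introns = int(rng.poisson(config.intron_rate))
        introns = sorted(int(j) for j in rng.integers(1, final_len, size=n_introns))

        # plant variants outside the SSR (and its maximality flanks)
        forbidden: set[int] = set()
        if ssr_span is not None:
            forbidden = set(range(max(0, ssr_span[0] - 1), min(final_len, ssr_span[1] + 1)))
        n_var = int(rng.poisson(config.snv_rate * final_len / 1000.0))
        positions = _plant_positions(rng, n_var, final_len, forbidden)

        kinds: list[SNVKind] = []
        refs: list[str] = []
        alts: list[str] = []
        carriers: list[str] = []
        het_gts: list[str | None] = []
        p_ts = config.ts_tv_ratio / (1.0 + config.ts_tv_ratio)
        for pos in positions:
            ref = seq[pos]
            if rng.random() < config.indel_fraction:
                if rng.random() < 0.5:
                    kind, alt = SNVKind.DELETION, "-"
                else:
                    ins = _random_bases(rng, int(rng.integers(1, 4)), config.gc_content)
                    kind, alt = SNVKind.INSERTION, "+" + ins
                het = None  # within-genotype variability is modelled for SNPs only
            else:
                kind = SNVKind.SNP
                if rng.random() < p_ts:
                    alt = _TRANSITION[ref]
                else:
                    alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
                het = (
                    config.genotypes[int(rng.integers(0, 2))]
                    if rng.random() < config.within_genotype_het_rate
                    else None
                )
            carrier = config.genotypes[int(rng.integers(0, 2))]
            kinds.append(kind)
            refs.append(ref)
            alts.append(alt)
            carriers.append(carrier)
            het_gts.append(het)

        tag_sets = _expected_tags(positions, kinds, het_gts, final_len, introns, config.genotypes)
        for pos, kind, ref, alt, carrier, het, tags in zip(
            positions, kinds, refs, alts, carriers, het_gts, tag_sets
        ):
            alleles = {}
            for g in config.genotypes:
                fixed = alt if g == carrier else ref
                if het == g:
                    alleles[g] = tuple(sorted({ref, alt}))
                else:
                    alleles[g] = (fixed,)
            truth.planted_snvs.append(
                PlantedSNV(uid, pos, kind, ref, alt, alleles, tags)
            )

        unigenes.append(Unigene(id=uid, seq="".join(seq), orf=orf, introns=introns))
    return unigenes, truth


# ---------------------------------------------------------------------------
# read-evidence generation
# ---------------------------------------------------------------------------


def gen_read_observations(
    unigenes: list[Unigene], truth: TruthSet, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the per-position, per-genotype read-observation table.

    Per position and genotype the read depth is Poisson(coverage_mean).
    At planted between-genotype sites the two genotypes carry their fixed
    alleles; at within-genotype-variable sites the variable genotype emits
    its two alleles at ~50/50.  Base miscalls are applied at
    ``base_error_rate`` to single-base calls only; qualities are drawn
    around ``base_quality_mean`` / ``mapq_mean``.
    """
    by_unigene: dict[str, list[PlantedSNV]] = {}
    for snv in truth.planted_snvs:
        by_unigene.setdefault(snv.unigene_id, []).append(snv)

    frames = []
    lookup_base = list(_BASES)
    for i, unigene in enumerate(unigenes):
        rng = np.random.default_rng((config.seed, i, 1))
        L = len(unigene)
        ref_codes = np.frombuffer(unigene.seq.encode(), dtype=np.uint8)
        base_map = np.zeros(256, dtype=np.int64)
        for code, b in enumerate(_BASES):
            base_map[ord(b)] = code
        ref_codes = base_map[ref_codes]

        for genotype in config.genotypes:
            tokens: list[str] = []
            template = ref_codes.copy()
            het_sites: dict[int, tuple[int, int]] = {}
            for snv in by_unigene.get(unigene.id, []):
                alleles = snv.genotype_alleles[genotype]

                def code_of(a: str) -> int:
                    if a in _BASES:
                        return lookup_base.index(a)
                    tokens.append(a)
                    return 3 + len(tokens)  # codes >= 4 are token indices

                if len(alleles) == 2:
                    het_sites[snv.pos] = (code_of(alleles[0]), code_of(alleles[1]))
                else:
                    template[snv.pos] = code_of(alleles[0])

            depth = rng.poisson(config.coverage_mean, size=L)
            positions = np.repeat(np.arange(L), depth)
            codes = np.repeat(template, depth)
            for pos, (c1, c2) in het_sites.items():
                idx = np.nonzero(positions == pos)[0]
                pick = rng.random(idx.size) < 0.5
                codes[idx] = np.where(pick, c1, c2)

            n = positions.size
            if config.base_error_rate > 0 and n:
                basecall = codes < 4
                err = (rng.random(n) < config.base_error_rate) & basecall
                shift = rng.integers(1, 4, size=n)
                codes = np.where(err, (codes + shift) % 4, codes)

            lookup = np.array(lookup_base + tokens, dtype=object)
            alleles_out = lookup[codes]
            base_q = np.clip(np.rint(rng.normal(config.base_quality_mean, 4.0, n)), 2, 60)
            map_q = np.clip(np.rint(rng.normal(config.mapq_mean, 3.0, n)), 0, 60)
            frames.append(
                pd.DataFrame(
                    {
                        "unigene_id": unigene.id,
                        "pos": positions,
                        "genotype": genotype,
                        "read_id": [f"{unigene.id}.{genotype}.{k}" for k in range(n)],
                        "allele": alleles_out,
                        "base_qual": base_q.astype(np.int64),
                        "map_qual": map_q.astype(np.int64),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=list(OBSERVATION_COLUMNS))
    return pd.concat(frames, ignore_index=True)[list(OBSERVATION_COLUMNS)]


def truth_snvs(truth: TruthSet, unigenes: dict[str, Unigene]) -> list[SNV]:
    """Materialise the planted variants as SNV records (for the truth VCF)."""
    out = []
    for p in truth.planted_snvs:
        pooled = {p.ref: (0, 0), p.alt: (0, 0)}
        gt_alleles = {g: {a: (0, 0) for a in alls} for g, alls in p.genotype_alleles.items()}
        out.append(
            SNV(
                unigene_id=p.unigene_id,
                pos=p.pos,
                kind=p.kind,
                ref=p.ref,
                alleles=gt_alleles,
                pooled=pooled,
                n_obs={g: 1 for g in p.genotype_alleles},
                filters=set(p.expected_filters),
            )
        )
    return out
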