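"""File formats used by the EST marker pipeline.

Internal coordinates are 0-based half-open everywhere; GFF3 and VCF are
1-based and conversion happens only here, at the file boundary.

Formats handled:

* FASTA — unigene (assembled consensus transcript) sequences.
* GFF3 — ORF and intron annotations per unigene.
* read-observation TSV — per-position, per-genotype mapped-read evidence
  with columns ``unigene_id pos genotype read_id allele base_qual map_qual``.
  The allele column holds a base, ``-`` for a single-base deletion at
  ``pos``, or ``+SEQ`` for an insertion of SEQ immediately after ``pos``.
* VCF 4.0 — called variants with the filter cascade codes in FILTER.
* YAML — threshold configuration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "Unigene",
    "ReadObservation",
    "FILTER_ORDER",
    "FILTER_DESCRIPTIONS",
    "OBSERVATION_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_annotations_gff3",
    "write_annotations_gff3",
    "read_observations",
    "read_observations_frame",
    "write_observations_frame",
    "write_vcf",
    "read_vcf",
    "load_config",
    "to_gff_interval",
    "from_gff_interval",
]


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


#: Filter codes of the selection cascade, in the fixed order used for
#: VCF header lines and for joining tags in the FILTER column.
FILTER_ORDER = ("VKS", "HVR4", "CS60", "I60", "CL60", "NVSM1", "NVSM2", "CEF")

FILTER_DESCRIPTIONS = {
    "VKS": "It is not an SNP (insertion or deletion)",
    "HVR4": "The region has more than 4 SNVs per 100 bp",
    "CS60": "SNV is closer than 60 bp to another SNV",
    "I60": "An intron is located closer than 60 bp",
    "CL60": "SNV is closer than 60 bp to the sequence end",
    "NVSM1": "SNV is variable within the second genotype or not sequenced in it",
    "NVSM2": "SNV is variable within the first genotype or not sequenced in it",
    "CEF": "SNV does not alter a restriction target and cannot be detected as a CAPS",
}

OBSERVATION_COLUMNS = (
    "unigene_id",
    "pos",
    "genotype",
    "read_id",
    "allele",
    "base_qual",
    "map_qual",
)

_DNA = set("ACGTN")


@dataclasses.dataclass
class Unigene:
    """An assembled consensus transcript with optional ORF/intron annotation.

    ``orf`` is a ``(start, end, strand)`` triple in 0-based half-open
    unigene coordinates; ``introns`` holds junction positions (the unigene
    coordinate at which a genomic intron was spliced out).
    """

    id: str
    seq: str
    orf: tuple[int, int, str] | None = None
    introns: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _DNA
        if bad:
            raise FormatError(f"unigene {self.id!r}: non-DNA characters {sorted(bad)}")
        if self.orf is not None:
            start, end, strand = self.orf
            if not (0 <= start < end <= len(self.seq)):
                raise FormatError(
                    f"unigene {self.id!r}: ORF interval ({start}, {end}) outside sequence"
                )
            if strand not in ("+", "-"):
                raise FormatError(f"unigene {self.id!r}: bad ORF strand {strand!r}")
        for j in self.introns:
            if not 0 <= j <= len(self.seq):
                raise FormatError(f"unigene {self.id!r}: intron position {j} out of range")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class ReadObservation:
    """One mapped-read base call at one unigene position for one genotype."""

    unigene_id: str
    pos: int
    genotype: str
    read_id: str
    allele: str
    base_quality: int
    mapping_quality: int


# ---------------------------------------------------------------------------
# coordinate conversion (0-based half-open <-> GFF 1-based closed)
# ---------------------------------------------------------------------------


def to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to GFF3 1-based closed."""
    return start + 1, end


def from_gff_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a GFF3 1-based closed interval to 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]`` in file order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# GFF3 annotations (ORF + introns)
# ---------------------------------------------------------------------------


def read_annotations_gff3(path: str | Path) -> dict[str, tuple[tuple[int, int, str] | None, list[int]]]:
    """Read ORF and intron features from GFF3.

    Returns ``{unigene_id: (orf, intron_junctions)}`` with internal 0-based
    coordinates.  Feature types ``ORF`` and ``CDS`` are both accepted as the
    open reading frame; when several are present for one unigene the longest
    wins.  ``intron`` features are reduced to their junction position (the
    0-based coordinate of the feature start).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, tuple[tuple[int, int, str] | None, list[int]]] = {}
    orfs: dict[str, tuple[int, int, str]] = {}
    introns: dict[str, list[int]] = {}
    for feat in db.all_features():
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature on {feat.seqid} has end < start")
        start, end = from_gff_interval(feat.start, feat.end)
        if feat.featuretype in ("ORF", "CDS"):
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            cur = orfs.get(feat.seqid)
            if cur is None or (end - start) > (cur[1] - cur[0]):
                orfs[feat.seqid] = (start, end, strand)
        elif feat.featuretype == "intron":
            introns.setdefault(feat.seqid, []).append(start)
    for uid in set(orfs) | set(introns):
        out[uid] = (orfs.get(uid), sorted(introns.get(uid, [])))
    return out


def write_annotations_gff3(unigenes: Iterable[Unigene], path: str | Path) -> None:
    """Write ORF and intron features of the given unigenes as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in unigenes:
            if u.orf is not None:
                start, end, strand = u.orf
                g1, g2 = to_gff_interval(start, end)
                fh.write(
                    f"{u.id}\testmarker\tORF\t{g1}\t{g2}\t.\t{strand}\t.\tID={u.id}.orf\n"
                )
            for k, j in enumerate(sorted(u.introns)):
                g1, g2 = to_gff_interval(j, j + 1)
                fh.write(
                    f"{u.id}\testmarker\tintron\t{g1}\t{g2}\t.\t+\t.\tID={u.id}.intron{k}\n"
                )


# ---------------------------------------------------------------------------
# read-observation TSV
# ---------------------------------------------------------------------------


def _check_allele(allele: str, where: str) -> None:
    if allele in ("A", "C", "G", "T", "-"):
        return
    if allele.startswith("+"):
        ins = allele[1:]
        if ins and set(ins) <= set("ACGT"):
            return
        raise FormatError(f"{where}: insertion token {allele!r} must carry DNA")
    raise FormatError(f"{where}: bad allele {allele!r}")


def read_observations(path: str | Path) -> Iterator[ReadObservation]:
    """Stream typed read observations from the tab-separated evidence table.

    Validation errors name the offending line number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != OBSERVATION_COLUMNS:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
            uid, pos_s, genotype, read_id, allele, bq_s, mq_s = fields
            try:
                pos, bq, mq = int(pos_s), int(bq_s), int(mq_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos < 0 or bq < 0 or mq < 0:
                raise FormatError(f"{path}:{lineno}: negative position or quality")
            allele = allele.upper()
            _check_allele(allele, f"{path}:{lineno}")
            yield ReadObservation(uid, pos, genotype, read_id, allele, bq, mq)


def read_observations_frame(path: str | Path) -> pd.DataFrame:
    """Read the observation table into a DataFrame (fast path for large files)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "unigene_id": str,
            "pos": "int64",
            "genotype": str,
            "read_id": str,
            "allele": str,
            "base_qual": "int64",
            "map_qual": "int64",
        },
    )
    if tuple(df.columns) != OBSERVATION_COLUMNS:
        raise FormatError(f"{path}: unexpected header {list(df.columns)}")
    if (df["pos"] < 0).any() or (df["base_qual"] < 0).any() or (df["map_qual"] < 0).any():
        raise FormatError(f"{path}: negative position or quality")
    df["allele"] = df["allele"].str.upper()
    return df


def write_observations_frame(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(OBSERVATION_COLUMNS))


# ---------------------------------------------------------------------------
# VCF 4.0
# ---------------------------------------------------------------------------


def _vcf_alt(allele: str) -> str:
    """Encode an internal allele token as a VCF ALT string.

    Single bases pass through; the indel dialect becomes ``D`` (deletion)
    and ``I<SEQ>`` (insertion), which matches the convention of writing
    I or D for indel alleles when no anchor base is available.
    """
    if allele == "-":
        return "D"
    if allele.startswith("+"):
        return "I" + allele[1:]
    return allele


def _vcf_alt_decode(alt: str) -> str:
    if alt == "D":
        return "-"
    if alt.startswith("I") and len(alt) > 1 and set(alt[1:]) <= set("ACGT"):
        return "+" + alt[1:]
    return alt


def write_vcf(snvs, unigene_lengths: dict[str, int], path: str | Path) -> None:
    """Write called variants as VCF 4.0.

    POS is 1-based; FILTER carries the cascade tags semicolon-joined in
    the fixed :data:`FILTER_ORDER`, or ``.`` for an untagged record.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.0\n")
        fh.write("##source=estmarker\n")
        for code in FILTER_ORDER:
            fh.write(f'##FILTER=<ID={code},Description="{FILTER_DESCRIPTIONS[code]}">\n')
        for uid in sorted(unigene_lengths):
            fh.write(f"##contig=<ID={uid},length={unigene_lengths[uid]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snv in sorted(snvs, key=lambda s: (s.unigene_id, s.pos)):
            if snv.unigene_id not in unigene_lengths:
                raise FormatError(f"SNV on unknown unigene {snv.unigene_id!r}")
            alts = sorted(a for a in snv.qualifying_alleles() if a != snv.ref)
            alt_field = ",".join(_vcf_alt(a) for a in alts) or "."
            tags = [c for c in FILTER_ORDER if c in snv.filters]
            filt = ";".join(tags) if tags else "."
            fh.write(
                f"{snv.unigene_id}\t{snv.pos + 1}\t.\t{snv.ref}\t{alt_field}\t.\t{filt}\t.\n"
            )


def read_vcf(path: str | Path) -> list[dict]:
    """Parse a pipeline VCF back into plain records.

    Returns dicts with keys ``unigene_id``, ``pos`` (0-based), ``ref``,
    ``alts`` (internal allele tokens) and ``filters`` (a set of cascade
    codes; empty for a ``.``/PASS record).
    """
    from cyvcf2 import VCF

    out = []
    for var in VCF(str(path)):
        filters = set(var.FILTER.split(";")) if var.FILTER else set()
        out.append(
            {
                "unigene_id": var.CHROM,
                "pos": var.POS - 1,
                "ref": var.REF,
                "alts": [_vcf_alt_decode(a) for a in var.ALT],
                "filters": filters,
            }
        )
    return out


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML threshold-configuration file into a plain dict.

    Recognised top-level sections are ``ssr``, ``calling``, ``filters``,
    ``caps`` and ``simulation``; each maps parameter names onto the
    corresponding dataclass fields of the pipeline modules.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return data
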