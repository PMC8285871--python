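"""Readers and writers for the standard formats the toolkit touches.

Conventions are strict and testable: coordinates are 1-based closed
throughout (SAM/GFF3 convention), genome sequences are uppercased on load
with IUPAC ambiguity codes other than N mapped to N, and the bisulfite
conversion strand of an alignment is carried in a Bismark-style ``XG:Z:CT``
/ ``XG:Z:GA`` tag (overridable with a per-file default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_AMBIGUITY = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})

#: bs_strand tag used by Bismark-style aligners
BS_STRAND_TAG = "XG"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class ConfigurationError(ValueError):
    """Required configuration (tag, default) missing."""


@dataclass
class GenomeSequence:
    """Named collection of chromosome sequences for one parental reference.

    Attributes
    ----------
    label : str
        Identifier of the parental genome (e.g. ``"parent1"``).
    sequences : dict[str, str]
        Ordered mapping chromosome id -> nucleotide string over A/C/G/T/N.
    """

    label: str
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"{self.label}/{chrom}: invalid characters {sorted(bad)}"
                )


@dataclass
class BSRead:
    """One bisulfite-treated sequencing read (FASTQ record)."""

    read_id: str
    mate: int  # 1 for single-end
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FormatError(f"{self.read_id}: base/quality length mismatch")


@dataclass
class AlignmentRecord:
    """One read's placement on one parental genome.

    ``pos`` is the 1-based leftmost mapping coordinate; ``bs_strand`` states
    which converted template the read derives from (``CT``: C->T conversions
    are expected matches; ``GA``: G->A).
    """

    read_id: str
    genome_label: str
    chrom: str
    pos: int
    strand: str
    cigar: str
    bs_strand: str | None
    mapped: bool
    bases: str
    quals: Sequence[int]
    mate: int = 1
    flag: int = 0
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.mapped and self.pos < 1:
            raise FormatError(f"{self.read_id}: pos must be >= 1")


@dataclass
class GeneAnnotation:
    """One annotated gene region, 1-based closed interval."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start > end")


@dataclass
class DMRRecord:
    """One tested differentially methylated region with its q-value."""

    chrom: str
    start: int
    end: int
    context: str
    stat: float
    qvalue: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"DMR {self.chrom}:{self.start}-{self.end}: start > end")
        if not 0.0 <= self.qvalue <= 1.0:
            raise FormatError(f"DMR {self.chrom}:{self.start}: qvalue outside [0,1]")


def read_fasta(path: str | Path, label: str | None = None) -> GenomeSequence:
    """Load a genome assembly from FASTA.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a logged warning (N positions are later skipped in scoring).

    Raises
    ------
    FormatError
        On an empty file or a duplicate chromosome id.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome id {rec.id!r}")
        seq = str(rec.seq).upper()
        cleaned = seq.translate(_AMBIGUITY)
        if cleaned != seq:
            n_amb = sum(a != b for a, b in zip(seq, cleaned))
            logger.warning(
                "%s/%s: %d ambiguity code(s) mapped to N", path.name, rec.id, n_amb
            )
        sequences[rec.id] = cleaned
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(label=label or path.stem, sequences=sequences)


def _bs_strand_of(rec: pysam.AlignedSegment, tag: str, default: str | None) -> str | None:
    if rec.has_tag(tag):
        value = rec.get_tag(tag)
        if value not in ("CT", "GA"):
            raise FormatError(f"{rec.query_name}: unexpected {tag} value {value!r}")
        return value
    if default is not None:
        return default
    raise ConfigurationError(
        f"{rec.query_name}: no {tag} tag and no default bs_strand configured"
    )


def read_sam(
    path: str | Path,
    genome: GenomeSequence,
    default_bs_strand: str | None = None,
    bs_strand_tag: str = BS_STRAND_TAG,
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file against ``genome``.

    Unmapped records are yielded with ``mapped=False``; a mapped record whose
    chromosome is absent from ``genome`` raises :class:`FormatError`. The
    bisulfite strand is taken from ``bs_strand_tag`` (Bismark's ``XG`` by
    default) or, failing that, from ``default_bs_strand``.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                yield AlignmentRecord(
                    read_id=rec.query_name,
                    genome_label=genome.label,
                    chrom="*",
                    pos=0,
                    strand="+",
                    cigar="*",
                    bs_strand=None,
                    mapped=False,
                    bases=rec.query_sequence or "",
                    quals=list(rec.query_qualities or []),
                    mate=2 if rec.is_read2 else 1,
                    flag=rec.flag,
                )
                continue
            chrom = rec.reference_name
            if chrom not in genome.sequences:
                raise FormatError(
                    f"{path}: chromosome {chrom!r} absent from genome {genome.label!r}"
                )
            yield AlignmentRecord(
                read_id=rec.query_name,
                genome_label=genome.label,
                chrom=chrom,
                pos=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                cigar=rec.cigarstring,
                bs_strand=_bs_strand_of(rec, bs_strand_tag, default_bs_strand),
                mapped=True,
                bases=rec.query_sequence or "",
                quals=list(rec.query_qualities or []),
                mate=2 if rec.is_read2 else 1,
                flag=rec.flag,
                is_secondary=rec.is_secondary or rec.is_supplementary,
            )


def _sam_header(genome: GenomeSequence) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in genome.lengths.items()],
        }
    )


def write_classified_sam(
    records: Iterable[AlignmentRecord],
    genome: GenomeSequence,
    path: str | Path,
) -> int:
    """Write one category's records as a valid SAM file; returns the count.

    All records must share one ``genome_label`` (one parental side per file).
    An empty record list yields a header-only file.
    """
    records = list(records)
    labels = {r.genome_label for r in records}
    if len(labels) > 1:
        raise FormatError(f"mixed genome labels in one output: {sorted(labels)}")
    if records and labels != {genome.label}:
        raise FormatError(
            f"records labelled {labels} do not match genome {genome.label!r}"
        )
    header = _sam_header(genome)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.flag = r.flag
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            if r.mapped:
                seg.reference_name = r.chrom
                seg.reference_start = r.pos - 1
                seg.cigarstring = r.cigar
                seg.mapping_quality = 255
                if r.bs_strand is not None:
                    seg.set_tag(BS_STRAND_TAG, r.bs_strand, "Z")
            out.write(seg)
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[BSRead]:
    """Stream FASTQ records; mate number parsed from a ``/1``-``/2`` suffix."""
    for rec in SeqIO.parse(str(path), "fastq"):
        mate = 1
        rid = rec.id
        if rid.endswith("/1") or rid.endswith("/2"):
            mate = int(rid[-1])
            rid = rid[:-2]
        yield BSRead(
            read_id=rid,
            mate=mate,
            bases=str(rec.seq).upper(),
            quals=rec.letter_annotations["phred_quality"],
        )


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[BSRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if r.mate == 2 else ("/1" if r.mate == 1 else "")
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}{suffix}\n{r.bases}\n+\n{qual}\n")


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Extract gene rows from a GFF3 file.

    Only the coordinates, strand and ``ID`` attribute are consumed; rows
    whose type differs from ``feature_type`` are ignored.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: GFF3 row with {len(fields)} columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype != feature_type:
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                gene_id = f"{chrom}:{start}-{end}"
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            )
    return genes


#: dmrseq-style export columns -> DMRRecord fields
DMR_COLUMN_MAP = {
    "seqnames": "chrom",
    "start": "start",
    "end": "end",
    "context": "context",
    "stat": "stat",
    "qval": "qvalue",
}


def read_dmr_table(path: str | Path, column_map: dict[str, str] | None = None):
    """Read a DMR table (TSV, dmrseq export shape) into a DataFrame.

    The default header is ``seqnames  start  end  context  stat  pval  qval``;
    ``column_map`` overrides the dialect. Raises :class:`FormatError` when the
    q-value column is missing.
    """
    import pandas as pd

    cmap = dict(DMR_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    present = {src: dst for src, dst in cmap.items() if src in df.columns}
    df = df.rename(columns=present)
    if "qvalue" not in df.columns:
        raise FormatError(f"{path}: no q-value column (expected one of {list(cmap)})")
    return df
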