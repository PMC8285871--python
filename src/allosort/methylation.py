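"""Per-cytosine methylation extraction, deduplication and conversion check.

A cytosine's context is determined by the two bases 3' of it on its own
strand: CG, CHG or CHH (H = A, T or C). Reads from the C->T-converted
strand report cytosines on the forward strand (read C = methylated, read
T = unmethylated); reads from the G->A-converted strand report cytosines
on the reverse strand, observed as G/A over reference G positions.
The output table is Bismark CX-report-shaped so downstream DMR callers can
consume it unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .bs_likelihood import aligned_pairs
from .io_formats import AlignmentRecord, GenomeSequence

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tri"]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class CytosineRecord:
    """Methylated/unmethylated call counts for one reference cytosine."""

    chrom: str
    pos: int
    strand: str
    context: str
    tri: str
    n_meth: int = 0
    n_unmeth: int = 0


class ContextError(ValueError):
    """The queried position is not a cytosine on the requested strand."""


def _context_of_tri(tri: str) -> str | None:
    t1, t2 = tri[1], tri[2]
    if "N" in (t1, t2):
        return None
    if t1 == "G":
        return "CG"
    if t2 == "G":
        return "CHG"
    return "CHH"


def assign_context(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> tuple[str | None, str | None]:
    """Context and trinucleotide (5'->3' on the C's strand) of one cytosine.

    ``pos`` is 1-based on the forward sequence; on the minus strand the
    forward base must be G (the C sits on the reverse complement). Positions
    whose trinucleotide runs off the chromosome end return ``(None, None)``
    and are skipped by callers with a warning.
    """
    seq = genome.sequences[chrom]
    if strand == "+":
        if seq[pos - 1] != "C":
            raise ContextError(f"{chrom}:{pos}(+) is {seq[pos - 1]}, not C")
        if pos + 2 > len(seq):
            logger.warning("%s:%d(+): trinucleotide runs off chromosome end", chrom, pos)
            return None, None
        tri = seq[pos - 1 : pos + 2]
    else:
        if seq[pos - 1] != "G":
            raise ContextError(f"{chrom}:{pos}(-) is {seq[pos - 1]}, not G")
        if pos < 3:
            logger.warning("%s:%d(-): trinucleotide runs off chromosome end", chrom, pos)
            return None, None
        tri = revcomp(seq[pos - 3 : pos])
    return _context_of_tri(tri), tri


def _read_unit_key(records: Sequence[AlignmentRecord]) -> tuple:
    """Duplicate key: (chrom, leftmost pos, strand) extended with the
    mate-pair outer coordinates for paired-end units."""
    mapped = [r for r in records if r.mapped and not r.is_secondary]
    first = mapped[0]
    if len(mapped) == 1:
        return (first.chrom, first.pos, first.strand)
    left = min(r.pos for r in mapped)
    right = max(r.pos + _ref_span(r) - 1 for r in mapped)
    return (first.chrom, left, first.strand, right)


def _ref_span(rec: AlignmentRecord) -> int:
    import re

    span = 0
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", rec.cigar):
        if op in "MDN=X":
            span += int(n)
    return span


def deduplicate(
    alignments: Iterable[AlignmentRecord],
) -> Iterator[AlignmentRecord]:
    """Remove duplicate read units on one genome side (stable: first wins).

    Two units are duplicates when they share chromosome, leftmost position,
    strand and (for pairs) outer coordinates. Emission order follows the
    input; both mates of a kept pair are emitted.
    """
    units: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    passthrough: list[AlignmentRecord] = []
    for rec in alignments:
        if not rec.mapped:
            passthrough.append(rec)
            continue
        if rec.read_id not in units:
            order.append(rec.read_id)
        units.setdefault(rec.read_id, []).append(rec)
    seen: set[tuple] = set()
    for rid in order:
        key = _read_unit_key(units[rid])
        if key in seen:
            continue
        seen.add(key)
        yield from units[rid]
    yield from passthrough


def methylation_calls(
    aln: AlignmentRecord, genome: GenomeSequence
) -> Iterator[tuple[int, str, bool]]:
    """Yield ``(ref_pos, strand, is_methylated)`` calls from one alignment.

    CT-strand reads call forward-strand cytosines (ref C; read C methylated,
    read T unmethylated); GA-strand reads call reverse-strand cytosines
    (ref G; read G methylated, read A unmethylated). Other read bases and N
    positions are ignored.
    """
    pairs, _, _, _ = aligned_pairs(aln, genome)
    if aln.bs_strand == "CT":
        for ref_pos, ref_b, read_b, _q in pairs:
            if ref_b == "C" and read_b in "CT":
                yield ref_pos, "+", read_b == "C"
    elif aln.bs_strand == "GA":
        for ref_pos, ref_b, read_b, _q in pairs:
            if ref_b == "G" and read_b in "GA":
                yield ref_pos, "-", read_b == "G"


def extract_methylation(
    classified: Iterable[AlignmentRecord],
    genome: GenomeSequence,
    cx_all: bool = False,
) -> pd.DataFrame:
    """Build the per-cytosine CX count table from classified alignments.

    Overlapping mates of one pair are counted once (mate 1 wins on the
    overlap). With ``cx_all`` every reference cytosine appears, including
    uncovered ones with zero counts.
    """
    counts: dict[tuple[str, int, str], list[int]] = {}
    covered_by_mate1: dict[str, set[int]] = {}
    for aln in classified:
        if not aln.mapped or aln.is_secondary:
            continue
        skip: set[int] = set()
        if aln.mate == 2:
            skip = covered_by_mate1.get(aln.read_id, set())
        calls = []
        for ref_pos, strand, is_meth in methylation_calls(aln, genome):
            if aln.chrom != "*" and ref_pos in skip:
                continue
            calls.append((ref_pos, strand, is_meth))
        if aln.mate == 1:
            covered_by_mate1.setdefault(aln.read_id, set()).update(
                p for p, _, _ in calls
            )
        for ref_pos, strand, is_meth in calls:
            cell = counts.setdefault((aln.chrom, ref_pos, strand), [0, 0])
            cell[0 if is_meth else 1] += 1

    rows = []
    if cx_all:
        sites = _all_cytosines(genome)
    else:
        sites = sorted(counts)
    for chrom, pos, strand in sites:
        context, tri = assign_context(genome, chrom, pos, strand)
        if context is None:
            continue
        m, u = counts.get((chrom, pos, strand), [0, 0])
        rows.append((chrom, pos, strand, m, u, context, tri))
    return pd.DataFrame(rows, columns=CX_COLUMNS)


def _all_cytosines(genome: GenomeSequence) -> list[tuple[str, int, str]]:
    sites = []
    for chrom, seq in genome.sequences.items():
        for i, b in enumerate(seq):
            if b == "C":
                sites.append((chrom, i + 1, "+"))
            elif b == "G":
                sites.append((chrom, i + 1, "-"))
    return sites


@dataclass
class ConversionReport:
    """Bisulfite conversion efficiency from an unmethylated control genome."""

    rate: float
    n_calls: int
    n_meth: int
    n_unmeth: int
    mapping_rate: float | None = None


def conversion_rate(
    control_alignments: Iterable[AlignmentRecord],
    control_genome: GenomeSequence,
    total_reads: int | None = None,
) -> ConversionReport:
    """Estimate conversion efficiency on a fully unmethylated control.

    rate = unconverted-free fraction = n_unmeth / (n_meth + n_unmeth) over
    all control cytosine calls. When ``total_reads`` is given, the control
    mapping rate (mapped control reads / total reads) is also reported —
    the lower it is, the better the conversion.
    """
    alignments = list(control_alignments)
    table = extract_methylation(alignments, control_genome)
    n_meth = int(table["n_meth"].sum())
    n_unmeth = int(table["n_unmeth"].sum())
    total_calls = n_meth + n_unmeth
    if total_calls == 0:
        raise ValueError("no cytosine calls on the control genome: rate undefined")
    mapping_rate = None
    if total_reads:
        n_mapped_units = len(
            {a.read_id for a in alignments if a.mapped and not a.is_secondary}
        )
        mapping_rate = n_mapped_units / total_reads
    return ConversionReport(
        rate=n_unmeth / total_calls,
        n_calls=total_calls,
        n_meth=n_meth,
        n_unmeth=n_unmeth,
        mapping_rate=mapping_rate,
    )
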