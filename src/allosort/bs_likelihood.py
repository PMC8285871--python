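"""Bisulfite-aware alignment likelihood (genotype-free).

Each aligned read base contributes a Phred-derived log probability:
with per-base error ``e = 10^(-q/10)``, a match contributes ``ln(1 - e)``
and a mismatch ``ln(e/3)``. Bisulfite conversion is treated as a match,
not an error: on the C->T-converted strand C and T are mutually
indistinguishable (collapsed three-letter alphabet), and on the
G->A-converted strand G and A are. The model needs no variant
information: both parental mappings of a read are scored against their own
reference and compared directly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignmentRecord, FormatError, GenomeSequence

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

DEFAULT_INDEL_LOGPEN = math.log(1e-4)


@dataclass
class ScoringConfig:
    """Parameters of the scoring and tie-calling model.

    bs_mode
        ``"strand"`` uses each read's conversion-strand tag; ``"both"``
        accepts C->T and G->A as matches regardless of strand (for tag-free
        input); ``"off"`` disables bisulfite awareness entirely.
    indel_logpen
        Per inserted/deleted base log penalty (must be negative).
    tie_margin
        Log-odds half-width below which a read is called ambiguous; with the
        default 0, equality is tested at 1e-9 absolute tolerance.
    """

    bs_mode: str = "strand"
    indel_logpen: float = DEFAULT_INDEL_LOGPEN
    tie_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.bs_mode not in ("off", "strand", "both"):
            raise ValueError(f"bs_mode {self.bs_mode!r} not in off/strand/both")
        if self.indel_logpen >= 0:
            raise ValueError("indel_logpen must be negative")
        if self.tie_margin < 0:
            raise ValueError("tie_margin must be >= 0")

    @property
    def tie_tolerance(self) -> float:
        return max(self.tie_margin, 1e-9)


@dataclass
class ScoredAlignment:
    """An alignment plus its log-likelihood and per-base bookkeeping."""

    alignment: AlignmentRecord
    loglik: float
    n_match: int = 0
    n_mismatch: int = 0
    n_bs_match: int = 0
    n_skipped: int = 0


def _is_bs_match(ref: str, read: str, bs_strand: str | None, bs_mode: str) -> bool:
    # Collapsed-alphabet (three-letter) semantics: on the C->T-converted
    # strand C and T are mutually indistinguishable, on the G->A strand G
    # and A are — so classification is invariant to template methylation.
    if bs_mode == "off":
        return False
    if {ref, read} == {"C", "T"}:
        return bs_mode == "both" or bs_strand == "CT"
    if {ref, read} == {"G", "A"}:
        return bs_mode == "both" or bs_strand == "GA"
    return False


def base_log_prob(
    ref_base: str,
    read_base: str,
    phred_q: int,
    bs_strand: str | None = None,
    bs_mode: str = "strand",
) -> float | None:
    """Log probability of observing ``read_base`` given ``ref_base``.

    Returns ``None`` for unscorable positions (N on either side); callers
    count those as skipped. This scalar form is the reference definition;
    :func:`score_alignment` applies the same model vectorized.
    """
    if ref_base == "N" or read_base == "N":
        return None
    e = 10.0 ** (-phred_q / 10.0)
    if ref_base == read_base or _is_bs_match(ref_base, read_base, bs_strand, bs_mode):
        return math.log1p(-e)
    return math.log(e / 3.0)


def aligned_pairs(
    aln: AlignmentRecord, genome: GenomeSequence
) -> tuple[list[tuple[int, str, str, int]], int, int, int]:
    """Walk the CIGAR and list scorable positions.

    Returns ``(pairs, n_inserted, n_deleted, n_clipped)`` where each pair is
    ``(ref_pos_1based, ref_base, read_base, phred_q)`` for an M/=/X column.
    """
    seq = genome.sequences[aln.chrom]
    ops = _CIGAR_RE.findall(aln.cigar)
    consumed = sum(int(n) for n, op in ops if op in "MIS=X")
    if consumed != len(aln.bases):
        raise FormatError(
            f"{aln.read_id}: CIGAR {aln.cigar} consumes {consumed} bases, "
            f"read has {len(aln.bases)}"
        )
    pairs: list[tuple[int, str, str, int]] = []
    rpos = aln.pos - 1  # 0-based reference cursor
    qpos = 0
    n_ins = n_del = n_clip = 0
    for n_str, op in ops:
        n = int(n_str)
        if op in "M=X":
            if rpos + n > len(seq):
                raise FormatError(
                    f"{aln.read_id}: alignment runs past end of {aln.chrom}"
                )
            for i in range(n):
                pairs.append(
                    (rpos + i + 1, seq[rpos + i], aln.bases[qpos + i], aln.quals[qpos + i])
                )
            rpos += n
            qpos += n
        elif op == "I":
            n_ins += n
            qpos += n
        elif op == "D":
            n_del += n
            rpos += n
        elif op == "N":
            rpos += n
        elif op == "S":
            n_clip += n
            qpos += n
        # H and P consume nothing we score
    return pairs, n_ins, n_del, n_clip


_BASE_CODE = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i
_A, _C, _G, _T, _N = range(5)


def score_alignment(
    aln: AlignmentRecord, genome: GenomeSequence, cfg: ScoringConfig
) -> ScoredAlignment:
    """Score one mapped alignment under the bisulfite-aware Phred model.

    loglik = sum of base_log_prob over M/=/X columns
             + indel_logpen * (inserted + deleted base count).
    Soft-clipped bases and N positions contribute nothing and are counted
    as skipped; ``n_match + n_mismatch + n_skipped`` equals the read length.
    """
    if not aln.mapped:
        raise ValueError(f"{aln.read_id}: cannot score an unmapped record")
    pairs, n_ins, n_del, n_clip = aligned_pairs(aln, genome)
    if not pairs:
        return ScoredAlignment(
            alignment=aln,
            loglik=cfg.indel_logpen * (n_ins + n_del),
            n_skipped=len(aln.bases),
        )
    ref = _BASE_CODE[np.frombuffer("".join(p[1] for p in pairs).encode(), np.uint8)]
    read = _BASE_CODE[np.frombuffer("".join(p[2] for p in pairs).encode(), np.uint8)]
    q = np.fromiter((p[3] for p in pairs), dtype=np.float64, count=len(pairs))

    valid = (ref != _N) & (read != _N)
    match = ref == read
    if cfg.bs_mode == "both" or (cfg.bs_mode == "strand" and aln.bs_strand == "CT"):
        match |= ((ref == _C) & (read == _T)) | ((ref == _T) & (read == _C))
    if cfg.bs_mode == "both" or (cfg.bs_mode == "strand" and aln.bs_strand == "GA"):
        match |= ((ref == _G) & (read == _A)) | ((ref == _A) & (read == _G))
    bs_match = match & (ref != read)

    e = 10.0 ** (-q / 10.0)
    with np.errstate(divide="ignore"):
        term = np.where(match, np.log1p(-e), np.log(e / 3.0))
    loglik = float(term[valid].sum()) + cfg.indel_logpen * (n_ins + n_del)

    n_match = int((match & valid).sum())
    n_mismatch = int((~match & valid).sum())
    n_skipped = len(aln.bases) - n_match - n_mismatch
    return ScoredAlignment(
        alignment=aln,
        loglik=loglik,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_bs_match=int((bs_match & valid).sum()),
        n_skipped=n_skipped,
    )
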