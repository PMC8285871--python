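"""Pair each read's alignments across two parental genomes and classify it.

A read (or mate pair) mapped on both parental sides is assigned by the sign
of its log-odds, ``loglik(parent1) - loglik(parent2)``, summed over mates
mapped on both sides; log-odds within the tie margin are called ambiguous.
Reads mapped on exactly one side are reported as unique to that side, and
reads mapped on neither as unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .bs_likelihood import ScoredAlignment, ScoringConfig, score_alignment
from .io_formats import (
    AlignmentRecord,
    FormatError,
    GenomeSequence,
    write_classified_sam,
)

CATEGORIES = (
    "parent1",
    "parent2",
    "ambiguous",
    "unique_parent1",
    "unique_parent2",
    "unmapped_both",
)


@dataclass
class ReadClassification:
    """Per-read verdict with its supporting log-likelihoods."""

    read_id: str
    category: str
    log_odds: float | None = None
    loglik1: float | None = None
    loglik2: float | None = None


def pair_alignments(
    sam1: Iterable[AlignmentRecord], sam2: Iterable[AlignmentRecord]
) -> Iterator[tuple[str, list[AlignmentRecord], list[AlignmentRecord]]]:
    """Group two alignment streams of the same read set by read id.

    Reads absent from one stream come through with an empty list on that
    side (treated as unmapped there). Order follows first appearance in
    ``sam1``, then ``sam2``-only reads.
    """
    by_id1: dict[str, list[AlignmentRecord]] = {}
    by_id2: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in sam1:
        if rec.read_id not in by_id1 and rec.read_id not in by_id2:
            order.append(rec.read_id)
        by_id1.setdefault(rec.read_id, []).append(rec)
    for rec in sam2:
        if rec.read_id not in by_id1 and rec.read_id not in by_id2:
            order.append(rec.read_id)
        by_id2.setdefault(rec.read_id, []).append(rec)
    for rid in order:
        yield rid, by_id1.get(rid, []), by_id2.get(rid, [])


def _best_per_mate(scored: Sequence[ScoredAlignment]) -> dict[int, ScoredAlignment]:
    """Best-scoring primary alignment per mate on one parental side."""
    best: dict[int, ScoredAlignment] = {}
    for s in scored:
        if s.alignment.is_secondary:
            continue
        m = s.alignment.mate
        if m not in best or s.loglik > best[m].loglik:
            best[m] = s
    return best


def classify_read(
    side1: Sequence[ScoredAlignment],
    side2: Sequence[ScoredAlignment],
    cfg: ScoringConfig,
) -> ReadClassification:
    """Classify one read unit from its scored alignments on both sides.

    For paired-end data the log-likelihoods are summed over mates mapped on
    BOTH sides; a mate mapped on only one side does not contribute (keeps
    the comparison symmetric).
    """
    best1 = _best_per_mate(side1)
    best2 = _best_per_mate(side2)
    rid = None
    for s in list(side1) + list(side2):
        rid = s.alignment.read_id
        break
    if not best1 and not best2:
        return ReadClassification(read_id=rid or "", category="unmapped_both")
    if best1 and not best2:
        ll1 = sum(s.loglik for s in best1.values())
        return ReadClassification(rid, "unique_parent1", loglik1=ll1)
    if best2 and not best1:
        ll2 = sum(s.loglik for s in best2.values())
        return ReadClassification(rid, "unique_parent2", loglik2=ll2)
    common = sorted(set(best1) & set(best2))
    if not common:
        # each side maps a different mate: no symmetric evidence either way
        return ReadClassification(rid, "ambiguous", log_odds=0.0)
    ll1 = sum(best1[m].loglik for m in common)
    ll2 = sum(best2[m].loglik for m in common)
    lo = ll1 - ll2
    if abs(lo) <= cfg.tie_tolerance:
        cat = "ambiguous"
    else:
        cat = "parent1" if lo > 0 else "parent2"
    return ReadClassification(rid, cat, log_odds=lo, loglik1=ll1, loglik2=ll2)


@dataclass
class ClassifiedReadset:
    """Full classification result: per-read table plus partitioned records."""

    table: pd.DataFrame
    partitions1: dict[str, list[AlignmentRecord]]
    partitions2: dict[str, list[AlignmentRecord]]

    @property
    def summary(self) -> pd.DataFrame:
        counts = self.table["category"].value_counts()
        return pd.DataFrame(
            {"category": CATEGORIES, "n": [int(counts.get(c, 0)) for c in CATEGORIES]}
        )


def classify_readset(
    sam1: Iterable[AlignmentRecord],
    sam2: Iterable[AlignmentRecord],
    genome1: GenomeSequence,
    genome2: GenomeSequence,
    cfg: ScoringConfig | None = None,
) -> ClassifiedReadset:
    """Classify every read unit and partition the alignments per category.

    Records on side 1 land in ``partitions1[category]`` (and symmetrically
    for side 2); ``unique_parent*`` records are filed on their own side.
    """
    cfg = cfg or ScoringConfig()
    rows: list[ReadClassification] = []
    parts1: dict[str, list[AlignmentRecord]] = {c: [] for c in CATEGORIES}
    parts2: dict[str, list[AlignmentRecord]] = {c: [] for c in CATEGORIES}
    for rid, recs1, recs2 in pair_alignments(sam1, sam2):
        scored1 = [score_alignment(r, genome1, cfg) for r in recs1 if r.mapped]
        scored2 = [score_alignment(r, genome2, cfg) for r in recs2 if r.mapped]
        verdict = classify_read(scored1, scored2, cfg)
        verdict.read_id = rid
        rows.append(verdict)
        for r in recs1:
            parts1[verdict.category].append(r)
        for r in recs2:
            parts2[verdict.category].append(r)
    table = pd.DataFrame(
        {
            "read_id": [r.read_id for r in rows],
            "category": [r.category for r in rows],
            "log_odds": [r.log_odds for r in rows],
            "loglik1": [r.loglik1 for r in rows],
            "loglik2": [r.loglik2 for r in rows],
        }
    )
    return ClassifiedReadset(table=table, partitions1=parts1, partitions2=parts2)


def write_partitions(
    result: ClassifiedReadset,
    genome1: GenomeSequence,
    genome2: GenomeSequence,
    out_dir: str | Path,
) -> dict[str, int]:
    """Write one SAM per (side, category); returns record counts per file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for side, parts, genome in (
        (1, result.partitions1, genome1),
        (2, result.partitions2, genome2),
    ):
        for cat, recs in parts.items():
            name = f"side{side}_{cat}.sam"
            counts[name] = write_classified_sam(recs, genome, out_dir / name)
    return counts
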