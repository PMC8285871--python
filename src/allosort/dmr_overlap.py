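"""Overlap significant DMRs with annotated genes (downstream analysis).

A DMR is significant when its q-value is strictly below the cutoff
(default 0.05); a gene is reported when it overlaps a significant DMR by at
least 1 bp. Both sides are 1-based closed intervals, so the overlap rule is
``end1 >= start2 and end2 >= start1``. Gene strand plays no role.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import DMRRecord, FormatError, GeneAnnotation

CONTEXTS = ("CG", "CHG", "CHH")

DEFAULT_ALPHA = 0.05


def filter_significant(dmrs: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Keep DMRs with qvalue strictly below ``alpha`` (q = alpha is dropped)."""
    if "qvalue" not in dmrs.columns:
        raise FormatError("DMR table lacks a 'qvalue' column")
    return dmrs.loc[dmrs["qvalue"] < alpha].reset_index(drop=True)


def overlap_genes(
    dmrs: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Report genes overlapping significant DMRs, per context.

    Returns ``(hits, summary)``. ``hits`` has one row per (gene, DMR)
    overlapping pair with the overlap width in bp. ``summary`` counts, per
    context, the significant DMRs and the distinct genes they touch, plus a
    ``total`` row where a gene hit in several contexts is counted once.
    """
    sig = filter_significant(dmrs, alpha)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # closed interval -> half-open for the tree
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)

    hit_rows = []
    for row in sig.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(row.start, row.end + 1)):
            g: GeneAnnotation = iv.data
            width = min(row.end, g.end) - max(row.start, g.start) + 1
            hit_rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "dmr_start": row.start,
                    "dmr_end": row.end,
                    "context": row.context,
                    "qvalue": row.qvalue,
                    "overlap_bp": width,
                }
            )
    hits = pd.DataFrame(
        hit_rows,
        columns=[
            "gene_id",
            "chrom",
            "gene_start",
            "gene_end",
            "dmr_start",
            "dmr_end",
            "context",
            "qvalue",
            "overlap_bp",
        ],
    )

    summary_rows = []
    for ctx in CONTEXTS:
        ctx_sig = sig.loc[sig["context"] == ctx]
        ctx_hits = hits.loc[hits["context"] == ctx]
        summary_rows.append(
            {
                "context": ctx,
                "n_dmrs": len(ctx_sig),
                "n_genes": ctx_hits["gene_id"].nunique(),
            }
        )
    summary_rows.append(
        {
            "context": "total",
            "n_dmrs": len(sig),
            "n_genes": hits["gene_id"].nunique(),
        }
    )
    return hits, pd.DataFrame(summary_rows)
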