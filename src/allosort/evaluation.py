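"""Benchmark harness: classification error rate vs. the concatenated baseline.

The benchmark design treats reads of known parental origin as if they were
allopolyploid reads: every read is classified between the two parental
genomes, and reads assigned to the wrong side are counted. The error rate
divides wrong assignments by the total number of uniquely mapped,
deduplicated reads — ambiguous reads stay in the denominator but are never
wrong. The "concatenated" baseline emulates mapping against both genomes
joined as one reference: the read goes to the genome holding its strictly
best-scoring candidate locus, and score ties make it non-unique (dropped
from the baseline's denominator, mirroring unique-mapping filters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bs_likelihood import ScoringConfig
from .classifier import classify_readset
from .methylation import deduplicate
from .simulator import SimConfig, SimResult, simulate_reads

#: score ties closer than this are not unique
TIE_EPS = 1e-9

_ASSIGNED = {
    "parent1": "parent1",
    "parent2": "parent2",
    "unique_parent1": "parent1",
    "unique_parent2": "parent2",
}


@dataclass
class EvalSummary:
    """Classification outcome counts and the error rate they imply."""

    n_unique_dedup: int
    n_correct: int
    n_wrong: int
    n_ambiguous: int
    error_rate: float


class TruthError(KeyError):
    """A classified read is missing from the truth table."""


def evaluate_classification(
    classifications: pd.DataFrame,
    truth: Mapping[str, str],
    denominator: str = "unique",
) -> EvalSummary:
    """Score a classification table against known read origins.

    ``denominator="unique"`` divides wrong calls by all uniquely mapped,
    deduplicated reads (ambiguous included); ``"assigned"`` divides by
    assigned reads only. Reads unique to one side count as assigned to it;
    reads unmapped on both sides are outside the denominator.
    """
    if denominator not in ("unique", "assigned"):
        raise ValueError(f"unknown denominator {denominator!r}")
    n_correct = n_wrong = n_ambiguous = n_eval = 0
    for rid, category in zip(classifications["read_id"], classifications["category"]):
        if category == "unmapped_both":
            continue
        if rid not in truth:
            raise TruthError(f"read {rid!r} absent from truth table")
        n_eval += 1
        if category == "ambiguous":
            n_ambiguous += 1
        elif _ASSIGNED[category] == truth[rid]:
            n_correct += 1
        else:
            n_wrong += 1
    denom = n_eval if denominator == "unique" else (n_correct + n_wrong)
    rate = n_wrong / denom if denom else 0.0
    return EvalSummary(
        n_unique_dedup=n_eval,
        n_correct=n_correct,
        n_wrong=n_wrong,
        n_ambiguous=n_ambiguous,
        error_rate=rate,
    )


def concatenated_baseline(
    candidates: Iterable[tuple[str, float]],
) -> str | None:
    """Assign a read as an aligner on the concatenated reference would.

    ``candidates`` are ``(genome_label, loglik)`` pairs for every candidate
    locus of one read across both genomes (secondary loci included when
    available). The read is uniquely mapped iff the best score strictly
    exceeds every other candidate's (beyond ``TIE_EPS``); returns the winning
    genome label, or ``None`` for non-unique/unmappable reads.
    """
    cands = list(candidates)
    if not cands:
        return None
    cands.sort(key=lambda t: -t[1])
    if len(cands) > 1 and cands[0][1] - cands[1][1] <= TIE_EPS:
        return None
    return cands[0][0]


def _read_unit_candidates(
    table: pd.DataFrame,
) -> Iterable[tuple[str, list[tuple[str, float]]]]:
    """Candidate (genome, score) lists per read from a classification table."""
    for row in table.itertuples(index=False):
        cands: list[tuple[str, float]] = []
        if row.loglik1 is not None and not (
            isinstance(row.loglik1, float) and math.isnan(row.loglik1)
        ):
            cands.append(("parent1", float(row.loglik1)))
        if row.loglik2 is not None and not (
            isinstance(row.loglik2, float) and math.isnan(row.loglik2)
        ):
            cands.append(("parent2", float(row.loglik2)))
        yield row.read_id, cands


def evaluate_baseline(
    table: pd.DataFrame, truth: Mapping[str, str]
) -> EvalSummary:
    """Run the concatenated-genome emulation over a classified read set.

    ``n_ambiguous`` reports the non-unique (tied) reads, which are excluded
    from the baseline denominator.
    """
    n_correct = n_wrong = n_not_unique = 0
    for rid, cands in _read_unit_candidates(table):
        if not cands:
            continue
        assigned = concatenated_baseline(cands)
        if assigned is None:
            n_not_unique += 1
        elif rid not in truth:
            raise TruthError(f"read {rid!r} absent from truth table")
        elif assigned == truth[rid]:
            n_correct += 1
        else:
            n_wrong += 1
    denom = n_correct + n_wrong
    return EvalSummary(
        n_unique_dedup=denom,
        n_correct=n_correct,
        n_wrong=n_wrong,
        n_ambiguous=n_not_unique,
        error_rate=n_wrong / denom if denom else 0.0,
    )


def run_benchmark(
    sim: SimResult, cfg: ScoringConfig | None = None
) -> dict[str, EvalSummary | float]:
    """Classify a simulated read set and score both methods against truth."""
    cfg = cfg or ScoringConfig()
    sam1 = list(deduplicate(sim.truth_sam1))
    kept = {r.read_id for r in sam1}
    sam2 = [r for r in sim.truth_sam2 if r.read_id in kept]
    result = classify_readset(sam1, sam2, sim.genome1, sim.genome2, cfg)
    truth = sim.truth_labels
    classifier = evaluate_classification(result.table, truth)
    baseline = evaluate_baseline(result.table, truth)
    if classifier.error_rate > 0:
        ratio = baseline.error_rate / classifier.error_rate
    else:
        ratio = math.inf if baseline.error_rate > 0 else float("nan")
    return {"classifier": classifier, "baseline": baseline, "ratio": ratio}


def compare_methods(
    sim_cfg: SimConfig,
    seeds: Sequence[int] = (1,),
    scoring: ScoringConfig | None = None,
    mode: str = "benchmark",
) -> pd.DataFrame:
    """Run the benchmark over several seeds; one row per (seed, method).

    Columns follow the benchmark report shape: unique/correct/wrong/ambiguous
    counts, error rate, and the baseline/classifier error-rate ratio.
    """
    rows = []
    for seed in seeds:
        cfg = SimConfig(**{**sim_cfg.__dict__, "seed": seed})
        sim = simulate_reads(cfg, mode=mode)
        res = run_benchmark(sim, scoring)
        for method in ("classifier", "baseline"):
            s: EvalSummary = res[method]  # type: ignore[assignment]
            rows.append(
                {
                    "seed": seed,
                    "method": method,
                    "n_unique": s.n_unique_dedup,
                    "n_correct": s.n_correct,
                    "n_wrong": s.n_wrong,
                    "n_ambiguous": s.n_ambiguous,
                    "error_rate": s.error_rate,
                    "error_ratio": res["ratio"],
                }
            )
    return pd.DataFrame(rows)
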