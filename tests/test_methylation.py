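"""Methylation extraction: contexts, dedup, counting, conversion check."""

import numpy as np
import pandas as pd
import pytest

from allosort.io_formats import GenomeSequence
from allosort.methylation import (
    ContextError,
    assign_context,
    conversion_rate,
    deduplicate,
    extract_methylation,
    methylation_calls,
    revcomp,
)
from allosort.simulator import SimConfig, simulate_reads
from .conftest import make_aln


class TestAssignContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected_ctx,expected_tri",
        [
            ("ACGTA", 2, "+", "CG", "CGT"),
            ("ACAGA", 2, "+", "CHG", "CAG"),
            ("ACTTA", 2, "+", "CHH", "CTT"),
            # forward "ACGAT": G at pos 3 is a minus-strand C; its 5'->3'
            # trinucleotide is revcomp("ACG") = "CGT" -> CG
            ("ACGAT", 3, "-", "CG", "CGT"),
            ("CCTGA", 4, "-", "CHG", "CAG"),
            ("TTTGA", 4, "-", "CHH", "CAA"),
        ],
    )
    def test_context_definitions(self, seq, pos, strand, expected_ctx, expected_tri):
        g = GenomeSequence("p", {"chr1": seq})
        ctx, tri = assign_context(g, "chr1", pos, strand)
        assert (ctx, tri) == (expected_ctx, expected_tri)

    def test_non_cytosine_is_a_contract_violation(self):
        g = GenomeSequence("p", {"chr1": "ACGTA"})
        with pytest.raises(ContextError):
            assign_context(g, "chr1", 1, "+")  # A
        with pytest.raises(ContextError):
            assign_context(g, "chr1", 2, "-")  # C is not a minus-strand C

    def test_chromosome_end_is_undefined(self):
        g = GenomeSequence("p", {"chr1": "ACGTC"})
        assert assign_context(g, "chr1", 5, "+") == (None, None)
        g2 = GenomeSequence("p", {"chr1": "GGTA"})
        assert assign_context(g2, "chr1", 2, "-") == (None, None)


class TestDeduplicate:
    def test_same_key_keeps_first(self):
        recs = [make_aln("ACGT", read_id="a"), make_aln("ACGT", read_id="b")]
        kept = list(deduplicate(recs))
        assert [r.read_id for r in kept] == ["a"]

    def test_opposite_strands_both_kept(self):
        r1 = make_aln("ACGT", read_id="a")
        r2 = make_aln("ACGT", read_id="b")
        r2.strand = "-"
        assert len(list(deduplicate([r1, r2]))) == 2

    def test_five_reads_three_keys(self):
        recs = [
            make_aln("ACGT", pos=1, read_id="a"),
            make_aln("ACGT", pos=1, read_id="b"),
            make_aln("CGTA", pos=2, read_id="c"),
            make_aln("CGTA", pos=2, read_id="d"),
            make_aln("GTAC", pos=3, read_id="e"),
        ]
        kept = list(deduplicate(recs))
        assert [r.read_id for r in kept] == ["a", "c", "e"]

    def test_paired_key_uses_outer_coordinates(self):
        pair_a = [
            make_aln("ACGT", pos=1, read_id="a", mate=1),
            make_aln("ACGT", pos=10, read_id="a", mate=2),
        ]
        pair_b = [
            make_aln("ACGT", pos=1, read_id="b", mate=1),
            make_aln("ACGT", pos=12, read_id="b", mate=2),  # different outer end
        ]
        kept = list(deduplicate(pair_a + pair_b))
        assert sorted({r.read_id for r in kept}) == ["a", "b"]


class TestExtractMethylation:
    def test_ct_read_conversion_rule(self):
        g = GenomeSequence("p", {"chr1": "ACGTA"})
        unmeth = extract_methylation([make_aln("ATGTA", bs_strand="CT")], g)
        row = unmeth.iloc[0]
        assert (row["pos"], row["n_meth"], row["n_unmeth"]) == (2, 0, 1)
        meth = extract_methylation([make_aln("ACGTA", bs_strand="CT")], g)
        assert (meth.iloc[0]["n_meth"], meth.iloc[0]["n_unmeth"]) == (1, 0)

    def test_ga_read_counts_minus_strand_cytosines(self):
        g = GenomeSequence("p", {"chr1": "ACGAT"})
        table = extract_methylation([make_aln("ACAAT", bs_strand="GA")], g)
        row = table.iloc[0]
        assert (row["pos"], row["strand"], row["n_unmeth"]) == (3, "-", 1)
        assert row["context"] == "CG"

    def test_count_conservation(self, small_benchmark_sim):
        sim = small_benchmark_sim
        recs = sim.truth_sam1[:200]
        table = extract_methylation(recs, sim.genome1)
        expected = sum(
            len(list(methylation_calls(r, sim.genome1))) for r in recs
        )
        # boundary cytosines with undefined context are the only drops
        assert table["n_meth"].sum() + table["n_unmeth"].sum() <= expected
        assert table["n_meth"].sum() + table["n_unmeth"].sum() >= expected - 4

    def test_contexts_partition_reference_cytosines(self):
        g = GenomeSequence("p", {"chr1": "ACGCAGCTTGCA"})
        table = extract_methylation([], g, cx_all=True)
        n_c = g.sequences["chr1"][:-2].count("C")  # '+' sites with full tri
        n_g = g.sequences["chr1"][2:].count("G")
        assert len(table) == n_c + n_g
        assert set(table["context"]).issubset({"CG", "CHG", "CHH"})
        assert not table.duplicated(subset=["chrom", "pos", "strand"]).any()

    def test_overlapping_mates_counted_once(self):
        g = GenomeSequence("p", {"chr1": "AACGTTACGTT"})
        m1 = make_aln("AACGTT", pos=1, read_id="R", mate=1, bs_strand="CT")
        m2 = make_aln("CGTTAC", pos=3, read_id="R", mate=2, bs_strand="CT")
        table = extract_methylation([m1, m2], g)
        at3 = table.loc[table["pos"] == 3].iloc[0]
        assert at3["n_meth"] + at3["n_unmeth"] == 1  # mate 1 wins the overlap
        at8 = table.loc[table["pos"] == 8].iloc[0]
        assert at8["n_meth"] + at8["n_unmeth"] == 1  # mate-2-only position

    def test_strand_symmetry_under_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        g = GenomeSequence("p", {"chr1": seq})
        alns = []
        for i in range(40):
            pos = int(rng.integers(0, 250))
            bs = "CT" if rng.random() < 0.5 else "GA"
            alns.append(
                make_aln(seq[pos : pos + 40], pos=pos + 1, read_id=f"r{i}", bs_strand=bs)
            )
        fwd = extract_methylation(alns, g)

        g_rc = GenomeSequence("p", {"chr1": revcomp(seq)})
        alns_rc = [
            make_aln(
                revcomp(a.bases),
                pos=len(seq) - (a.pos + 39) + 1,
                read_id=a.read_id,
                bs_strand="GA" if a.bs_strand == "CT" else "CT",
            )
            for a in alns
        ]
        rev = extract_methylation(alns_rc, g_rc)
        key = ["context", "n_meth", "n_unmeth"]
        assert sorted(map(tuple, fwd[key].values.tolist())) == sorted(
            map(tuple, rev[key].values.tolist())
        )

    def test_per_read_level_recovery(self):
        """Pooled calls are Bernoulli(level) per context when conversion is
        perfect, so the genome-wide mean lands within 3 binomial SE."""
        cfg = SimConfig(
            genome_length=20_000,
            n_reads=2000,
            divergence=0.0,
            base_error=0.0,
            conversion=1.0,
            seed=7,
        )
        sim = simulate_reads(cfg)
        table = extract_methylation(sim.truth_sam1, sim.genome1)
        for ctx, level in cfg.meth_levels.items():
            sub = table.loc[table["context"] == ctx]
            n = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
            est = sub["n_meth"].sum() / n
            se = np.sqrt(level * (1 - level) / n)
            assert abs(est - level) <= 3 * se, (ctx, est, level, n)


class TestConversionRate:
    def test_fully_converted_control(self):
        g = GenomeSequence("control", {"chr1": "ACGCAA"})
        rep = conversion_rate([make_aln("ATGTAA", bs_strand="CT")], g)
        assert rep.rate == 1.0 and rep.n_calls == 2

    def test_arithmetic(self):
        g = GenomeSequence("control", {"chr1": "AC" + "C" * 100 + "GA"})
        alns = []
        # 99 converted + 1 unconverted call via two reads over the C run
        bases_conv = "T" * 50
        alns.append(make_aln(bases_conv, pos=3, read_id="a", bs_strand="CT"))
        alns.append(
            make_aln("C" + "T" * 49, pos=53, read_id="b", bs_strand="CT")
        )
        rep = conversion_rate(alns, g)
        assert rep.n_calls == 100
        assert rep.rate == pytest.approx(0.99)

    def test_zero_calls_is_an_error(self):
        g = GenomeSequence("control", {"chr1": "ATATA"})
        with pytest.raises(ValueError, match="undefined"):
            conversion_rate([make_aln("ATATA", bs_strand="CT")], g)

    def test_mapping_rate_reported(self):
        g = GenomeSequence("control", {"chr1": "ACGCA"})
        rep = conversion_rate(
            [make_aln("ATGTA", bs_strand="CT")], g, total_reads=10
        )
        assert rep.mapping_rate == pytest.approx(0.1)
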