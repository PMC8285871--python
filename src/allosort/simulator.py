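"""Synthetic WGBS data with known subgenome-of-origin truth.

The generator emulates the study design used to benchmark subgenome read
classification: two colinear parental genomes at a chosen per-site
divergence, context-specific methylomes, bisulfite conversion at a chosen
efficiency, and error-bearing reads with per-base Phred qualities. Because
the genomes are colinear (substitutions only, no indels), every read has a
coordinate-identical truth alignment on BOTH parents, which stands in for
the two per-parent mappings a bisulfite aligner would produce.

Composition order per read is fixed: methylation state is drawn (or looked
up, in site-fixed mode), bisulfite conversion applied, then sequencing
errors — so an error can corrupt a converted base but never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    BSRead,
    GenomeSequence,
    write_fasta,
    write_fastq,
    write_classified_sam,
)
from .methylation import assign_context

_BASES = np.frombuffer(b"ACGT", np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}

DEFAULT_METH_LEVELS = {"CG": 0.8, "CHG": 0.4, "CHH": 0.05}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the benchmark regime exercised throughout the package:
    150 bp reads at Q30 with 1% sequencing error over 1%-diverged parents,
    plant-like methylation levels (CG 0.8, CHG 0.4, CHH 0.05) and 99%
    bisulfite conversion.
    """

    genome_length: int = 100_000
    n_chroms: int = 1
    gc_content: float = 0.4
    divergence: float = 0.01
    meth_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METH_LEVELS)
    )
    conversion: float = 0.99
    meth_protection: float = 1.0
    read_length: int = 150
    n_reads: int = 5000
    base_error: float = 0.01
    phred_q: int = 30
    paired: bool = False
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    site_fixed: bool = False
    duplication_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "divergence",
            "conversion",
            "meth_protection",
            "base_error",
            "duplication_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for p, lv in self.meth_levels.items():
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"meth_levels[{p}]={lv} outside [0,1]")
        if self.genome_length <= 0 or self.read_length <= 0 or self.n_reads < 0:
            raise ValueError("lengths and counts must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds chromosome length")


def make_parent_genomes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, GenomeSequence, list[tuple[str, int, str, str]]]:
    """Sample an ancestral genome and derive two colinear diverged parents.

    Parent 2 differs from parent 1 at Bernoulli(divergence) sites, each
    substituted uniformly among the three alternative bases. Returns both
    genomes plus the divergent-site list ``(chrom, pos_1based, base1, base2)``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs1: dict[str, str] = {}
    seqs2: dict[str, str] = {}
    sites: list[tuple[str, int, str, str]] = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        codes = rng.choice(4, size=cfg.genome_length, p=probs)
        anc = _BASES[codes]
        divergent = rng.random(cfg.genome_length) < cfg.divergence
        alt = codes.copy()
        if divergent.any():
            # uniform among the 3 non-ancestral bases
            shift = rng.integers(1, 4, size=int(divergent.sum()))
            alt[divergent] = (codes[divergent] + shift) % 4
        par2 = _BASES[alt]
        s1 = anc.tobytes().decode()
        s2 = par2.tobytes().decode()
        seqs1[chrom] = s1
        seqs2[chrom] = s2
        for pos0 in np.flatnonzero(divergent):
            sites.append((chrom, int(pos0) + 1, s1[pos0], s2[pos0]))
    return (
        GenomeSequence("parent1", seqs1),
        GenomeSequence("parent2", seqs2),
        sites,
    )


def make_methylome(
    genome: GenomeSequence,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-cytosine methylation probabilities (and fixed states if asked).

    For each chromosome, ``prob_fwd``/``prob_rev`` give the per-position
    methylation probability of the forward-strand C (resp. reverse-strand C,
    i.e. forward G), from the context-specific levels; non-cytosine positions
    carry 0. In site-fixed mode Bernoulli states are drawn once per site and
    every read over the site reports that state.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    methylome: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        prob_fwd = np.zeros(n)
        prob_rev = np.zeros(n)
        for i, b in enumerate(seq):
            if b == "C":
                ctx, _ = assign_context(genome, chrom, i + 1, "+")
                if ctx is not None:
                    prob_fwd[i] = cfg.meth_levels[ctx]
            elif b == "G":
                ctx, _ = assign_context(genome, chrom, i + 1, "-")
                if ctx is not None:
                    prob_rev[i] = cfg.meth_levels[ctx]
        entry = {"prob_fwd": prob_fwd, "prob_rev": prob_rev}
        if cfg.site_fixed:
            entry["state_fwd"] = rng.random(n) < prob_fwd
            entry["state_rev"] = rng.random(n) < prob_rev
        methylome[chrom] = entry
    return methylome


@dataclass
class SimResult:
    """Everything a downstream test needs: data plus ground truth."""

    cfg: SimConfig
    genome1: GenomeSequence
    genome2: GenomeSequence
    divergent_sites: list[tuple[str, int, str, str]]
    reads: list[BSRead]
    truth_sam1: list[AlignmentRecord]
    truth_sam2: list[AlignmentRecord]
    truth: pd.DataFrame  # read_id, origin, chrom, pos, bs_strand, meth_states

    @property
    def truth_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["read_id"], self.truth["origin"]))

    def divergent_site_counts(self) -> dict[str, int]:
        """Divergent sites under each read unit's truth footprint."""
        cum: dict[str, np.ndarray] = {}
        for chrom, seq in self.genome1.sequences.items():
            ind = np.zeros(len(seq) + 1, dtype=np.int64)
            cum[chrom] = ind
        for chrom, pos, _, _ in self.divergent_sites:
            cum[chrom][pos] = 1
        for chrom in cum:
            cum[chrom] = np.cumsum(cum[chrom])
        length = self.cfg.read_length
        counts: dict[str, int] = {}
        for row in self.truth.itertuples(index=False):
            cs = cum[row.chrom]
            starts = [int(row.pos)]
            if self.cfg.paired:
                starts.append(int(row.pos2))
            n = 0
            for start in starts:
                end = min(start + length - 1, len(cs) - 1)
                n += int(cs[end] - cs[start - 1])
            counts[row.read_id] = n
        return counts

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome1": out_dir / "parent1.fasta",
            "genome2": out_dir / "parent2.fasta",
            "reads": out_dir / "reads.fastq",
            "sam1": out_dir / "reads_vs_parent1.sam",
            "sam2": out_dir / "reads_vs_parent2.sam",
            "truth": out_dir / "truth.tsv",
            "sites": out_dir / "divergent_sites.tsv",
        }
        write_fasta(self.genome1, paths["genome1"])
        write_fasta(self.genome2, paths["genome2"])
        write_fastq(self.reads, paths["reads"])
        write_classified_sam(self.truth_sam1, self.genome1, paths["sam1"])
        write_classified_sam(self.truth_sam2, self.genome2, paths["sam2"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        pd.DataFrame(
            self.divergent_sites, columns=["chrom", "pos", "base1", "base2"]
        ).to_csv(paths["sites"], sep="\t", index=False)
        return paths


def _bisulfite_convert(
    window: np.ndarray,
    start0: int,
    bs_strand: str,
    meth: dict[str, np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """Apply methylation + conversion to one read template in place.

    Returns the converted bases and a 0/1 string of per-C methylation states
    (in read order over convertible positions).
    """
    if bs_strand == "CT":
        target, repl = ord("C"), ord("T")
        prob = meth["prob_fwd"]
        state = meth.get("state_fwd")
    else:
        target, repl = ord("G"), ord("A")
        prob = meth["prob_rev"]
        state = meth.get("state_rev")
    idx = np.flatnonzero(window == target)
    states = []
    for i in idx:
        p = prob[start0 + i]
        is_meth = bool(state[start0 + i]) if state is not None else rng.random() < p
        states.append("1" if is_meth else "0")
        if is_meth:
            if rng.random() >= cfg.meth_protection:
                window[i] = repl
        else:
            if rng.random() < cfg.conversion:
                window[i] = repl
    return window, "".join(states)


def _apply_errors(window: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    errs = np.flatnonzero(rng.random(window.size) < cfg.base_error)
    for i in errs:
        cur = _IDX[chr(window[i])]
        window[i] = _BASES[(cur + rng.integers(1, 4)) % 4]
    return window


def simulate_reads(cfg: SimConfig, mode: str = "allopolyploid") -> SimResult:
    """Generate a full truth-labeled dataset.

    ``mode="allopolyploid"`` draws each read's genome of origin 50/50 and
    emits ``cfg.n_reads`` read units in total; ``mode="benchmark"`` emulates
    the progenitor benchmark (each progenitor dataset treated as if it were
    allopolyploid) and emits ``cfg.n_reads`` units per parent. Truth SAMs
    place every read on BOTH parents at the same coordinates (colinearity).
    """
    if mode not in ("allopolyploid", "benchmark"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(cfg.seed)
    genome1, genome2, sites = make_parent_genomes(cfg, rng)
    meth1 = make_methylome(genome1, cfg, rng)
    meth2 = make_methylome(genome2, cfg, rng)

    if mode == "benchmark":
        origins = ["parent1"] * cfg.n_reads + ["parent2"] * cfg.n_reads
    else:
        origins = [
            "parent1" if rng.random() < 0.5 else "parent2" for _ in range(cfg.n_reads)
        ]

    chroms = list(genome1.sequences)
    lengths = np.array([len(genome1.sequences[c]) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    reads: list[BSRead] = []
    sam1: list[AlignmentRecord] = []
    sam2: list[AlignmentRecord] = []
    truth_rows: list[dict] = []
    quals = [cfg.phred_q] * cfg.read_length
    cigar = f"{cfg.read_length}M"
    prev_unit: tuple | None = None

    for i, origin in enumerate(origins):
        rid = f"read{i:06d}"
        dup = prev_unit is not None and rng.random() < cfg.duplication_rate
        if dup:
            # a duplicate re-reads the same molecule: origin copies too
            origin, chrom, starts, bs_strand, frag_bases, frag_states = prev_unit
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            src = genome1 if origin == "parent1" else genome2
            meth = (meth1 if origin == "parent1" else meth2)[chrom]
            seq = np.frombuffer(src.sequences[chrom].encode(), np.uint8)
            if cfg.paired:
                max_insert = len(seq)
                insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
                insert = max(cfg.read_length, min(insert, max_insert))
                start1 = int(rng.integers(0, len(seq) - insert + 1))
                starts = (start1, start1 + insert - cfg.read_length)
            else:
                starts = (int(rng.integers(0, len(seq) - cfg.read_length + 1)),)
            bs_strand = "CT" if rng.random() < 0.5 else "GA"
            frag_bases = []
            frag_states = []
            for s0 in starts:
                window = seq[s0 : s0 + cfg.read_length].copy()
                window, states = _bisulfite_convert(
                    window, s0, bs_strand, meth, cfg, rng
                )
                frag_bases.append(window)
                frag_states.append(states)
        prev_unit = (origin, chrom, starts, bs_strand, frag_bases, frag_states)

        mate_bases = []
        for template in frag_bases:
            observed = _apply_errors(template.copy(), cfg, rng)
            mate_bases.append(observed.tobytes().decode())

        for m, (s0, bases) in enumerate(zip(starts, mate_bases), start=1):
            mate = m if cfg.paired else 1
            reads.append(BSRead(rid, mate, bases, list(quals)))
            for sam, genome in ((sam1, genome1), (sam2, genome2)):
                flag = 0
                if cfg.paired:
                    flag = 0x1 | 0x2 | (0x40 if mate == 1 else 0x80)
                sam.append(
                    AlignmentRecord(
                        read_id=rid,
                        genome_label=genome.label,
                        chrom=chrom,
                        pos=s0 + 1,
                        strand="+",
                        cigar=cigar,
                        bs_strand=bs_strand,
                        mapped=True,
                        bases=bases,
                        quals=list(quals),
                        mate=mate,
                        flag=flag,
                    )
                )
        row = {
            "read_id": rid,
            "origin": origin,
            "chrom": chrom,
            "pos": starts[0] + 1,
            "bs_strand": bs_strand,
            "meth_states": ";".join(frag_states),
            "is_duplicate": dup,
        }
        if cfg.paired:
            row["pos2"] = starts[1] + 1
        truth_rows.append(row)

    return SimResult(
        cfg=cfg,
        genome1=genome1,
        genome2=genome2,
        divergent_sites=sites,
        reads=reads,
        truth_sam1=sam1,
        truth_sam2=sam2,
        truth=pd.DataFrame(truth_rows),
    )
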