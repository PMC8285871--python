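# Methods

## Scope

`allosort` implements the allopolyploid-specific computational core of a
WGBS analysis: sorting bisulfite reads between two parental subgenomes
from their two per-parent alignments, extracting per-cytosine methylation,
checking bisulfite conversion efficiency, intersecting significant DMRs
with gene annotations, and benchmarking the read sorter against the
genome-concatenation baseline on truth-labeled synthetic data. It does not
run an aligner, trim reads, or call DMRs — alignments come in as SAM, DMRs
as a q-value table (dmrseq export shape).

## Scoring model

Each mapped read is scored against its reference with an independent
per-base Phred model. With `e = 10^(-q/10)`:

* aligned match: `ln(1 - e)`
* aligned mismatch: `ln(e/3)` (errors assumed uniform over the three
  alternative bases)
* inserted or deleted base: constant `ln(1e-4)` per base (CIGAR is the only
  gap information available; no gap-open/extend distinction)
* soft-clipped bases and columns with N on either side: skipped, zero
  contribution.

Bisulfite awareness collapses the alphabet per conversion strand: for a
read tagged `CT` (observed from the C→T-converted template), any C/T
pairing between read and reference is a match in **both** directions; for
`GA` reads, any G/A pairing. This mirrors three-letter alignment (the
aligner reduces read *and* genome, so reference-T/read-C is also a match)
and gives the model its key invariance: an error-free read scores
identically whether its template cytosines were methylated (retained as C)
or converted (read as T) — classification never mistakes conversion for
divergence, at the cost of ignoring genuine C/T (G/A) divergence between
the parents on the corresponding strand. `bs_mode` selects `strand`
(per-read tag; default), `both` (tag-free input) or `off`.

The mismatch term is quality-aware, so a divergent site covered at Q30
moves the log-odds by `ln(0.999) − ln(0.001/3) ≈ 8.0`, while a low-quality
base barely moves it. Only the best-scoring primary alignment per
(read, mate, genome) represents a side; marginalizing over candidate loci
is not attempted.

## Classification

For each read unit (read, or mate pair), `log_odds = loglik(parent1) −
loglik(parent2)` summed over mates mapped on both sides. Verdicts:
`parent1`/`parent2` by sign when `|log_odds| > tie_margin`, else
`ambiguous`. `tie_margin` defaults to 0 with equality tested at 1e-9
absolute — on colinear genomes an exact tie occurs precisely when the two
aligned windows are bisulfite-indistinguishable. Reads mapped on one side
only are `unique_parent1/2` and kept distinct from the likelihood-based
calls so downstream consumers can include or exclude them explicitly.
Paired units where each side maps only a different mate carry no symmetric
evidence and are called ambiguous with log-odds 0.

Deduplication (first-seen wins) keys on (chromosome, leftmost position,
strand), extended with the mate-pair outer coordinates for paired ends,
and is applied per genome side before scoring; a read removed on one side
is dropped from the comparison entirely so both sides see the same units.

## Benchmark design

Reads simulated from a known parent are treated as allopolyploid reads and
classified; the error rate is wrong assignments divided by all uniquely
mapped, deduplicated read units (ambiguous reads stay in the denominator,
`--denominator=assigned` offers the stricter reading). The concatenated
baseline is an emulation, not an aligner rerun: the same candidate loci,
scored with the same model, assigned to the genome with the strictly best
score; ties (beyond 1e-9) are non-unique and leave the baseline's
denominator. With zero assignable reads either rate is reported as 0.0
with its zero denominator alongside, keeping rates in [0, 1] on degenerate
inputs such as identical parents.

Because both methods share the same scores, they make the same wrong
calls; the baseline's error rate is higher exactly because its denominator
excludes the tied reads that the classifier honestly labels ambiguous. One
consequence, measured at the default conditions and deliberately left
visible as a failing end-to-end check: the classifier's error rate under
this denominator is *not* monotone in parental divergence (0.00036 at
0.001, 0.00168 at 0.01, 0.00006 at 0.05 divergence, means over seeds 1–5).
At low divergence most reads cover no informative site, so the numerator
(wrongs require exactly one informative, error-flipped site) shrinks
faster than the difficulty grows while the denominator stays fixed. The
per-assigned-read error is monotone; the two readings answer different
questions and the package reports the inputs to both.

## Methylation extraction and conversion check

Cytosine context is a deterministic function of the trinucleotide 5'→3' on
the cytosine's strand: `CG` if the next base is G, else `CHG` if the base
after is G, else `CHH` (H ∈ {A, T, C}). Cytosines whose trinucleotide runs
off the chromosome end have undefined context and are skipped with a
warning. `CT` reads call forward-strand cytosines (read C methylated, read
T unmethylated); `GA` reads call reverse-strand cytosines over reference
Gs. Other read bases, read/reference Ns, and the mate-2 half of an
overlapping mate pair are ignored. The output is a Bismark-CX-shaped TSV;
`--cx-all` emits zero-coverage rows too.

Conversion efficiency on an assumed-unmethylated control genome is
`n_unmeth / (n_meth + n_unmeth)` over all control calls; the control
mapping rate (the common report-level proxy: the lower, the better the
conversion) is also emitted when the total read count is supplied.

## DMR–gene overlap

Significance is strict (`q < alpha`, default 0.05; `q = 0.05` drops). All
intervals are 1-based closed, so "at least 1 bp overlap" is `end1 ≥ start2
∧ end2 ≥ start1`; gene strand is ignored. Per-context counts report
significant DMRs and distinct genes; the total counts a gene once however
many contexts hit it. Feature rows of GFF3 type `gene` are used by
default (`--feature-type` overrides).

## Synthetic data

The generator emulates the progenitor-benchmark design: an ancestral
sequence sampled at a chosen GC content (default 0.4, plant-like), a
second parent derived by Bernoulli(divergence) substitutions uniform over
the three alternatives, and reads drawn uniformly with equal CT/GA strand
probability. Because the parents are colinear (no indels), every read has
a coordinate-identical truth alignment on both genomes, standing in for
the two per-parent mappings an aligner would produce. Defaults define the
reference study conditions: 100 kb single chromosome, 1% divergence,
150 bp single-end reads at Q30, 1% sequencing error, methylation levels
CG 0.8 / CHG 0.4 / CHH 0.05, 99% conversion, full methyl protection.
Methylation state is drawn per read by default (cell-population
heterogeneity); `site_fixed` freezes one Bernoulli state per site for
recovery tests. Composition order is fixed: methylation, then conversion,
then sequencing error. A `duplication_rate` knob re-emits the previous
fragment (same molecule, same origin) under a new id. Outputs are
byte-deterministic given config + seed.

What the simulator does **not** model — and hence what green tests do not
establish about real data: structural divergence and indels between
parents (real subgenome sorting also faces missing or collapsed loci),
assembly quality asymmetry, realistic quality profiles and M-bias,
PCR/optical duplicate structure, non-uniform coverage, and an actual
bisulfite aligner's mapping errors. The benchmark's published-scale error
rates on real progenitor datasets (e.g. *A. halleri* ≈ 1.2% classified vs
≈ 4.0% concatenated) sit far above the synthetic rates here because real
data carry all of those effects; this package reproduces the *ordering*
and the mechanism, not the magnitudes.

## Numerical choices and edge cases

* Likelihoods in natural log, float64; the vectorized scorer agrees with a
  scalar per-base summation to < 1e-9 (tested on 1000 random pairs).
* Tie tolerance 1e-9 absolute wherever "equal" scores are compared
  (ambiguity call, baseline uniqueness).
* Q = 0 bases give `ln(1-e) = -inf` for a match — mathematically forced;
  simulated qualities are ≥ 2.
* IUPAC ambiguity codes in FASTA become N (warning) and are skipped in
  scoring and counting rather than rejected.
* Degenerate inputs: empty SAMs classify to an empty table; zero control
  cytosine calls make the conversion rate an error rather than a silent
  NaN.

## Problem sizes

Test-suite and acceptance runs use 20–100 kb genomes with 500–10 000 read
units per run (30× coverage for methylation recovery, 2 × 5000 reads per
benchmark run, 5 seeds), sizes at which every binomial check has
comfortable power while a full run of the suite plus the acceptance script
completes in a few minutes on one CPU.
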