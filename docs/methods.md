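# Methods

## The mapping model

A bisulfite read differs from its reference locus through four confounded
processes: bisulfite conversion of unmethylated cytosines (C→T on the
read's own strand, seen as G→A in forward-genome coordinates for reads
descended from the PCR-synthesized strand), genomic variation, sequencing
error, and low-quality base calls. `probsmap` treats the read
probabilistically throughout rather than making hard decisions early.

**Base probabilities.** A called base with Phred quality Q is modelled as
the true base with probability 1−ε, ε = 10^(−Q/10), and each of the other
three bases with probability ε/3; an N is uniform. This is the standard
probabilistic-alignment observation model; in the Q→∞ limit the aligner
reduces exactly to classical Needleman–Wunsch on the literal strings (a
property the test suite checks against Biopython's `PairwiseAligner`).

**Scoring.** The substitution score of read position i against genome
base g is the expectation Σ_b P_i(b)·M(b,g) with M the match/mismatch
matrix. Bisulfite chemistry is a one-sided edit to M: in CT mode
M(T,C) = match (an unmethylated, converted cytosine is not a mismatch)
while M(C,T) stays a mismatch — the asymmetry matters, because a read C
over a genome T is real evidence against the locus. GA mode applies the
mirrored edit M(A,G) = match. Genome N scores as a mismatch against
everything.

**Alignment shape.** The read is consumed in full; the genome window
(candidate start ± a pad of 5 bp) has free overhangs on both sides, so
the score does not depend on the padding. Gaps are affine with defaults
match +1, mismatch −1, gap open −4, gap extend −1: a read-length score
scale on which a 100-bp read tolerates up to five mismatches, or one
indel plus three mismatches, at the default acceptance fraction
a = 0.90. The threshold is a·L_eff·match where L_eff is the effective
read length after QC (3′ trimming at quality ≤ 2, N-masking at quality
≤ 2), so trimmed reads are held to a proportionally lower bar. The full
dynamic program is computed exactly (numba-compiled kernels; a pure-
Python fallback produces identical results); no banding or heuristic
pruning is applied. Traceback ties break deterministically: diagonal
over read-gap over genome-gap, earliest end column, gap-open preferred
over extension.

**Seeding.** The forward genome is hashed twice at k = 17, step 1 (the
defaults; tests use k = 3–5): once C→T-converted and once G→A-converted.
The GA table is not redundant — a C→T index retains G/A distinctions
that reads from the PCR-synthesized strands have lost, so those reads
cannot be seeded through any transform against a CT-only index
(CT(revcomp(S)) = revcomp(GA(S)) puts their keys on the other strand's
conversion). Each read is looked up in four passes, (mode, strand) ∈
{CT, GA} × {+, −}, reverse-complementing before conversion on the minus
strand; a directional-library switch restricts to (CT,+) and (GA,−).
Every k-mer of the converted read votes for the alignment start implied
by its hit's diagonal; candidates whose vote counts fall within the top
two distinct counts (capped at 50) proceed to alignment. N-containing
windows and k-mers spanning chromosome boundaries are never hashed.

**Best-match set and posteriors.** All threshold-passing alignments are
pooled across the four passes; duplicate (chromosome, position, strand)
entries arising from both modes keep the higher-scoring mode, with
near-ties (within 10⁻⁴ per effective base, the magnitude of the
quality-noise difference between the CT and GA matrices when no
conversion evidence exists) resolved deterministically in favour of CT.
The pooled list is ranked by score and truncated at 20 locations; the
retained scores are softmax-normalized into posterior mapping
probabilities. SAM output carries the exact posterior in `XP:f`, the
mode in `XB:A`, the rounded score in `AS:i`, and a derived
MAPQ = round(−10·log₁₀(1−P)) capped at 60 (the cap also serves P = 1);
non-best hits are flagged secondary, unmapped reads are emitted with
flag 0x4.

**Methylation calling.** Each aligned (read, genome) base pair at a
genomic C (CT-mode hits) adds the hit's posterior to that base's
weighted tally at the site; GA-mode hits do the same at genomic Gs with
complemented bases, attributing the evidence to the reverse-strand
cytosine. The ratio is weighted-C/(weighted-C + weighted-T), undefined
(reported `NA`) without C/T evidence. Gapped positions contribute
nothing. Significance is a one-sided binomial likelihood-ratio test of
P(C) = null rate (default 0.01) against the observed ratio, on rounded
effective counts, with the statistic 2[ℓ(ĉ)−ℓ(c₀)] referred to χ²₁; the
rounding keeps the χ² reference defensible for fractional posterior
masses, and observed ratios at or below the null give p = 1 by
construction. The per-cytosine table (`gmp` text format) has one row per
genomic C and G; `--merge-cg` sums the two strands of each CpG dyad into
a single record at the C's position, which is the natural unit when
dyads share one methylation state. A concordance statistic — the
fraction of shared sites whose two estimates differ by less than a
cutoff (default 0.25) — supports comparison against external methylome
profiles.

## The simulator

The generator reproduces a typical mammalian whole-genome BS-seq design:
an i.i.d. genome at GC 0.42; CpG dyads labelled 20% unmethylated (level
0), 75% fully methylated (level 1), 5% partially methylated with levels
uniform on [0.1, 0.9] — both cytosines of a dyad share the level, as CpG
maintenance methylation does — and all non-CpG cytosines unmethylated.
Reads are 100 bp at 10× nominal depth (N = coverage·genome/read-length,
so 5% random-sequence decoy reads leave ≈9.5× genomic depth), drawn
uniformly from both strands, mutated at 0.002/base (20% of mutations are
1-bp indels, insertion or deletion with equal probability), converted by
per-site Bernoulli draws with probability 1−level per read-frame
cytosine — which is what partial methylation requires and subsumes the
all-or-none cases — and then corrupted by substitution errors at a rate
rising linearly from 0.001 (cycle 1) to 0.008 (cycle 100), with Phred
qualities set from the per-cycle rate (capped at Q40 when a rate is 0).
Truth records the origin coordinates, strand, class, and mutation/error
counts per read; identical seeds give byte-identical FASTQ and truth
output.

Evaluation calls a primary alignment correct when chromosome and strand
match the truth and the position is within ±5 bp — a tolerance absorbing
indel-induced shifts; both the non-random-read denominator and an
all-reads convention are reported, along with the stratum of reads
carrying at least one mutation or sequencing error.

What the simulator does *not* emulate: real genomes' repeat structure
and CpG islands (an i.i.d. genome is nearly repeat-free, so multi-mapping
is rarer than in mammalian data and measured specificity is optimistic),
quality miscalibration, adapter read-through, PCR duplicates,
non-uniform coverage, CHG/CHH methylation, and paired-end fragments.
Passing results on synthetic data therefore demonstrate correctness of
the algorithms under the stated model, not field performance on a human
genome.

## Evaluation design and problem sizes

The standard study (tests and `scripts/acceptance.py`) uses a 200 kb
genome — about 20,000 reads and 17,000 CpG dyads — which runs the whole
pipeline in tens of seconds on one CPU while leaving per-metric sampling
error well below the margins being checked. The error-free recovery
check uses 5,000 reads on 100 kb; the alignment-oracle check compares
the DP against exhaustive enumeration on 500 tiny instances (reads ≤ 6
nt, windows ≤ 9 nt), where enumeration is feasible and exact.

A note on the methylation-accuracy metric: at ≈9.5× genomic depth a
per-site estimate from n ≈ Poisson(10) hard C/T observations carries an
irreducible binomial error — E|Bin(n,p)/n − p| ≈ 0.11–0.12 averaged over
p ~ U(0.1, 0.9) — so the measured mean absolute error over partially
methylated dyads (≈0.11–0.13 depending on seed) is dominated by sampling
noise, not by alignment or attribution mistakes; it shrinks with
coverage as 1/√n (the test suite checks the high-coverage limit
separately).

## Design choices made where the design was open

- **Read-side strand handling with a dual-conversion index** (CT + GA
  tables over the forward strand) rather than hashing both strands of
  the genome: equivalent hit set, one coordinate space, no reverse-strand
  bookkeeping in the index.
- **Diagonal voting** for seed aggregation (as opposed to counting raw
  hash hits per locus): hits that agree on a diagonal are the ones a
  gapped alignment can actually reconcile; indels split a read's votes
  across two adjacent diagonals, both of which then fall in the top two
  counts.
- **J (best-match set) definition:** all threshold-passing hits, ranked
  by score, truncated at 20; ties at the cutoff drop in (chromosome,
  position) order. MAPQ from the posterior is a convenience for SAM
  consumers; `XP` is authoritative.
- **Posterior-weighted counting** (fractional evidence) rather than
  1/#mappings: the softmax posterior discounts inferior locations
  instead of averaging over them.
- **Unmapped rather than rescued:** reads whose every candidate fails
  the threshold are reported unmapped; there is no exhaustive-scan
  fallback, matching seeded-aligner behaviour.
- **Parallelism contract:** reads are processed in independent chunks
  merged in input order; output is byte-identical for 1 vs N workers
  (checked in the tests).

## Known limitations

- Single-end reads only; no paired-end mating or BAM/CRAM output.
- Local (soft-clipped) alignment is not offered; a read crossing a
  structural breakpoint will fail the threshold rather than clip.
- The significance test treats rounded posterior masses as counts; at
  very low coverage the χ² reference is approximate.
- Indels longer than the window pad (5 bp) are not representable.
- Ambiguity codes other than N in references are collapsed to N.
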