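"""Bisulfite sequencing simulation with ground truth, and truth-based evaluation.

The generator emulates a whole-genome bisulfite experiment: an i.i.d.
random genome, CpG-dyad methylation states (20% unmethylated, 75% fully
methylated, 5% partially methylated with levels uniform on [0.1, 0.9];
all non-CpG cytosines unmethylated), and 100-bp single-end reads at 10x
depth sampled uniformly from both strands.  Reads acquire genomic
variation (mutation rate 0.002, of which 20% are 1-bp indels), per-site
Bernoulli bisulfite conversion (each read-frame cytosine converts to T
with probability 1 minus its site's methylation level), and a
position-dependent sequencing-error ramp rising linearly from 0.001 at
the 5' end to 0.008 at the 3' end, with Phred qualities set from that
ramp.  5% of reads are uniform random sequence.  Truth (origin, strand,
class, variant counts) is recorded for every read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference_index import ReferenceGenome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationParams:
    read_length: int = 100
    coverage: float = 10.0
    error_rate_5p: float = 0.001
    error_rate_3p: float = 0.008
    random_read_fraction: float = 0.05
    mutation_rate: float = 0.002
    indel_fraction_of_mutations: float = 0.2
    frac_unmethylated: float = 0.20
    frac_full: float = 0.75
    frac_partial: float = 0.05
    partial_low: float = 0.1
    partial_high: float = 0.9

    def __post_init__(self) -> None:
        total = self.frac_unmethylated + self.frac_full + self.frac_partial
        if abs(total - 1.0) > 1e-9:
            raise ValueError("methylation class fractions must sum to 1")
        for r in (
            self.error_rate_5p, self.error_rate_3p,
            self.random_read_fraction, self.mutation_rate,
            self.indel_fraction_of_mutations,
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class MethylationProfile:
    """True methylation level of every cytosine (both strands).

    ``level`` is indexed by global genome offset and is meaningful at
    genomic C positions (forward-strand cytosines) and G positions
    (reverse-strand cytosines); the two cytosines of a CpG dyad share
    one level.  ``dyads`` lists the global offsets of each dyad's C with
    its class label.
    """

    genome_digest: str
    level: np.ndarray  # float, per global offset
    dyads: pd.DataFrame  # columns: gpos, label, level

    def level_at(self, genome: ReferenceGenome, chrom: str, pos1: int) -> float:
        return float(self.level[genome.global_offset(chrom, pos1 - 1)])

    def dyad_table(self, genome: ReferenceGenome) -> pd.DataFrame:
        """Dyads with chromosome coordinates (1-based position of the C)."""
        gpos = self.dyads["gpos"].to_numpy()
        bidx = np.searchsorted(genome.boundaries, gpos, side="right") - 1
        out = self.dyads.copy()
        out["chrom"] = np.asarray(genome.names, dtype=object)[bidx]
        out["pos"] = gpos - genome.boundaries[bidx] + 1
        return out


@dataclass
class SimulatedRead:
    id: str
    bases: str
    quals: np.ndarray
    chrom: str | None  # None for random-sequence reads
    start: int | None  # 1-based leftmost position on the forward strand
    strand: str | None
    origin: str  # "genomic" or "random"
    n_mutations: int = 0
    n_errors: int = 0

    @property
    def has_variant(self) -> bool:
        return self.n_mutations + self.n_errors > 0


def simulate_genome(
    length: int, gc_fraction: float = 0.42, seed: int | np.random.Generator = 0,
    name: str = "chrSim",
) -> ReferenceGenome:
    """I.i.d. random genome with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = _BASES[codes].tobytes().decode()
    return ReferenceGenome([(name, seq)])


def assign_methylation(
    genome: ReferenceGenome,
    params: SimulationParams | None = None,
    seed: int | np.random.Generator = 0,
) -> MethylationProfile:
    """Label every CpG dyad unmethylated / fully / partially methylated.

    Both cytosines of a dyad share the drawn level; every non-CpG
    cytosine has level 0 (no non-CG methylation).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    level = np.zeros(genome.total_length)
    is_c = seq == ord("C")
    is_g = seq == ord("G")
    # dyad = C at p, G at p+1, within one chromosome
    dyad_pos = np.flatnonzero(is_c[:-1] & is_g[1:])
    chrom_end = genome.boundaries[
        np.searchsorted(genome.boundaries, dyad_pos, side="right")
    ]
    dyad_pos = dyad_pos[dyad_pos + 1 < chrom_end]
    n = dyad_pos.size
    labels = rng.choice(
        3, size=n,
        p=[params.frac_unmethylated, params.frac_full, params.frac_partial],
    )
    levels = np.zeros(n)
    levels[labels == 1] = 1.0
    n_partial = int((labels == 2).sum())
    levels[labels == 2] = rng.uniform(params.partial_low, params.partial_high, n_partial)
    level[dyad_pos] = levels
    level[dyad_pos + 1] = levels
    label_names = np.array(["unmethylated", "full", "partial"])
    dyads = pd.DataFrame(
        {"gpos": dyad_pos, "label": label_names[labels], "level": levels}
    )
    return MethylationProfile(genome.digest(), level, dyads)


def _mutate(
    frag: np.ndarray, src: np.ndarray, rate: float, indel_frac: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Apply point mutations and 1-bp indels; track source genome offsets.

    ``src`` maps each fragment base to its genomic offset (-1 for inserted
    bases).  Returns the mutated fragment, its source map, and the number
    of mutations applied.
    """
    n_mut = rng.binomial(frag.size, rate)
    if n_mut == 0:
        return frag, src, 0
    sites = rng.choice(frag.size, size=n_mut, replace=False)
    frag = frag.copy()
    src = src.copy()
    is_indel = rng.random(n_mut) < indel_frac
    # substitutions first (positions stable), then indels right-to-left
    for s in sites[~is_indel]:
        old = frag[s]
        new = _BASES[rng.integers(4)]
        while new == old:
            new = _BASES[rng.integers(4)]
        frag[s] = new
    frag_l = list(frag)
    src_l = list(src)
    for s in sorted(sites[is_indel], reverse=True):
        if rng.random() < 0.5 and len(frag_l) > 1:  # deletion
            del frag_l[s]
            del src_l[s]
        else:  # insertion of one random base after s
            frag_l.insert(s, _BASES[rng.integers(4)])
            src_l.insert(s, -1)
    return (
        np.asarray(frag_l, dtype=np.uint8),
        np.asarray(src_l, dtype=np.int64),
        int(n_mut),
    )


def simulate_reads(
    genome: ReferenceGenome,
    profile: MethylationProfile,
    params: SimulationParams | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SimulatedRead]:
    """Generate N = round(coverage * genome_length / read_length) reads."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    L = params.read_length
    if genome.total_length <= L:
        raise ValueError("genome shorter than the read length")
    n_reads = int(round(params.coverage * genome.total_length / L))
    err = np.linspace(params.error_rate_5p, params.error_rate_3p, L)
    # Phred from the per-cycle error rate, capped at Q40 for error-free cycles
    quals = np.round(-10.0 * np.log10(np.maximum(err, 1e-4))).astype(np.int64)
    seq_codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    slack = 8  # extra genome bases so deletions still fill the read
    reads: list[SimulatedRead] = []
    # valid fragment starts: fragment + slack within one chromosome
    starts_hi = np.asarray(genome.boundaries[1:]) - (L + slack)
    starts_lo = np.asarray(genome.boundaries[:-1])
    valid_spans = [
        (int(lo), int(hi)) for lo, hi in zip(starts_lo, starts_hi) if hi >= lo
    ]
    if not valid_spans:
        raise ValueError("no chromosome long enough for the read length")
    span_lens = np.array([hi - lo + 1 for lo, hi in valid_spans], dtype=np.float64)
    span_p = span_lens / span_lens.sum()

    for i in range(n_reads):
        rid = f"sim_{i:07d}"
        if rng.random() < params.random_read_fraction:
            bases = _BASES[rng.integers(0, 4, size=L)]
            bases, n_err = _sequencing_errors(bases, err, rng)
            reads.append(
                SimulatedRead(
                    rid, bases.tobytes().decode(), quals.copy(),
                    None, None, None, "random", 0, n_err,
                )
            )
            continue
        span = valid_spans[rng.choice(len(valid_spans), p=span_p)]
        gstart = int(rng.integers(span[0], span[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq_codes[gstart : gstart + L + slack].copy()
        src = np.arange(gstart, gstart + L + slack, dtype=np.int64)
        if strand == "-":
            frag = _revcomp_codes(frag)
            src = src[::-1].copy()
        frag, src, n_mut = _mutate(
            frag, src, params.mutation_rate, params.indel_fraction_of_mutations, rng
        )
        frag = frag[:L]
        src = src[:L]
        # bisulfite chemistry: read-frame Cs convert with prob 1 - level
        is_read_c = frag == ord("C")
        if is_read_c.any():
            idx = np.flatnonzero(is_read_c)
            lv = np.zeros(idx.size)
            target = ord("C") if strand == "+" else ord("G")
            for j, s in enumerate(idx):
                g = src[s]
                if g >= 0 and seq_codes[g] == target:
                    lv[j] = profile.level[g]
            convert = rng.random(idx.size) >= lv
            frag[idx[convert]] = ord("T")
        # truth start: leftmost forward-genome position of the fragment
        true_start = int(src[src >= 0].min()) if (src >= 0).any() else gstart
        chrom, pos0 = genome.locate(true_start)
        frag, n_err = _sequencing_errors(frag, err, rng)
        reads.append(
            SimulatedRead(
                rid, frag.tobytes().decode(), quals.copy(),
                chrom, pos0 + 1, strand, "genomic", n_mut, n_err,
            )
        )
    return reads


_RC_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_LUT[_a] = _b


def _revcomp_codes(frag: np.ndarray) -> np.ndarray:
    return _RC_LUT[frag][::-1].copy()


def _sequencing_errors(
    frag: np.ndarray, err: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    hit = rng.random(frag.size) < err[: frag.size]
    idx = np.flatnonzero(hit)
    if idx.size:
        frag = frag.copy()
        for s in idx:
            old = frag[s]
            new = _BASES[rng.integers(4)]
            while new == old:
                new = _BASES[rng.integers(4)]
            frag[s] = new
    return frag, int(idx.size)


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = "".join(chr(33 + int(x)) for x in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{q}\n")


def write_truth(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tchrom\tpos\tstrand\torigin\tn_mutations\tn_errors\n")
        for r in reads:
            chrom = r.chrom or "NA"
            pos = r.start if r.start is not None else 0
            strand = r.strand or "NA"
            fh.write(
                f"{r.id}\t{chrom}\t{pos}\t{strand}\t{r.origin}\t"
                f"{r.n_mutations}\t{r.n_errors}\n"
            )


def read_truth(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame.columns = ["id", "chrom", "pos", "strand", "origin", "n_mutations", "n_errors"]
    return frame


def write_profile(
    profile: MethylationProfile, genome: ReferenceGenome, path: str | Path
) -> None:
    """True dyad levels as TSV: chrom, 1-based C position, label, level."""
    table = profile.dyad_table(genome)
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tlabel\tlevel\n")
        for row in table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.label}\t{row.level:.6f}\n")


def read_profile_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame.columns = ["chrom", "pos", "label", "level"]
    return frame


def evaluate_alignments(
    truth: Sequence[SimulatedRead] | pd.DataFrame,
    sam_path: str | Path,
    tolerance: int = 5,
) -> dict:
    """Score primary alignments against simulation truth.

    An alignment is correct when chromosome and strand match the truth
    and the reported position is within ``tolerance`` bases.  Fractions
    use non-random reads as the denominator (random-sequence reads are
    reported separately, and an all-reads convention is included).
    """
    if isinstance(truth, pd.DataFrame):
        frame = truth
    else:
        frame = pd.DataFrame(
            {
                "id": [r.id for r in truth],
                "chrom": [r.chrom or "NA" for r in truth],
                "pos": [r.start or 0 for r in truth],
                "strand": [r.strand or "NA" for r in truth],
                "origin": [r.origin for r in truth],
                "n_mutations": [r.n_mutations for r in truth],
                "n_errors": [r.n_errors for r in truth],
            }
        )
    info = {
        row.id: row for row in frame.itertuples(index=False)
    }
    aligned: dict[str, tuple[str, int, str]] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in aligned:
                raise ValueError(f"multiple primary alignments for {rec.query_name}")
            strand = "-" if rec.is_reverse else "+"
            aligned[rec.query_name] = (
                rec.reference_name, rec.reference_start + 1, strand
            )
    missing = set(aligned) - set(info)
    if missing:
        raise ValueError(f"SAM read ids absent from truth: {sorted(missing)[:3]}...")

    def tally(rows) -> dict:
        total = len(rows)
        n_aligned = n_correct = 0
        for row in rows:
            hit = aligned.get(row.id)
            if hit is None:
                continue
            n_aligned += 1
            chrom, pos, strand = hit
            if (
                row.origin == "genomic"
                and chrom == row.chrom
                and strand == row.strand
                and abs(pos - row.pos) <= tolerance
            ):
                n_correct += 1
        n_incorrect = n_aligned - n_correct
        frac = lambda x: x / total if total else float("nan")
        return {
            "n_reads": total,
            "n_aligned": n_aligned,
            "n_correct": n_correct,
            "n_incorrect": n_incorrect,
            "aligned_fraction": frac(n_aligned),
            "correct_fraction": frac(n_correct),
            "incorrect_fraction": frac(n_incorrect),
        }

    rows = list(info.values())
    genomic = [r for r in rows if r.origin == "genomic"]
    random_rows = [r for r in rows if r.origin != "genomic"]
    variant = [r for r in genomic if (r.n_mutations + r.n_errors) > 0]
    return {
        "tolerance": tolerance,
        "non_random": tally(genomic),
        "random": tally(random_rows),
        "all_reads": tally(rows),
        "with_variant": tally(variant),
    }


def evaluate_methylation(
    estimates: "pd.DataFrame | object",
    profile_table: pd.DataFrame,
    genome: ReferenceGenome | None = None,
) -> dict:
    """Mean |estimated - true| level over partially methylated dyads.

    ``estimates`` is a dyad-merged methylome table (or its frame) keyed by
    (chrom, pos of the dyad's C); only dyads with a defined ratio (>= 1
    informative covering read) enter the average.
    """
    frame = getattr(estimates, "frame", estimates)
    est = frame[frame["ratio"].notna()].set_index(["chrom", "pos"])["ratio"]
    partial = profile_table[profile_table["label"] == "partial"]
    diffs = []
    for row in partial.itertuples(index=False):
        key = (row.chrom, row.pos)
        if key in est.index:
            diffs.append(abs(float(est.loc[key]) - row.level))
    diffs = np.asarray(diffs)
    return {
        "n_sites": int(diffs.size),
        "mean_abs_error": float(diffs.mean()) if diffs.size else float("nan"),
        "sd_abs_error": float(diffs.std(ddof=1)) if diffs.size > 1 else float("nan"),
    }
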