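"""End-to-end bisulfite read mapping.

Seeds are exact k-mer matches in the converted alphabet; each seed votes
for a candidate alignment start (diagonal voting), the candidates with
the top two vote counts are aligned with the probabilistic
Needleman-Wunsch against the *original* genome, and every alignment
clearing the adaptive threshold enters the best-match set.  The scores
of that set are converted to posterior mapping probabilities by a
softmax, so a uniquely mapping read gets posterior 1 and multi-mapped
reads split their evidence.

Four search passes cover the non-directional bisulfite protocol:
(CT, +) original top strand, (CT, -) PCR complement of the top strand,
(GA, +) PCR complement of the bottom strand, (GA, -) original bottom
strand.  Mode names refer to the scoring applied in forward-genome
coordinates after any reverse complementing of the read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from . import __version__
from .prob_align import (
    BisulfiteRead,
    ScoringScheme,
    alignment_score,
    min_score_threshold,
    prob_needleman_wunsch,
    read_to_pwm,
)
from .reference_index import (
    GenomeIndex,
    KmerHashTable,
    ReferenceGenome,
    bs_convert_sequence,
    reverse_complement,
)

PASSES = (("CT", "+"), ("CT", "-"), ("GA", "+"), ("GA", "-"))
DIRECTIONAL_PASSES = (("CT", "+"), ("GA", "-"))


@dataclass
class MappingHit:
    """One candidate alignment of a read, with its posterior probability."""

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost aligned genome position
    strand: str  # "+" or "-"
    mode: str  # "CT" or "GA"
    score: float
    cigar: str
    posterior: float = 0.0
    # read in forward-genome orientation (reverse-complemented for - hits)
    genome_frame_bases: str = ""
    genome_frame_quals: np.ndarray | None = None


@dataclass
class HitSet:
    read_id: str
    hits: list[MappingHit] = field(default_factory=list)
    passed_threshold: bool = False
    read: BisulfiteRead | None = None


@dataclass
class MapperConfig:
    a_fraction: float = 0.90
    max_hits: int = 20
    top_n_candidates: int = 50
    pad: int = 5  # window padding = maximum representable indel shift
    directional: bool = False
    mask_quality: int = 2
    trim_quality: int = 2
    scheme: ScoringScheme = field(default_factory=ScoringScheme)


def candidate_locations(
    read: BisulfiteRead,
    table: KmerHashTable,
    mode: str,
    strand: str,
    top_n: int = 50,
) -> list[int]:
    """Diagonal-voting seed lookup.

    The read is reverse-complemented first for the minus strand, then
    converted (C->T or G->A) to the index alphabet.  Every k-mer at
    offsets {0, step, ...} is looked up; a genome hit at offset o seen
    from read offset j votes for alignment start o - j.  Candidates whose
    vote counts fall in the top two distinct counts are returned, capped
    at ``top_n`` (ties broken by ascending offset).
    """
    k, step = table.k, table.step
    bases = read.bases if strand == "+" else reverse_complement(read.bases)
    conv = bs_convert_sequence(bases, mode)
    L = len(conv)
    if L < k:
        return []
    votes: dict[int, int] = {}
    for j in range(0, L - k + 1, step):
        kmer = conv[j : j + k]
        if "N" in kmer:
            continue
        for o in table.lookup(kmer):
            start = int(o) - j
            votes[start] = votes.get(start, 0) + 1
    if not votes:
        return []
    counts = sorted(set(votes.values()), reverse=True)
    keep = set(counts[:2])
    cands = sorted(
        (start for start, c in votes.items() if c in keep),
        key=lambda s: (-votes[s], s),
    )
    return cands[:top_n]


def posterior_probabilities(scores: Sequence[float]) -> np.ndarray:
    """Softmax of alignment scores: P_d = exp(q_d) / sum_j exp(q_j)."""
    q = np.asarray(scores, dtype=np.float64)
    if q.size == 0:
        raise ValueError("no scores")
    if not np.all(np.isfinite(q)):
        raise ValueError("scores must be finite")
    z = np.exp(q - q.max())
    return z / z.sum()


_MODE_RANK = {"CT": 0, "GA": 1}


def align_read(
    read: BisulfiteRead,
    genome: ReferenceGenome,
    index: GenomeIndex,
    config: MapperConfig | None = None,
) -> HitSet:
    """Map one QC'd read: seed, align all four passes, pool, and weight.

    Returns an empty HitSet (``passed_threshold`` False) when no
    candidate alignment clears the adaptive score threshold.
    """
    config = config or MapperConfig()
    hitset = HitSet(read_id=read.id, read=read)
    if not read.mappable:
        return hitset
    threshold = min_score_threshold(
        read.effective_length, config.a_fraction, config.scheme
    )
    pad = config.pad
    L = len(read.bases)
    pwm_fw = read_to_pwm(read)
    rc_read = BisulfiteRead(
        read.id, reverse_complement(read.bases), read.quals[::-1].copy(),
        effective_length=read.effective_length,
    )
    pwm_rc = read_to_pwm(rc_read)
    passes = DIRECTIONAL_PASSES if config.directional else PASSES

    # score-only pass over all candidates of all passes
    pooled: list[tuple[str, str, int, int, np.ndarray]] = []
    for mode, strand in passes:
        scheme = config.scheme.with_mode(mode)
        pwm = pwm_fw if strand == "+" else pwm_rc
        for start in candidate_locations(
            read, index.table(mode), mode, strand, config.top_n_candidates
        ):
            lo, hi = genome.chrom_span(min(max(start, 0), genome.total_length - 1))
            wstart = max(start - pad, lo)
            wend = min(start + L + pad, hi)
            if wend - wstart < L:
                continue
            window = genome.fetch(wstart, wend)
            score = alignment_score(pwm, window, scheme)
            if score >= threshold:
                pooled.append((mode, strand, wstart, wend, pwm))

    if not pooled:
        return hitset

    # full alignment (with traceback) for qualifying candidates
    raw_hits: list[MappingHit] = []
    for mode, strand, wstart, wend, pwm in pooled:
        scheme = config.scheme.with_mode(mode)
        window = genome.fetch(wstart, wend)
        aln = prob_needleman_wunsch(pwm, window, scheme)
        gstart = wstart + aln.genome_start_offset
        chrom, pos0 = genome.locate(gstart)
        bases = read.bases if strand == "+" else rc_read.bases
        quals = read.quals if strand == "+" else rc_read.quals
        raw_hits.append(
            MappingHit(
                read_id=read.id,
                chrom=chrom,
                pos=pos0 + 1,
                strand=strand,
                mode=mode,
                score=aln.score,
                cigar=aln.cigar,
                genome_frame_bases=bases,
                genome_frame_quals=quals,
            )
        )

    # duplicate (chrom, pos, strand) across modes: keep the higher score.
    # Scores within one epsilon are ties (the CT/GA matrices differ by
    # O(quality-error) terms even without any conversion evidence); ties
    # deterministically keep CT.
    tie_eps = 1e-4 * max(1.0, float(read.effective_length))
    best: dict[tuple[str, int, str], MappingHit] = {}
    for hit in raw_hits:
        key = (hit.chrom, hit.pos, hit.strand)
        prev = best.get(key)
        if (
            prev is None
            or hit.score > prev.score + tie_eps
            or (
                abs(hit.score - prev.score) <= tie_eps
                and _MODE_RANK[hit.mode] < _MODE_RANK[prev.mode]
            )
        ):
            best[key] = hit
    chrom_rank = {name: i for i, name in enumerate(genome.names)}
    hits = sorted(
        best.values(),
        key=lambda h: (-h.score, chrom_rank[h.chrom], h.pos, h.strand),
    )[: config.max_hits]
    for hit, p in zip(hits, posterior_probabilities([h.score for h in hits])):
        hit.posterior = float(p)
    hitset.hits = hits
    hitset.passed_threshold = True
    return hitset


def _map_batch(
    reads: Sequence[BisulfiteRead],
    genome: ReferenceGenome,
    index: GenomeIndex,
    config: MapperConfig,
) -> list[HitSet]:
    return [align_read(r, genome, index, config) for r in reads]


_WORKER_STATE: dict = {}


def _worker_map(args):
    lo, hi = args
    return _map_batch(
        _WORKER_STATE["reads"][lo:hi],
        _WORKER_STATE["genome"],
        _WORKER_STATE["index"],
        _WORKER_STATE["config"],
    )


def map_reads(
    reads: Sequence[BisulfiteRead],
    genome: ReferenceGenome,
    index: GenomeIndex,
    config: MapperConfig | None = None,
    workers: int = 1,
    qc: bool = True,
) -> list[HitSet]:
    """Map a batch of reads; results are independent of ``workers``.

    Reads are processed in independent chunks whose outputs are merged in
    input order, so 1 and N workers produce identical output.
    """
    from .prob_align import qc_read

    config = config or MapperConfig()
    if qc:
        reads = [
            qc_read(r, config.mask_quality, config.trim_quality) for r in reads
        ]
    if workers <= 1 or len(reads) < 2:
        return _map_batch(reads, genome, index, config)

    import multiprocessing as mp

    bounds = np.linspace(0, len(reads), workers * 4 + 1).astype(int)
    chunks = [
        (int(lo), int(hi)) for lo, hi in zip(bounds[:-1], bounds[1:]) if hi > lo
    ]
    _WORKER_STATE.update(
        reads=reads, genome=genome, index=index, config=config
    )
    try:
        ctx = mp.get_context("fork")
        with ctx.Pool(workers) as pool:
            parts = pool.map(_worker_map, chunks)
    finally:
        _WORKER_STATE.clear()
    out: list[HitSet] = []
    for part in parts:
        out.extend(part)
    return out


def _mapq(posterior: float) -> int:
    if posterior >= 1.0:
        return 60
    return min(60, int(round(-10.0 * math.log10(1.0 - posterior))))


def sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in zip(genome.names, genome.lengths)
            ],
            "PG": [{"ID": "probsmap", "PN": "probsmap", "VN": __version__}],
        }
    )


def write_sam(
    hitsets: Iterable[HitSet], genome: ReferenceGenome, path: str | Path
) -> None:
    """Emit one SAM line per hit (secondary hits flagged 0x100) plus unmapped reads.

    MAPQ is derived from the posterior as round(-10*log10(1 - P)), capped
    at 60; the exact posterior is carried in the XP:f tag, the conversion
    mode in XB:A (C for CT, G for GA) and the alignment score in AS:i.
    """
    header = sam_header(genome)
    chrom_id = {name: i for i, name in enumerate(genome.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hs in hitsets:
            if not hs.hits:
                seg = pysam.AlignedSegment(header)
                seg.query_name = hs.read_id
                seg.flag = 0x4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
                if hs.read is not None and len(hs.read.bases) > 0:
                    seg.query_sequence = hs.read.bases
                    seg.query_qualities = array_to_quals(hs.read.quals)
                out.write(seg)
                continue
            for rank, hit in enumerate(hs.hits):
                seg = pysam.AlignedSegment(header)
                seg.query_name = hs.read_id
                flag = 0
                if hit.strand == "-":
                    flag |= 0x10
                if rank > 0:
                    flag |= 0x100
                seg.flag = flag
                seg.reference_id = chrom_id[hit.chrom]
                seg.reference_start = hit.pos - 1
                seg.mapping_quality = _mapq(hit.posterior)
                seg.cigarstring = hit.cigar
                seg.query_sequence = hit.genome_frame_bases
                if hit.genome_frame_quals is not None:
                    seg.query_qualities = array_to_quals(hit.genome_frame_quals)
                seg.set_tag("AS", int(round(hit.score)), "i")
                seg.set_tag("XP", float(hit.posterior), "f")
                seg.set_tag("XB", "C" if hit.mode == "CT" else "G", "A")
                out.write(seg)


def array_to_quals(quals: np.ndarray):
    import array

    return array.array("B", [int(q) for q in quals])


def read_fastq(path: str | Path) -> list[BisulfiteRead]:
    """Load single-end reads from FASTQ (Phred+33) or FASTA (quality 40)."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") else "fastq"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        bases = str(rec.seq).upper()
        if fmt == "fasta":
            quals = np.full(len(bases), 40, dtype=np.int64)
        else:
            quals = np.asarray(
                rec.letter_annotations["phred_quality"], dtype=np.int64
            )
        reads.append(BisulfiteRead(rec.id, bases, quals))
    return reads
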