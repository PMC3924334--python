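"""Quality-aware probabilistic Needleman-Wunsch with bisulfite scoring.

Each read position is represented by a probability distribution over
A/C/G/T derived from its Phred quality; the substitution score against a
genome base is the expectation of the match/mismatch score under that
distribution.  Bisulfite chemistry is handled by a one-sided change to
the scoring matrix: in CT mode a read T over a genome C scores as a
match (the signature of an unmethylated, converted cytosine) while a
read C over a genome T remains a mismatch; GA mode does the same for
read A over genome G on the PCR-synthesized strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _dp

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}

A, C, G, T, N = range(5)


@dataclass
class BisulfiteRead:
    """A single-end bisulfite read: bases, Phred qualities, QC bookkeeping.

    ``effective_length`` is the number of informative bases left after
    3'-trimming and N-masking; it drives the adaptive score threshold.
    """

    id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, one per base
    effective_length: int = field(default=-1)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != self.quals.size:
            raise ValueError(f"{self.id}: bases/qualities length mismatch")
        if self.effective_length < 0:
            self.effective_length = len(self.bases) - self.bases.count("N")

    @property
    def mappable(self) -> bool:
        return self.effective_length > 0

    @classmethod
    def from_phred33(cls, id: str, bases: str, qual_string: str) -> "BisulfiteRead":
        quals = np.frombuffer(qual_string.encode(), dtype=np.uint8).astype(np.int64) - 33
        return cls(id, bases.upper(), quals)


@dataclass
class ScoringScheme:
    """Match/mismatch/affine-gap parameters plus the bisulfite mode."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    mode: str = "plain"  # "CT", "GA", or "plain"

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mode not in ("CT", "GA", "plain"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def with_mode(self, mode: str) -> "ScoringScheme":
        return replace(self, mode=mode)

    def matrix(self) -> np.ndarray:
        """(4 read bases) x (5 genome bases incl. N) expected-score matrix."""
        m = np.full((4, 5), self.mismatch)
        for b in range(4):
            m[b, b] = self.match
        if self.mode == "CT":
            m[T, C] = self.match  # converted unmethylated cytosine
        elif self.mode == "GA":
            m[A, G] = self.match  # same event seen on the PCR strand
        m[:, N] = self.mismatch  # genome N never matches
        return m


@dataclass
class Alignment:
    score: float
    cigar: str
    genome_start_offset: int  # bases skipped at the window's 5' end
    aligned_pairs: list[tuple[int | None, int | None]]  # (read idx, window idx)


def qc_read(
    read: BisulfiteRead, mask_quality: int = 2, trim_quality: int = 2
) -> BisulfiteRead:
    """3'-trim then N-mask low-quality bases.

    The trailing maximal run of bases with quality <= ``trim_quality`` is
    removed; any remaining base with quality <= ``mask_quality`` becomes N
    (its quality entry is kept).  A read emptied by trimming is returned
    with effective_length 0 and is flagged unmappable.
    """
    if mask_quality < 0 or trim_quality < 0:
        raise ValueError("quality thresholds must be >= 0")
    quals = read.quals
    end = len(read.bases)
    while end > 0 and quals[end - 1] <= trim_quality:
        end -= 1
    bases = list(read.bases[:end])
    kept_quals = quals[:end].copy()
    n_masked = 0
    for i in range(end):
        if kept_quals[i] <= mask_quality or bases[i] == "N":
            if bases[i] != "N":
                n_masked += 1
            bases[i] = "N"
    n_existing = read.bases[:end].count("N")
    return BisulfiteRead(
        read.id, "".join(bases), kept_quals, effective_length=end - n_masked - n_existing
    )


def read_to_pwm(read: BisulfiteRead) -> np.ndarray:
    """Per-position base probabilities from Phred qualities.

    A called base with Phred quality Q has error probability
    eps = 10**(-Q/10): the called base gets 1 - eps, the other three
    eps/3.  An N is fully uncertain: 0.25 everywhere.
    """
    L = len(read.bases)
    pwm = np.empty((L, 4))
    eps = 10.0 ** (-read.quals / 10.0)
    for i, b in enumerate(read.bases):
        if b == "N":
            pwm[i] = 0.25
        else:
            pwm[i] = eps[i] / 3.0
            pwm[i, BASE_TO_CODE[b]] = 1.0 - eps[i]
    return pwm


def substitution_score(row: np.ndarray, genome_base: str, scheme: ScoringScheme) -> float:
    """Expected score of one read-position distribution vs one genome base."""
    g = BASE_TO_CODE[genome_base]
    return float(row @ scheme.matrix()[:, g])


# fast vectorized encoder: ASCII -> code lookup
_CODE_LUT = np.full(256, 4, dtype=np.int64)
for _b, _c in BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _c


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as integer codes 0..4."""
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def score_profile(pwm: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    """(L, 5) expected substitution scores: pwm rows x scoring matrix."""
    return pwm @ scheme.matrix()


def prob_needleman_wunsch(
    pwm: np.ndarray, window: str, scheme: ScoringScheme
) -> Alignment:
    """Optimal semi-global alignment of a read profile to a genome window.

    The read is consumed in full; unaligned window overhangs on either
    side are free.  Ties are broken deterministically (diagonal over
    read-gap over genome-gap; leftmost end column).
    """
    if pwm.shape[0] == 0:
        raise ValueError("empty position probability matrix")
    codes = encode(window)
    profile = score_profile(pwm, scheme)
    score, start, moves = _dp.nw_traceback(
        profile, codes, scheme.gap_open, scheme.gap_extend
    )
    cigar = _dp.moves_to_cigar(moves)
    pairs: list[tuple[int | None, int | None]] = []
    i, j = 0, start
    for m in moves:
        if m == 0:
            pairs.append((i, j))
            i += 1
            j += 1
        elif m == 1:
            pairs.append((i, None))
            i += 1
        else:
            pairs.append((None, j))
            j += 1
    return Alignment(score=score, cigar=cigar, genome_start_offset=start, aligned_pairs=pairs)


def alignment_score(pwm: np.ndarray, window: str, scheme: ScoringScheme) -> float:
    """Score-only fast path of :func:`prob_needleman_wunsch`."""
    codes = encode(window)
    profile = score_profile(pwm, scheme)
    return float(_dp.nw_score(profile, codes, scheme.gap_open, scheme.gap_extend))


def min_score_threshold(
    effective_length: int, a_fraction: float, scheme: ScoringScheme
) -> float:
    """Adaptive acceptance threshold: a_fraction of the perfect score.

    The perfect score scales with the effective (post-QC) read length, so
    trimming a read lowers the bar proportionally.
    """
    if effective_length < 1:
        raise ValueError("effective length must be >= 1")
    if not 0 < a_fraction <= 1:
        raise ValueError("a_fraction must be in (0, 1]")
    return a_fraction * effective_length * scheme.match
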