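"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: the
alignment oracle enumerates monotone alignments recursively, the hash
oracle scans every genome offset with string slicing, and the seed-vote
oracle counts matching k-mers per candidate start directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from probsmap.reference_index import ReferenceGenome, bs_convert_sequence

NEG = float("-inf")


def brute_force_nw(profile: np.ndarray, codes: np.ndarray, gap_open: float,
                   gap_extend: float) -> float:
    """Exhaustive recursion over all monotone semi-global alignments.

    The read (profile rows) must be consumed in full; window overhangs on
    both sides are free.  Gap runs are affine: first gapped base costs
    gap_open, each further base gap_extend.
    """
    L = profile.shape[0]
    W = codes.shape[0]
    best = [NEG]

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        if i == L:
            if score > best[0]:
                best[0] = score
            return
        if j < W:
            rec(i + 1, j + 1, score + profile[i, codes[j]], "M")
        rec(i + 1, j, score + (gap_extend if last == "I" else gap_open), "I")
        if j < W:
            rec(i, j + 1, score + (gap_extend if last == "D" else gap_open), "D")

    for start in range(W + 1):
        rec(0, start, 0.0, None)
    return best[0]


def naive_hash(genome: ReferenceGenome, k: int, step: int, mode: str = "CT"):
    """Dictionary of converted k-mers built by scanning every offset."""
    out: dict[str, list[int]] = {}
    for c, (_, seq) in enumerate(genome.chromosomes):
        conv = bs_convert_sequence(seq, mode)
        base = int(genome.boundaries[c])
        for off in range(0, len(conv) - k + 1, step):
            kmer = conv[off : off + k]
            if len(kmer) == k and "N" not in kmer:
                out.setdefault(kmer, []).append(base + off)
    return out


def naive_vote_counts(conv_read: str, conv_genome: str, k: int) -> dict[int, int]:
    """Votes per alignment start, counted by direct k-mer comparison."""
    votes: dict[int, int] = {}
    L = len(conv_read)
    for start in range(-L, len(conv_genome)):
        n = 0
        for j in range(L - k + 1):
            g = start + j
            if "N" in conv_read[j : j + k]:
                continue
            if 0 <= g <= len(conv_genome) - k and conv_genome[g : g + k] == conv_read[j : j + k]:
                n += 1
        if n:
            votes[start] = n
    return votes


def random_genome_string(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=p))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
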