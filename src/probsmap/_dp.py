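"""Compiled dynamic-programming kernels for the probabilistic aligner.

The alignment is semi-global: the read is consumed in full while the
genome window has free (unpenalized) overhangs on both sides.  Gaps are
affine.  ``profile[i, g]`` holds the expected substitution score of read
position i against genome base code g (A,C,G,T,N = 0..4), so the kernels
are agnostic of the bisulfite scoring mode.

Kernels fall back to pure Python when numba is unavailable; results are
identical either way.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


NEG_INF = -1.0e30

# traceback move codes
_DIAG = 0
_UP = 1  # consume read (insertion to genome -> CIGAR I)
_LEFT = 2  # consume genome (deletion from read -> CIGAR D)


@njit(cache=True)
def nw_score(profile, codes, gap_open, gap_extend):
    """Best semi-global score of the read profile against the window codes."""
    L = profile.shape[0]
    W = codes.shape[0]
    H = np.zeros(W + 1)
    E = np.full(W + 1, NEG_INF)  # vertical gap state (read consumed in gap)
    Hprev = np.zeros(W + 1)
    for i in range(1, L + 1):
        for j in range(W + 1):
            Hprev[j] = H[j]
        # column 0: read overhang before the window, penalized as one gap
        e0 = Hprev[0] + gap_open
        alt = E[0] + gap_extend
        if alt > e0:
            e0 = alt
        E[0] = e0
        H[0] = e0
        F = NEG_INF
        for j in range(1, W + 1):
            e = Hprev[j] + gap_open
            alt = E[j] + gap_extend
            if alt > e:
                e = alt
            E[j] = e
            f = H[j - 1] + gap_open
            alt = F + gap_extend
            if alt > f:
                f = alt
            F = f
            h = Hprev[j - 1] + profile[i - 1, codes[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[j] = h
    best = H[0]
    for j in range(1, W + 1):
        if H[j] > best:
            best = H[j]
    return best


@njit(cache=True)
def nw_matrices(profile, codes, gap_open, gap_extend):
    """Full H/E/F matrices for traceback (same recurrences as nw_score)."""
    L = profile.shape[0]
    W = codes.shape[0]
    H = np.zeros((L + 1, W + 1))
    E = np.full((L + 1, W + 1), NEG_INF)
    F = np.full((L + 1, W + 1), NEG_INF)
    for i in range(1, L + 1):
        e0 = H[i - 1, 0] + gap_open
        alt = E[i - 1, 0] + gap_extend
        if alt > e0:
            e0 = alt
        E[i, 0] = e0
        H[i, 0] = e0
        for j in range(1, W + 1):
            e = H[i - 1, j] + gap_open
            alt = E[i - 1, j] + gap_extend
            if alt > e:
                e = alt
            E[i, j] = e
            f = H[i, j - 1] + gap_open
            alt = F[i, j - 1] + gap_extend
            if alt > f:
                f = alt
            F[i, j] = f
            h = H[i - 1, j - 1] + profile[i - 1, codes[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


def nw_traceback(profile, codes, gap_open, gap_extend):
    """Score plus one optimal alignment path.

    Returns ``(score, genome_start, moves)`` where ``moves`` is an array of
    move codes (0 diagonal / 1 read-gap / 2 genome-gap) from the start of
    the alignment, and ``genome_start`` is the number of window bases
    skipped for free before the first aligned pair.

    Tie-breaking is deterministic: the smallest end column achieving the
    optimum is chosen, and at each cell diagonal is preferred over a
    vertical gap over a horizontal gap (gap states prefer opening).
    """
    H, E, F = nw_matrices(profile, codes, gap_open, gap_extend)
    L = profile.shape[0]
    W = codes.shape[0]
    end = int(np.argmax(H[L]))  # argmax returns the first (smallest) index
    score = float(H[L, end])
    moves: list[int] = []
    i, j = L, end
    state = "H"
    while i > 0:
        if state == "H":
            if j > 0 and H[i, j] == H[i - 1, j - 1] + profile[i - 1, codes[j - 1]]:
                moves.append(_DIAG)
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            moves.append(_UP)
            opened = H[i - 1, j] + gap_open
            i -= 1
            if E[i + 1, j] == opened:
                state = "H"
        else:  # state == "F"
            moves.append(_LEFT)
            opened = H[i, j - 1] + gap_open
            j -= 1
            if F[i, j + 1] == opened:
                state = "H"
    return score, j, np.asarray(moves[::-1], dtype=np.int8)


def moves_to_cigar(moves: np.ndarray) -> str:
    """Collapse a move-code path into a SAM CIGAR string (M/I/D)."""
    ops = "MID"
    out = []
    run_op = -1
    run_len = 0
    for m in moves:
        if m == run_op:
            run_len += 1
        else:
            if run_len:
                out.append(f"{run_len}{ops[run_op]}")
            run_op = int(m)
            run_len = 1
    if run_len:
        out.append(f"{run_len}{ops[run_op]}")
    return "".join(out)
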