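"""Posterior-weighted methylation calling from bisulfite alignments.

Every aligned read base over a genomic cytosine contributes its hit's
posterior mapping probability to the base tally at that site, so a read
mapped to J equally good locations adds 1/J of a read's worth of
evidence at each.  The methylation ratio at a cytosine is the weighted
C mass divided by the weighted C+T mass:

    c[i] = sum P(r_d | n_i = C_methylated) / sum P(r_d)

CT-mode hits report on forward-strand cytosines (genomic C positions);
GA-mode hits descend from the PCR-synthesized strand, so their G/A
signal at genomic G positions is attributed to the cytosine of the
complementary (bottom) strand.

Significance of methylation at a site is assessed with a one-sided
binomial likelihood-ratio test against a small null C rate that absorbs
sequencing error and residual non-conversion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from scipy.stats import chi2

from .mapper import HitSet
from .reference_index import ReferenceGenome

BASE_ORDER = "ACGTN"
_BASE_IDX = {b: i for i, b in enumerate(BASE_ORDER)}
_COMP_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

DEFAULT_NULL_C_RATE = 0.01


@dataclass
class CytosineSite:
    """Per-cytosine evidence record (weighted counts in posterior-mass units)."""

    chromosome: str
    position: int  # 1-based
    strand: str
    context: str  # "CG" or "CH"
    read_count: int = 0
    weighted_A: float = 0.0
    weighted_C: float = 0.0
    weighted_G: float = 0.0
    weighted_T: float = 0.0
    weighted_N: float = 0.0
    methylation_ratio: float | None = None
    p_value: float = 1.0


class MethylomeTable:
    """One row per genomic cytosine: forward-strand Cs and reverse-strand Cs
    (genomic Gs), ordered by (chromosome, position)."""

    COLUMNS = [
        "chrom", "pos", "strand", "context", "read_count",
        "wA", "wC", "wG", "wT", "wN", "ratio", "p_value",
    ]

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def sites(self) -> Iterable[CytosineSite]:
        for row in self.frame.itertuples(index=False):
            yield CytosineSite(
                chromosome=row.chrom, position=int(row.pos), strand=row.strand,
                context=row.context, read_count=int(row.read_count),
                weighted_A=row.wA, weighted_C=row.wC, weighted_G=row.wG,
                weighted_T=row.wT, weighted_N=row.wN,
                methylation_ratio=None if pd.isna(row.ratio) else float(row.ratio),
                p_value=float(row.p_value),
            )

    def ratio_map(self) -> dict[tuple[str, int, str], float]:
        """(chrom, pos, strand) -> defined methylation ratio."""
        out = {}
        for row in self.frame.itertuples(index=False):
            if not pd.isna(row.ratio):
                out[(row.chrom, int(row.pos), row.strand)] = float(row.ratio)
        return out


def _cigar_aligned_arrays(cigar: str, pos0: int) -> tuple[np.ndarray, np.ndarray]:
    """Read indices and genome positions of the M-aligned columns of a CIGAR."""
    ridx, gpos = [], []
    r = 0
    g = pos0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "M=X":
            ridx.extend(range(r, r + n))
            gpos.extend(range(g, g + n))
            r += n
            g += n
        elif op in "IS":
            r += n
        elif op in "DN":
            g += n
    return np.asarray(ridx, dtype=np.int64), np.asarray(gpos, dtype=np.int64)


class _EvidenceAccumulator:
    """Vectorized per-genome-position tallies shared by both input paths."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        self.is_c = codes == ord("C")
        self.is_g = codes == ord("G")
        L = genome.total_length
        # [strand 0=+ (genomic C), 1=- (genomic G)] x [base A..N] x position
        self.counts = np.zeros((2, 5, L), dtype=np.float64)
        self.read_count = np.zeros((2, L), dtype=np.int64)

    def add_hit(
        self, chrom: str, pos0: int, mode: str, cigar: str,
        bases_codes: np.ndarray, posterior: float,
    ) -> None:
        offset = self.genome.global_offset(chrom, 0)
        ridx, gpos = _cigar_aligned_arrays(cigar, offset + pos0)
        if gpos.size and gpos[-1] >= self.genome.total_length:
            raise ValueError("alignment extends beyond the genome")
        if mode == "CT":
            m = self.is_c[gpos]
            s = 0
            b = bases_codes[ridx[m]]
        else:
            m = self.is_g[gpos]
            s = 1
            b = _COMP_IDX[bases_codes[ridx[m]]]
        p = gpos[m]
        np.add.at(self.counts[s], (b, p), posterior)
        np.add.at(self.read_count[s], p, 1)

    def to_table(self) -> MethylomeTable:
        g = self.genome
        rows = []
        for strand_idx, mask in ((0, self.is_c), (1, self.is_g)):
            pos = np.flatnonzero(mask)
            rows.append((strand_idx, pos))
        recs = []
        for strand_idx, pos in rows:
            strand = "+" if strand_idx == 0 else "-"
            counts = self.counts[strand_idx][:, pos]
            recs.append(
                pd.DataFrame(
                    {
                        "gpos": pos,
                        "strand": strand,
                        "read_count": self.read_count[strand_idx][pos],
                        "wA": counts[0], "wC": counts[1], "wG": counts[2],
                        "wT": counts[3], "wN": counts[4],
                    }
                )
            )
        frame = pd.concat(recs, ignore_index=True)
        frame.sort_values(["gpos", "strand"], inplace=True, kind="mergesort")
        frame.reset_index(drop=True, inplace=True)
        gpos = frame["gpos"].to_numpy()
        bidx = np.searchsorted(g.boundaries, gpos, side="right") - 1
        frame["chrom"] = np.asarray(g.names, dtype=object)[bidx]
        frame["pos"] = gpos - g.boundaries[bidx] + 1
        frame["context"] = _contexts(g, gpos, frame["strand"].to_numpy())
        frame.drop(columns=["gpos"], inplace=True)
        _finalize(frame)
        return MethylomeTable(frame[MethylomeTable.COLUMNS].copy())


def _contexts(genome: ReferenceGenome, gpos: np.ndarray, strands: np.ndarray) -> list[str]:
    seq = genome.sequence
    out = []
    for p, s in zip(gpos, strands):
        if s == "+":
            nxt = seq[p + 1] if p + 1 < genome.total_length else ""
            # dinucleotide must not span a chromosome boundary
            same = p + 1 < genome.chrom_span(p)[1]
            out.append("CG" if (same and nxt == "G") else "CH")
        else:
            prv = seq[p - 1] if p - 1 >= 0 else ""
            same = p - 1 >= genome.chrom_span(p)[0]
            out.append("CG" if (same and prv == "C") else "CH")
    return out


def _finalize(frame: pd.DataFrame, null_c_rate: float = DEFAULT_NULL_C_RATE) -> None:
    wc = frame["wC"].to_numpy()
    wt = frame["wT"].to_numpy()
    denom = wc + wt
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, wc / np.maximum(denom, 1e-300), np.nan)
    frame["ratio"] = ratio
    frame["p_value"] = _lrt_pvalues(wc, wt, null_c_rate)


def _lrt_pvalues(wc: np.ndarray, wt: np.ndarray, null_c_rate: float) -> np.ndarray:
    """Vectorized one-sided binomial LRT on rounded effective counts."""
    if not 0 < null_c_rate < 1:
        raise ValueError("null C rate must be in (0, 1)")
    nc = np.round(wc).astype(np.int64)
    nt = np.round(wt).astype(np.int64)
    n = nc + nt
    p = np.ones(nc.size)
    ok = n > 0
    chat = np.where(ok, nc / np.maximum(n, 1), 0.0)
    sided = ok & (chat > null_c_rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        ll1 = np.where(nc > 0, nc * np.log(chat), 0.0) + np.where(
            nt > 0, nt * np.log(1.0 - chat), 0.0
        )
        ll0 = nc * math.log(null_c_rate) + nt * math.log(1.0 - null_c_rate)
    lam = 2.0 * (ll1 - ll0)
    p[sided] = chi2.sf(lam[sided], df=1)
    return p


def methylation_ratio(site: CytosineSite) -> float | None:
    """Eq.-(2)-style ratio: weighted C over weighted C + T; None if uncovered."""
    denom = site.weighted_C + site.weighted_T
    if denom <= 0:
        return None
    return site.weighted_C / denom


def methylation_significance(
    site: CytosineSite, null_c_rate: float = DEFAULT_NULL_C_RATE
) -> float:
    """One-sided binomial likelihood-ratio p-value for excess Cs at a site.

    H0: P(C) = null_c_rate vs H1: P(C) = observed ratio, on rounded
    effective counts; the statistic 2*[l(c_hat) - l(null)] is referred to
    a chi-square with 1 df; an observed ratio at or below the null gives
    p = 1.
    """
    if not 0 < null_c_rate < 1:
        raise ValueError("null C rate must be in (0, 1)")
    if site.weighted_C + site.weighted_T <= 0:
        raise ValueError("site has no C/T evidence")
    p = _lrt_pvalues(
        np.array([site.weighted_C]), np.array([site.weighted_T]), null_c_rate
    )
    return float(p[0])


def accumulate_evidence(
    hitsets: Iterable[HitSet],
    genome: ReferenceGenome,
    null_c_rate: float = DEFAULT_NULL_C_RATE,
) -> MethylomeTable:
    """Build the per-cytosine table from in-memory mapping results."""
    from .prob_align import encode

    acc = _EvidenceAccumulator(genome)
    for hs in hitsets:
        for hit in hs.hits:
            acc.add_hit(
                hit.chrom, hit.pos - 1, hit.mode, hit.cigar,
                encode(hit.genome_frame_bases), hit.posterior,
            )
    table = acc.to_table()
    _finalize(table.frame, null_c_rate)
    return table


def accumulate_from_sam(
    sam_path: str | Path,
    genome: ReferenceGenome,
    null_c_rate: float = DEFAULT_NULL_C_RATE,
) -> MethylomeTable:
    """Build the per-cytosine table from a SAM file carrying XP/XB tags."""
    from .prob_align import encode

    acc = _EvidenceAccumulator(genome)
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            posterior = float(rec.get_tag("XP")) if rec.has_tag("XP") else 1.0
            mode = "GA" if (rec.has_tag("XB") and rec.get_tag("XB") == "G") else "CT"
            acc.add_hit(
                rec.reference_name, rec.reference_start, mode,
                rec.cigarstring, encode(rec.query_sequence.upper()), posterior,
            )
    table = acc.to_table()
    _finalize(table.frame, null_c_rate)
    return table


def merge_cg_dyads(
    table: MethylomeTable, genome: ReferenceGenome,
    null_c_rate: float = DEFAULT_NULL_C_RATE,
) -> MethylomeTable:
    """Sum the two strands' weighted counts over each CpG dyad.

    Returns a table with one row per CG dyad, reported at the position of
    the forward-strand C with strand '+'.
    """
    f = table.frame
    plus = f[(f.strand == "+") & (f.context == "CG")].set_index(["chrom", "pos"])
    minus = f[(f.strand == "-") & (f.context == "CG")].copy()
    minus["pos"] = minus["pos"] - 1  # G of the dyad sits one base right of the C
    minus = minus.set_index(["chrom", "pos"])
    joined = plus.join(minus, how="outer", lsuffix="", rsuffix="_m")
    out = pd.DataFrame(index=joined.index)
    for col in ("wA", "wC", "wG", "wT", "wN"):
        out[col] = joined[col].fillna(0.0) + joined[f"{col}_m"].fillna(0.0)
    out["read_count"] = (
        joined["read_count"].fillna(0) + joined["read_count_m"].fillna(0)
    ).astype(np.int64)
    out = out.reset_index()
    out["strand"] = "+"
    out["context"] = "CG"
    out.sort_values(["chrom", "pos"], inplace=True, kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    _finalize(out, null_c_rate)
    return MethylomeTable(out[MethylomeTable.COLUMNS].copy())


def write_gmp(table: MethylomeTable, path: str | Path) -> None:
    """Write the per-cytosine summary as a tab-separated text file."""
    f = table.frame
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tpos\tstrand\tcontext\tread_count\twA\twC\twG\twT\twN\tratio\tp_value\n"
        )
        for row in f.itertuples(index=False):
            ratio = "NA" if pd.isna(row.ratio) else f"{row.ratio:.6f}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t{row.read_count}\t"
                f"{row.wA:.4f}\t{row.wC:.4f}\t{row.wG:.4f}\t{row.wT:.4f}\t{row.wN:.4f}\t"
                f"{ratio}\t{row.p_value:.6g}\n"
            )


def read_gmp(path: str | Path) -> MethylomeTable:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    frame.columns = MethylomeTable.COLUMNS  # first header field carries the '#'
    return MethylomeTable(frame)


def concordance(
    estimates: Mapping, reference: Mapping, cutoff: float = 0.25
) -> float:
    """Fraction of shared sites whose two methylation levels differ by < cutoff."""
    shared = [k for k in estimates if k in reference]
    shared = [
        k for k in shared
        if estimates[k] is not None and reference[k] is not None
    ]
    if not shared:
        raise ValueError("no shared sites with defined ratios")
    hits = sum(1 for k in shared if abs(estimates[k] - reference[k]) < cutoff)
    return hits / len(shared)
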