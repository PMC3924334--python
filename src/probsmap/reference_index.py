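"""Reference genome handling and three-letter k-mer seed index.

Bisulfite chemistry converts unmethylated cytosine to thymine (read-out),
so a bisulfite read may legitimately differ from the reference at every
unmethylated C.  Seeding therefore works in a reduced alphabet: the genome
and the reads are both "in-silico converted" (C->T for reads descended
from the original top strand, G->A for reads descended from the
PCR-synthesized strand) before exact k-mer lookup.  The index stores the
positions of every k-mer of the converted forward genome, one sub-table
per conversion mode, so that all four read orientations can be seeded.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_CT_TABLE = str.maketrans("C", "T")
_GA_TABLE = str.maketrans("G", "A")
_IUPAC_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")

_INDEX_MAGIC = b"PBSIDX"
_INDEX_VERSION = 2


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


class IndexFormatError(ValueError):
    """Serialized index file is corrupt or has an incompatible version."""


@dataclass
class ReferenceGenome:
    """An ordered set of named chromosomes over the A/C/G/T/N alphabet.

    Chromosomes are concatenated into a single global offset space
    (0-based, half-open); ``boundaries[c]`` is the global offset of the
    first base of chromosome ``c``.  k-mers spanning a chromosome
    boundary are never indexed.
    """

    chromosomes: list[tuple[str, str]]
    names: list[str] = field(init=False)
    lengths: list[int] = field(init=False)
    boundaries: np.ndarray = field(init=False)  # starts, plus total at end
    total_length: int = field(init=False)
    sequence: str = field(init=False)  # concatenated forward genome

    def __post_init__(self) -> None:
        self.names = [n for n, _ in self.chromosomes]
        if len(set(self.names)) != len(self.names):
            raise FastaError("duplicate chromosome name")
        seqs = []
        for name, seq in self.chromosomes:
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaError(
                    f"invalid characters {sorted(bad)} in chromosome {name!r}"
                )
            seqs.append(seq)
        self.lengths = [len(s) for s in seqs]
        self.boundaries = np.concatenate([[0], np.cumsum(self.lengths)])
        self.total_length = int(self.boundaries[-1])
        self.sequence = "".join(seqs)

    def digest(self) -> str:
        h = hashlib.sha256()
        for name, seq in self.chromosomes:
            h.update(name.encode())
            h.update(b"\0")
            h.update(seq.encode())
            h.update(b"\0")
        return h.hexdigest()

    def locate(self, offset: int) -> tuple[str, int]:
        """Global offset -> (chromosome name, 0-based position)."""
        if not 0 <= offset < self.total_length:
            raise IndexError(f"offset {offset} outside genome")
        c = int(np.searchsorted(self.boundaries, offset, side="right")) - 1
        return self.names[c], int(offset - self.boundaries[c])

    def global_offset(self, chrom: str, pos0: int) -> int:
        c = self.names.index(chrom)
        if not 0 <= pos0 < self.lengths[c]:
            raise IndexError(f"position {pos0} outside {chrom}")
        return int(self.boundaries[c]) + pos0

    def chrom_span(self, offset: int) -> tuple[int, int]:
        """Global [start, end) of the chromosome containing ``offset``."""
        c = int(np.searchsorted(self.boundaries, offset, side="right")) - 1
        return int(self.boundaries[c]), int(self.boundaries[c + 1])

    def fetch(self, start: int, end: int) -> str:
        return self.sequence[start:end]


def _clean_sequence(raw: str, name: str) -> str:
    seq = raw.upper()
    if set(seq) <= VALID_BASES:
        return seq
    cleaned = seq.translate(_IUPAC_TO_N)
    if set(cleaned) <= VALID_BASES:
        warnings.warn(
            f"ambiguity codes in chromosome {name!r} mapped to N", stacklevel=3
        )
        return cleaned
    return seq  # invalid characters surface as FastaError downstream


def load_fasta(paths: str | Path | Sequence[str | Path]) -> ReferenceGenome:
    """Read one or more FASTA files into a :class:`ReferenceGenome`.

    Multiple files concatenate their records in the given order.
    Lower-case bases are uppercased; IUPAC ambiguity codes other than N
    are mapped to N with a warning.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    chroms: list[tuple[str, str]] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except ValueError as exc:
            raise FastaError(f"{path}: {exc}") from exc
        if not records:
            raise FastaError(f"{path}: no FASTA records (missing '>' header?)")
        for rec in records:
            chroms.append((rec.id, _clean_sequence(str(rec.seq), rec.id)))
    return ReferenceGenome(chroms)


def bs_convert_sequence(seq: str, mode: str) -> str:
    """Apply in-silico bisulfite conversion: CT replaces C->T, GA replaces G->A."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence")
    if mode == "CT":
        return seq.translate(_CT_TABLE)
    if mode == "GA":
        return seq.translate(_GA_TABLE)
    raise ValueError(f"unknown conversion mode {mode!r}")


@dataclass
class KmerHashTable:
    """Exact-match seed table over one converted strand of the genome.

    ``entries`` maps each converted k-mer to the ascending array of global
    genome offsets at which the converted genome spells that k-mer.
    """

    k: int
    step: int
    mode: str
    entries: dict[str, np.ndarray]
    genome_digest: str = ""

    def lookup(self, kmer: str) -> np.ndarray:
        return self.entries.get(kmer, _EMPTY_OFFSETS)

    def __eq__(self, other: object) -> bool:  # field-for-field, array-aware
        if not isinstance(other, KmerHashTable):
            return NotImplemented
        return (
            self.k == other.k
            and self.step == other.step
            and self.mode == other.mode
            and self.genome_digest == other.genome_digest
            and self.entries.keys() == other.entries.keys()
            and all(
                np.array_equal(v, other.entries[key])
                for key, v in self.entries.items()
            )
        )


_EMPTY_OFFSETS = np.empty(0, dtype=np.int64)


def build_hash(
    genome: ReferenceGenome, k: int, step: int = 1, mode: str = "CT"
) -> KmerHashTable:
    """Hash every k-mer of the converted forward genome.

    Offsets run {0, step, 2*step, ...} within each chromosome; windows
    containing N and windows spanning a chromosome boundary are skipped.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    if k > max(genome.lengths, default=0):
        raise ValueError(f"k={k} exceeds every chromosome length")
    entries: dict[str, list[int]] = {}
    for c, (_, seq) in enumerate(genome.chromosomes):
        conv = bs_convert_sequence(seq, mode)
        base = int(genome.boundaries[c])
        for off in range(0, len(conv) - k + 1, step):
            kmer = conv[off : off + k]
            if "N" in kmer:
                continue
            entries.setdefault(kmer, []).append(base + off)
    packed = {key: np.asarray(v, dtype=np.int64) for key, v in entries.items()}
    return KmerHashTable(k, step, mode, packed, genome.digest())


@dataclass
class GenomeIndex:
    """Paired CT/GA seed tables over the forward genome.

    The CT table seeds reads descended from the original strands (their
    converted form matches the C->T genome); the GA table seeds reads
    descended from the PCR-synthesized strands, whose conversions appear
    as G->A in forward-genome coordinates.
    """

    ct: KmerHashTable
    ga: KmerHashTable

    @property
    def k(self) -> int:
        return self.ct.k

    @property
    def step(self) -> int:
        return self.ct.step

    @property
    def genome_digest(self) -> str:
        return self.ct.genome_digest

    def table(self, mode: str) -> KmerHashTable:
        if mode == "CT":
            return self.ct
        if mode == "GA":
            return self.ga
        raise ValueError(f"unknown mode {mode!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIndex):
            return NotImplemented
        return self.ct == other.ct and self.ga == other.ga


def build_index(genome: ReferenceGenome, k: int = 17, step: int = 1) -> GenomeIndex:
    return GenomeIndex(
        ct=build_hash(genome, k, step, "CT"),
        ga=build_hash(genome, k, step, "GA"),
    )


def _to_payload(obj: KmerHashTable | GenomeIndex):
    if isinstance(obj, KmerHashTable):
        return ("table", obj)
    if isinstance(obj, GenomeIndex):
        return ("index", obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def save_index(obj: KmerHashTable | GenomeIndex, path: str | Path) -> None:
    """Write a seed table (or CT/GA pair) to a versioned binary container."""
    payload = pickle.dumps(_to_payload(obj), protocol=4)
    with open(path, "wb") as fh:
        fh.write(_INDEX_MAGIC)
        fh.write(bytes([_INDEX_VERSION]))
        fh.write(len(payload).to_bytes(8, "little"))
        fh.write(payload)


def load_index(path: str | Path) -> KmerHashTable | GenomeIndex:
    """Load a serialized seed table; raises :class:`IndexFormatError` on corruption."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_INDEX_MAGIC))
        if magic != _INDEX_MAGIC:
            raise IndexFormatError(f"{path}: not a seed-index file")
        version = fh.read(1)
        if not version or version[0] != _INDEX_VERSION:
            raise IndexFormatError(
                f"{path}: unsupported index version {version!r}"
            )
        size_bytes = fh.read(8)
        if len(size_bytes) != 8:
            raise IndexFormatError(f"{path}: truncated header")
        size = int.from_bytes(size_bytes, "little")
        payload = fh.read(size)
        if len(payload) != size:
            raise IndexFormatError(f"{path}: truncated payload")
    try:
        kind, obj = pickle.loads(payload)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure is corruption
        raise IndexFormatError(f"{path}: corrupt payload ({exc})") from exc
    if kind not in ("table", "index"):
        raise IndexFormatError(f"{path}: unknown payload kind {kind!r}")
    return obj


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
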