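"""Reference/FASTQ ingestion and exact-seed read mapping.

The termini signal used throughout this package depends only on the
*starting position* of each sequenced read, so alignment is reduced to an
exact match of the first ``S`` bases of the read (the seed) against the
reference top strand and its reverse complement.  Reads whose seed matches
nowhere go to an unmapped pool (reused later for host analysis); reads whose
seed matches more than one location are discarded from the profiles and
tallied, since a wrong start position would corrupt the terminus signal.

Coordinate conventions
----------------------
Internally every coordinate is 0-based.  A forward alignment ``start`` is the
reference position of the read's first base.  A reverse alignment ``start``
is the top-strand position of the base *complementary to the read's first
sequenced base*, i.e. the rightmost top-strand position the read reaches.
With this convention reverse-strand starting positions accumulate at right
termini, mirroring forward starts at left termini.
"""

from __future__ import annotations

import gzip
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC nucleotide codes accepted in a reference sequence.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")

DEFAULT_SEED_LENGTH = 20
DEFAULT_MAX_INSERT = 2000


def revcomp(sequence: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass(frozen=True)
class ReferenceGenome:
    """A single-contig reference genome (phage or host)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"reference {self.id!r} contains non-IUPAC character "
                f"{sorted(bad)[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class ReadRecord:
    """A sequencing read; ``mate`` is 1 or 2 for paired data, 0 otherwise."""

    id: str
    sequence: str
    mate: int = 0


@dataclass(slots=True)
class Alignment:
    read_id: str
    strand: str  # "forward" | "reverse"
    start: int
    read_length: int


@dataclass(slots=True)
class Fragment:
    """A sequencing fragment reconstructed from a properly oriented pair.

    ``[left, right)`` on the top strand; ``orientation`` is the strand of
    mate 1 (or of the single read).
    """

    left: int
    right: int
    orientation: str = "forward"

    @property
    def size(self) -> int:
        return self.right - self.left


def load_reference(path) -> ReferenceGenome:
    """Load the first record of a FASTA file as the reference.

    Phage references are single contigs; extra records trigger a warning and
    are ignored.
    """
    records = list(SeqIO.parse(_open_text(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path, len(records), records[0].id,
        )
    rec = records[0]
    return ReferenceGenome(id=rec.id, sequence=str(rec.seq).upper())


def read_fastq(path, mate: int = 0) -> list[ReadRecord]:
    with _open_text(path) as fh:
        return [
            ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), mate=mate)
            for rec in SeqIO.parse(fh, "fastq")
        ]


def load_read_pairs(reads1, reads2=None) -> list[tuple[ReadRecord, ReadRecord | None]]:
    """Load one or two FASTQ files into a list of (mate1, mate2|None) pairs."""
    r1 = read_fastq(reads1, mate=1 if reads2 else 0)
    if reads2 is None:
        return [(rec, None) for rec in r1]
    r2 = read_fastq(reads2, mate=2)
    if len(r1) != len(r2):
        raise ValueError(
            f"paired FASTQ files have unequal read counts ({len(r1)} vs {len(r2)})"
        )
    return list(zip(r1, r2))


class SeedIndex:
    """Exact k-mer lookup table over a reference top strand."""

    def __init__(self, sequence: str, k: int):
        if k < 10:
            raise ValueError(f"seed length must be >= 10, got {k}")
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            index.setdefault(sequence[i : i + k], []).append(i)
        self._index = index

    def hits(self, seed: str) -> Sequence[int]:
        return self._index.get(seed, ())


@dataclass
class MappingResult:
    alignments: list[Alignment]
    fragments: list[Fragment]
    unmapped: list[ReadRecord]
    n_reads: int = 0
    n_mapped: int = 0
    n_multi: int = 0
    mean_read_length: float = 0.0
    F: float | None = None
    F_is_approximate: bool = False
    pair_alignments: list[tuple[Alignment | None, Alignment | None]] = field(
        default_factory=list
    )


def _map_one(rec: ReadRecord, index: SeedIndex):
    """Return ('unique', Alignment) | ('multi', None) | ('unmapped', None)."""
    S = index.k
    if len(rec.sequence) < S:
        return "unmapped", None
    seed = rec.sequence[:S]
    fwd = index.hits(seed)
    rev = index.hits(revcomp(seed))
    n = len(fwd) + len(rev)
    if n == 0:
        return "unmapped", None
    if n > 1:
        return "multi", None
    if fwd:
        aln = Alignment(rec.id, "forward", fwd[0], len(rec.sequence))
    else:
        # seed occupies [p, p+S) on the top strand; the read's first base is
        # complementary to the top-strand base at p+S-1
        aln = Alignment(rec.id, "reverse", rev[0] + S - 1, len(rec.sequence))
    return "unique", aln


def map_reads(
    pairs: Sequence[tuple[ReadRecord, ReadRecord | None]],
    ref: ReferenceGenome,
    seed_length: int = DEFAULT_SEED_LENGTH,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> MappingResult:
    """Map reads by exact seed match; reconstruct fragments from proper pairs.

    A fragment is emitted for a pair when both mates map uniquely, on
    opposite strands, with the forward mate to the left and an insert of at
    most ``max_insert``.  Improper pairs still contribute their individual
    reads to the alignments (hence SPC/COV) but no fragment.
    """
    index = SeedIndex(ref.sequence, seed_length)
    result = MappingResult(alignments=[], fragments=[], unmapped=[])
    lengths: list[int] = []

    for r1, r2 in pairs:
        alns: list[Alignment | None] = []
        for rec in (r1, r2):
            if rec is None:
                alns.append(None)
                continue
            result.n_reads += 1
            lengths.append(len(rec.sequence))
            status, aln = _map_one(rec, index)
            if status == "unique":
                result.alignments.append(aln)
                result.n_mapped += 1
            elif status == "multi":
                result.n_multi += 1
            else:
                result.unmapped.append(rec)
            alns.append(aln)
        result.pair_alignments.append((alns[0], alns[1] if len(alns) > 1 else None))

        a1, a2 = alns[0], (alns[1] if len(alns) > 1 else None)
        if a1 is not None and a2 is not None and a1.strand != a2.strand:
            fwd, rev = (a1, a2) if a1.strand == "forward" else (a2, a1)
            left, right = fwd.start, rev.start + 1
            if left < right and right - left <= max_insert:
                result.fragments.append(
                    Fragment(left=left, right=right, orientation=a1.strand)
                )

    result.mean_read_length = statistics.fmean(lengths) if lengths else 0.0
    if result.fragments:
        result.F = mean_fragment_size(result.fragments)
        result.F_is_approximate = False
    elif lengths:
        # single-end stand-in: read length approximates fragment size
        result.F = result.mean_read_length
        result.F_is_approximate = True
    return result


def mean_fragment_size(fragments: Iterable[Fragment]) -> float:
    """Arithmetic mean fragment size (the F of the background model)."""
    sizes = [f.size for f in fragments]
    if not sizes:
        raise ValueError("cannot compute mean fragment size of an empty set")
    return statistics.fmean(sizes)
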